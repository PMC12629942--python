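"""Stage supervision, anchor geometry and cognition-guided penalties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroprog import (
    AnchorSet,
    CognitiveField,
    SoftStageHead,
    anchor_loss,
    cognitive_direction_penalty,
    disentangle_penalty,
    monotonicity_penalty,
    ordinal_regularizer,
    stage_kl_loss,
    stage_probabilities,
)
from neuroprog.autodiff import Tensor, value_of


def _head(weight, bias):
    return SoftStageHead(Tensor(np.asarray(weight, float)),
                         Tensor(np.asarray(bias, float)))


class TestStageProbabilities:
    def test_zero_parameters_uniform(self):
        head = _head(np.zeros((3, 2)), np.zeros(3))
        p = value_of(stage_probabilities(np.array([5.0, -1.0]), head))
        assert np.allclose(p, 1.0 / 3.0)

    def test_large_bias_dominates(self):
        head = _head(np.zeros((3, 2)), [10.0, 0.0, 0.0])
        p = value_of(stage_probabilities(np.zeros(2), head))
        assert p[0] > 0.9999

    def test_matches_hand_softmax(self):
        w = np.array([[1.0, 0.0], [0.5, -0.5], [0.0, 1.0]])
        b = np.array([0.1, 0.0, -0.2])
        z = np.array([0.4, 0.8])
        logits = w @ z + b
        expect = np.exp(logits) / np.exp(logits).sum()
        got = value_of(stage_probabilities(z, _head(w, b)))
        assert np.allclose(got, expect, atol=1e-6)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_simplex_membership(self, seed):
        r = np.random.default_rng(seed)
        head = _head(r.normal(size=(4, 3)), r.normal(size=4))
        p = value_of(stage_probabilities(r.normal(size=3), head))
        assert np.all(p > 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)


class TestStageKL:
    def test_one_hot_prediction_zero(self):
        p = np.array([0.0, 1.0, 0.0])
        # exact one-hot on the true stage: -log 1 = 0
        assert float(value_of(stage_kl_loss(np.array([1e-300, 1.0, 1e-300]), 1))) \
            == pytest.approx(0.0, abs=1e-12)

    def test_uniform_three_stages_ln3(self):
        p = np.full(3, 1.0 / 3.0)
        assert float(value_of(stage_kl_loss(p, 2))) == \
            pytest.approx(np.log(3.0), abs=1e-12)

    def test_hand_value(self):
        p = np.array([0.7, 0.2, 0.1])
        assert float(value_of(stage_kl_loss(p, 1))) == \
            pytest.approx(-np.log(0.2), abs=1e-9)

    def test_equals_cross_entropy_with_one_hot(self, rng):
        """KL(one-hot || p) == cross-entropy oracle on random simplexes."""
        for _ in range(50):
            raw = rng.random(4) + 1e-3
            p = raw / raw.sum()
            s = int(rng.integers(4))
            onehot = np.eye(4)[s]
            xent = -(onehot * np.log(p)).sum()
            assert float(value_of(stage_kl_loss(p, s))) == \
                pytest.approx(xent, abs=1e-9)

    def test_exact_zero_capped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            out = stage_kl_loss(np.array([1.0, 0.0]), 1)
        assert float(out) == pytest.approx(1e3)


class TestAnchors:
    def test_zero_at_anchor(self):
        anchors = AnchorSet.create(3, 2, anchors=np.arange(6.0).reshape(3, 2))
        z = np.array([[0.0, 1.0], [4.0, 5.0]])
        assert float(value_of(anchor_loss(z, [0, 2], anchors))) == \
            pytest.approx(0.0)

    def test_residual_1_2_gives_5(self):
        anchors = AnchorSet.create(2, 2)
        z = np.array([[1.0, 2.0]])
        assert float(value_of(anchor_loss(z, [0], anchors))) == pytest.approx(5.0)

    def test_unlabeled_contribute_zero(self):
        anchors = AnchorSet.create(2, 2)
        z = np.array([[1.0, 2.0], [50.0, 50.0]])
        with_unlabeled = float(value_of(anchor_loss(z, [0, None], anchors)))
        assert with_unlabeled == pytest.approx(5.0)

    def test_ordinal_zero_for_even_spacing(self):
        delta = np.array([0.5, -0.25])
        mus = np.stack([np.array([1.0, 1.0]) + s * delta for s in range(4)])
        aset = AnchorSet.create(4, 2, anchors=mus, shift=delta)
        assert float(value_of(ordinal_regularizer(aset))) == \
            pytest.approx(0.0, abs=1e-18)

    def test_ordinal_1d_hand_value(self):
        aset = AnchorSet.create(3, 1, anchors=np.array([[0.0], [1.0], [3.0]]),
                                shift=np.array([1.0]))
        assert float(value_of(ordinal_regularizer(aset))) == pytest.approx(1.0)

    def test_ordinal_translation_invariant(self, rng):
        mus = rng.normal(size=(4, 3))
        shift = rng.normal(size=3)
        a = AnchorSet.create(4, 3, anchors=mus, shift=shift)
        b = AnchorSet.create(4, 3, anchors=mus + 2.5, shift=shift)
        assert float(value_of(ordinal_regularizer(a))) == \
            pytest.approx(float(value_of(ordinal_regularizer(b))), rel=1e-12)

    def test_gradient_step_decreases_anchor_loss(self, rng):
        """A small gradient step on the anchors strictly decreases the loss."""
        aset = AnchorSet.create(3, 2, anchors=rng.normal(size=(3, 2)))
        z = rng.normal(size=(10, 2))
        stages = rng.integers(0, 3, size=10)
        loss = anchor_loss(Tensor(z), stages, aset)
        loss.backward()
        before = loss.item()
        aset.anchors.value -= 1e-3 * aset.anchors.grad
        after = float(value_of(anchor_loss(z, stages, aset)))
        assert after < before


class TestCognitiveField:
    def _field(self, u, c=0.0):
        return CognitiveField(Tensor(np.asarray(u, float)),
                              Tensor(np.asarray(c)))

    def test_antiparallel_flow_zero(self):
        field = self._field([1.0, 1.0])
        velocities = -np.tile([1.0, 1.0], (5, 1))
        assert float(value_of(cognitive_direction_penalty(velocities, field))) \
            == pytest.approx(0.0)

    def test_parallel_flow_norm_squared(self):
        """Flow equal to u with ||u||^2 = 2 is penalised by exactly 2."""
        field = self._field([1.0, 1.0])
        velocities = np.tile([1.0, 1.0], (5, 1))
        assert float(value_of(cognitive_direction_penalty(velocities, field))) \
            == pytest.approx(2.0)

    def test_zero_direction_degenerate(self, rng):
        field = self._field([0.0, 0.0])
        assert float(value_of(cognitive_direction_penalty(
            rng.normal(size=(7, 2)), field))) == pytest.approx(0.0)


class TestMonotonicity:
    def test_nondecreasing_series_zero(self):
        p = np.array([[0.8, 0.1, 0.1], [0.5, 0.2, 0.3], [0.2, 0.3, 0.5]])
        assert float(value_of(monotonicity_penalty(p))) == pytest.approx(0.0)

    def test_decrease_mass(self):
        p = np.array([[0.2, 0.8], [0.4, 0.6]])
        assert float(value_of(monotonicity_penalty(p))) == pytest.approx(0.2)

    def test_reversed_series_no_penalty(self):
        p = np.array([[0.4, 0.6], [0.2, 0.8]])
        assert float(value_of(monotonicity_penalty(p))) == pytest.approx(0.0)

    def test_stage_zero_excluded(self):
        """A decline in the baseline-stage probability is not penalised."""
        p = np.array([[0.9, 0.1], [0.1, 0.9]])
        assert float(value_of(monotonicity_penalty(p))) == pytest.approx(0.0)

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            monotonicity_penalty(np.array([[0.5, 0.5]]))


class TestDisentangle:
    def test_same_labels_zero(self, rng):
        z = rng.normal(size=(5, 3))
        assert float(value_of(disentangle_penalty(z, [1] * 5))) == 0.0

    def test_coincident_different_labels(self):
        z = np.zeros((2, 3))
        assert float(value_of(disentangle_penalty(z, [0, 1]))) == \
            pytest.approx(2.0)

    def test_vanishes_at_large_separation(self):
        z = np.array([[0.0, 0.0], [100.0, 0.0]])
        assert float(value_of(disentangle_penalty(z, [0, 1]))) < 1e-100


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 100_000))
def test_every_penalty_nonnegative(seed):
    """All alignment penalties are >= 0 on random configurations."""
    r = np.random.default_rng(seed)
    k, n = 3, 6
    z = r.normal(size=(n, k))
    head = SoftStageHead(Tensor(r.normal(size=(4, k))), Tensor(r.normal(size=4)))
    aset = AnchorSet.create(4, k, anchors=r.normal(size=(4, k)),
                            shift=r.normal(size=k))
    field = CognitiveField(Tensor(r.normal(size=k)), Tensor(np.asarray(0.0)))
    probs = value_of(stage_probabilities(z, head))
    stages = r.integers(0, 4, size=n)
    checks = [
        float(value_of(stage_kl_loss(probs[0], int(stages[0])))),
        float(value_of(anchor_loss(z, stages, aset))),
        float(value_of(ordinal_regularizer(aset))),
        float(value_of(cognitive_direction_penalty(r.normal(size=(5, k)), field))),
        float(value_of(monotonicity_penalty(probs))),
        float(value_of(disentangle_penalty(z, stages))),
    ]
    assert all(c >= 0.0 for c in checks)
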