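"""Quadrature and the five clinical coherence constraints."""

import numpy as np
import pytest

from neuroprog import (
    CoherenceSpecs,
    PiecewiseCurve,
    TreatmentShift,
    biomarker_alignment_loss,
    counterfactual_loss,
    manifold_projection_loss,
    modality_consistency_loss,
    quadrature,
    template_alignment_loss,
)
from neuroprog.autodiff import Tensor, value_of
from neuroprog.stage_cognition import CognitiveField


def _field(u, c=0.0):
    return CognitiveField(Tensor(np.asarray(u, float)), Tensor(np.asarray(c)))


class TestQuadrature:
    def test_constant_closed_form(self):
        grid = np.array([0.0, 1.0, 2.0])
        assert quadrature(np.full(3, 0.25), grid) == pytest.approx(0.5)

    def test_affine_exactness_on_irregular_grid(self):
        grid = np.array([0.0, 0.13, 0.4, 0.77, 1.0])
        assert quadrature(grid.copy(), grid) == pytest.approx(0.5, abs=1e-15)

    def test_quadratic_converges(self):
        grid = np.linspace(0.0, 1.0, 1001)
        assert quadrature(grid**2, grid) == pytest.approx(1.0 / 3.0, abs=1e-5)

    def test_second_order_convergence(self):
        """Halving the spacing quarters the error on a smooth integrand."""
        exact = 1.0 - np.cos(1.0)
        errors = []
        for n in (8, 16, 32):
            grid = np.linspace(0.0, 1.0, n + 1)
            errors.append(abs(quadrature(np.sin(grid), grid) - exact))
        for a, b in zip(errors, errors[1:]):
            assert a / b == pytest.approx(4.0, rel=0.1)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            quadrature(np.array([1.0]), np.array([0.0]))


def _specs_with_decoder(weight, bias=0.0, curves=None):
    return CoherenceSpecs(
        biomarker_decoder={"W": Tensor(np.asarray(weight, float)),
                           "b": Tensor(np.asarray(bias))},
        reference_curves=curves or {},
    )


class TestBiomarkerAlignment:
    def test_zero_when_predictions_match(self):
        grid = np.linspace(0.0, 2.0, 21)
        curves = {"b0": PiecewiseCurve([0.0, 2.0], [0.3, 0.3])}
        specs = _specs_with_decoder([1.0], bias=0.3, curves=curves)
        traj = np.zeros((21, 1, 1))  # Gamma(r) = 0.3 everywhere
        assert value_of(biomarker_alignment_loss(traj, specs, grid)) == \
            pytest.approx(0.0)

    def test_constant_offset_closed_form(self):
        """Offset 0.5 over T=2 integrates to 0.5^2 * 2 = 0.5."""
        grid = np.linspace(0.0, 2.0, 21)
        curves = {"b0": PiecewiseCurve([0.0, 2.0], [0.0, 0.0])}
        specs = _specs_with_decoder([0.0], bias=0.5, curves=curves)
        traj = np.zeros((21, 1, 1))
        assert value_of(biomarker_alignment_loss(traj, specs, grid)) == \
            pytest.approx(0.5)

    def test_two_variables_sum(self):
        grid = np.linspace(0.0, 1.0, 11)
        curves = {
            "b0": PiecewiseCurve([0.0, 1.0], [0.0, 0.0]),
            "b1": PiecewiseCurve([0.0, 1.0], [0.0, 0.0]),
        }
        specs = _specs_with_decoder([1.0], curves=curves)
        traj = np.zeros((11, 2, 1))
        traj[:, 0, 0] = 0.5  # offsets 0.5 and 1.0
        traj[:, 1, 0] = 1.0
        assert value_of(biomarker_alignment_loss(
            traj, specs, grid, variables=["b0", "b1"]
        )) == pytest.approx(0.25 + 1.0)

    def test_missing_curve_names_variable(self):
        specs = _specs_with_decoder([1.0],
                                    curves={"b0": PiecewiseCurve([0, 1], [0, 0])})
        with pytest.raises(KeyError, match="b9"):
            biomarker_alignment_loss(np.zeros((3, 1, 1)), specs,
                                     np.linspace(0, 1, 3), variables=["b9"])


class TestTemplateAlignment:
    def test_zero_when_readout_matches(self):
        grid = np.linspace(0.0, 3.0, 31)
        template = PiecewiseCurve([0.0, 3.0], [1.0, -2.0])
        specs = CoherenceSpecs(templates={0: template})
        field = _field([1.0], c=1.0)
        z = (template(grid) - 1.0)[:, None]  # u.z + c reproduces the template
        assert value_of(template_alignment_loss(z, 0, specs, field, grid)) == \
            pytest.approx(0.0, abs=1e-18)

    def test_constant_deviation_closed_form(self):
        grid = np.linspace(0.0, 3.0, 31)
        specs = CoherenceSpecs(templates={0: PiecewiseCurve([0, 3], [0, 0])})
        z = np.ones((31, 1))
        assert value_of(template_alignment_loss(z, 0, specs, _field([1.0]),
                                                grid)) == pytest.approx(3.0)

    def test_linear_deviation_third(self):
        grid = np.linspace(0.0, 1.0, 201)
        specs = CoherenceSpecs(templates={0: PiecewiseCurve([0, 1], [0, 0])})
        z = grid[:, None]  # deviation t -> integral t^2 = 1/3
        got = value_of(template_alignment_loss(z, 0, specs, _field([1.0]), grid))
        assert got == pytest.approx(1.0 / 3.0, abs=1e-4)

    def test_unknown_subtype_rejected(self):
        specs = CoherenceSpecs(templates={0: PiecewiseCurve([0, 1], [0, 0])})
        with pytest.raises(KeyError):
            template_alignment_loss(np.zeros((3, 1)), 7, specs, _field([1.0]),
                                    np.linspace(0, 1, 3))


class TestModalityConsistency:
    def test_identity_map_equal_embeddings(self):
        specs = CoherenceSpecs(alignment_map=Tensor(np.eye(3)))
        z = np.array([0.5, -1.0, 2.0])
        assert value_of(modality_consistency_loss(z, z, specs)) == \
            pytest.approx(0.0)

    def test_residual_1_2_2_gives_9(self):
        specs = CoherenceSpecs(alignment_map=Tensor(np.eye(3)))
        macro = np.array([1.0, 2.0, 2.0])
        assert value_of(modality_consistency_loss(macro, np.zeros(3), specs)) \
            == pytest.approx(9.0)

    def test_zero_embeddings_zero(self):
        specs = CoherenceSpecs(alignment_map=Tensor(np.ones((3, 3))))
        assert value_of(modality_consistency_loss(np.zeros(3), np.zeros(3),
                                                  specs)) == pytest.approx(0.0)


class TestCounterfactual:
    def test_zero_shift_matching_outcomes(self):
        grid = np.linspace(0.0, 4.0, 41)
        field = _field([1.0], c=0.0)
        z = np.ones((41, 1)) * 2.0  # O(z) = 2
        shift = TreatmentShift.create(1, scale=0.0)
        outcomes = [(1.0, 2.0), (4.0, 2.0)]
        got = value_of(counterfactual_loss(z, grid, 1.0, outcomes, shift, field))
        assert got == pytest.approx(0.0, abs=1e-18)

    def test_pre_onset_identity(self):
        """Delta_a is exactly zero before onset (no anticipation)."""
        shift = TreatmentShift.create(2, scale=3.0, length=0.5,
                                      direction=[1.0, -1.0])
        tau = np.array([-2.0, -0.1, 0.0])
        assert np.allclose(value_of(shift(tau)), 0.0)

    def test_constant_mismatch_closed_form(self):
        """Mismatch 1 over a post-onset window of length 2 integrates to 2."""
        grid = np.linspace(0.0, 3.0, 31)
        field = _field([1.0])
        z = np.zeros((31, 1))  # O(z) = 0
        shift = TreatmentShift.create(1, scale=0.0)
        outcomes = [(1.0, 1.0), (3.0, 1.0)]
        got = value_of(counterfactual_loss(z, grid, 1.0, outcomes, shift, field))
        assert got == pytest.approx(2.0)

    def test_requires_post_outcomes(self):
        shift = TreatmentShift.create(1)
        with pytest.raises(ValueError):
            counterfactual_loss(np.zeros((5, 1)), np.linspace(0, 1, 5), 0.5,
                                [], shift, _field([1.0]))


class TestManifoldProjection:
    def test_in_span_zero(self, rng):
        basis = rng.normal(size=(2, 4))
        coeff = rng.normal(size=(10, 2))
        z = coeff @ basis
        assert value_of(manifold_projection_loss(z, basis)) == \
            pytest.approx(0.0, abs=1e-10)

    def test_hand_residual(self):
        z = np.array([[1.0, 1.0]])
        basis = np.array([[1.0, 0.0]])
        assert value_of(manifold_projection_loss(z, basis)) == pytest.approx(1.0)

    def test_residual_orthogonal_to_basis(self, rng):
        basis = rng.normal(size=(2, 5))
        z = rng.normal(size=(6, 5))
        gram_inv = np.linalg.inv(basis @ basis.T)
        proj = basis.T @ gram_inv @ basis
        resid = z - z @ proj
        assert np.abs(resid @ basis.T).max() < 1e-8

    def test_invariant_to_basis_reparameterization(self, rng):
        """Any invertible recombination of the basis gives the same loss."""
        basis = rng.normal(size=(3, 6))
        mix = rng.normal(size=(3, 3)) + 3.0 * np.eye(3)
        z = rng.normal(size=(8, 6))
        a = value_of(manifold_projection_loss(z, basis))
        b = value_of(manifold_projection_loss(z, mix @ basis))
        q, _ = np.linalg.qr(basis.T)
        c = value_of(manifold_projection_loss(z, q.T))
        assert a == pytest.approx(b, rel=1e-9)
        assert a == pytest.approx(c, rel=1e-9)

    def test_rank_deficient_rejected(self):
        basis = np.array([[1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            manifold_projection_loss(np.zeros((3, 2)), basis)
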