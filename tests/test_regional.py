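"""Graph-attention propagation and the two spatial regularisers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroprog import (
    GraphLayerParams,
    anatomical_projection_penalty,
    attention_coefficients,
    cosine_similarity,
    propagate_regions,
    sync_regularizer,
)
from neuroprog.autodiff import value_of
from neuroprog.cohort import RegionGraph


def _triangle_graph():
    # directed edges into every node: in-neighbourhoods {1,2}, {0}, {0,1}
    edges = [("r1", "r0", 1.0), ("r2", "r0", 1.0), ("r0", "r1", 1.0),
             ("r0", "r2", 1.0), ("r1", "r2", 1.0)]
    kernel = np.ones((3, 3)) - np.eye(3)
    return RegionGraph(["r0", "r1", "r2"], edges, kernel)


class TestCosine:
    def test_self_similarity_is_one(self, rng):
        a = rng.normal(size=5)
        assert value_of(cosine_similarity(a, a)) == pytest.approx(1.0, abs=1e-9)

    def test_antiparallel_is_minus_one(self, rng):
        a = rng.normal(size=5)
        assert value_of(cosine_similarity(a, -a)) == pytest.approx(-1.0, abs=1e-9)

    def test_45_degree_value(self):
        got = value_of(cosine_similarity(np.array([1.0, 0.0]),
                                         np.array([1.0, 1.0])))
        assert got == pytest.approx(1.0 / np.sqrt(2.0), abs=1e-5)

    def test_zero_vector_stabilised(self):
        got = value_of(cosine_similarity(np.zeros(3), np.ones(3)))
        assert abs(got) < 1e-6


class TestAttention:
    def test_identical_neighbours_uniform(self):
        graph = _triangle_graph()
        emb = np.tile(np.array([1.0, 2.0]), (3, 1))
        attn = attention_coefficients(emb, graph)
        nbrs, w = attn[0]
        assert len(nbrs) == 2
        assert np.allclose(value_of(w), 0.5)

    def test_single_neighbour_weight_one(self):
        graph = _triangle_graph()
        emb = np.random.default_rng(0).normal(size=(3, 2))
        nbrs, w = attention_coefficients(emb, graph)[1]  # N(r1) = {r0}
        assert list(nbrs) == [0]
        assert value_of(w)[0] == pytest.approx(1.0)

    def test_similarities_one_and_zero(self):
        """sims {1, 0} to the target give weights (e, 1)/(e+1)."""
        graph = RegionGraph(
            ["a", "b", "c"], [("a", "c", 1.0), ("b", "c", 1.0)],
            kernel=np.zeros((3, 3)),
        )
        emb = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        nbrs, w = attention_coefficients(emb, graph)[2]
        expect = np.array([np.e, 1.0]) / (np.e + 1.0)
        assert np.allclose(value_of(w), expect, atol=1e-5)
        assert value_of(w)[0] == pytest.approx(0.73106, abs=1e-5)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_columns_sum_to_one(self, seed):
        graph = _triangle_graph()
        emb = np.random.default_rng(seed).normal(size=(3, 4))
        attn = attention_coefficients(emb, graph)
        for _, (nbrs, w) in attn.items():
            if len(nbrs):
                assert value_of(w).sum() == pytest.approx(1.0, abs=1e-8)


class TestPropagate:
    def _params(self, rng, d=2, n=3):
        return GraphLayerParams.create(rng, n, d, latent_dim=2)

    def test_zero_weights_zero_bias_tanh(self, rng):
        graph = _triangle_graph()
        params = self._params(rng)
        params.weight.value[:] = 0.0
        params.bias.value[:] = 0.0
        out = propagate_regions(rng.normal(size=(3, 2)), graph, params)
        assert np.allclose(value_of(out), 0.0)

    def test_identity_pass_through_single_neighbour(self, rng):
        graph = RegionGraph(["u", "v"], [("u", "v", 1.0)],
                            kernel=np.zeros((2, 2)))
        params = self._params(rng, n=2)
        params.weight.value[:] = np.eye(2)
        params.bias.value[:] = 0.0
        params.activation = "identity"
        emb = np.array([[0.4, -0.2], [9.0, 9.0]])
        out = value_of(propagate_regions(emb, graph, params))
        assert np.allclose(out[1], emb[0])  # v receives exactly r_u

    def test_three_node_hand_computed(self, rng):
        graph = _triangle_graph()
        params = self._params(rng)
        params.weight.value[:] = np.array([[1.0, 0.5], [0.0, 1.0]])
        params.bias.value[:] = np.array([0.1, -0.1])
        params.activation = "identity"
        emb = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        out = value_of(propagate_regions(emb, graph, params))
        # node r1: single neighbour r0 -> W r0 + b
        assert np.allclose(out[1], params.weight.value.T @ emb[0]
                           + params.bias.value, atol=1e-6)
        # node r0: neighbours r1, r2 with attention from cosine sims
        s1 = 0.0  # cos((0,1),(1,0))
        s2 = 1.0 / np.sqrt(2.0)
        a1, a2 = np.exp([s1, s2]) / (np.exp(s1) + np.exp(s2))
        msg = a1 * params.weight.value.T @ emb[1] + \
            a2 * params.weight.value.T @ emb[2] + params.bias.value
        assert np.allclose(out[0], msg, atol=1e-6)

    def test_equivariant_under_relabeling(self, rng):
        """Relabeling nodes permutes the output embeddings accordingly."""
        graph = _triangle_graph()
        params = self._params(rng)
        emb = rng.normal(size=(3, 2))
        out = value_of(propagate_regions(emb, graph, params))
        perm = [2, 0, 1]  # new index of old node i is perm.index(i)
        ids = [graph.region_ids[p] for p in perm]
        g2 = RegionGraph(ids, graph.edges, graph.kernel[np.ix_(perm, perm)])
        out2 = value_of(propagate_regions(emb[perm], g2, params))
        assert np.allclose(out[perm], out2, atol=1e-9)


class TestSyncRegularizer:
    def test_equal_embeddings_zero(self):
        emb = np.tile(np.array([1.0, 2.0, 3.0]), (4, 1))
        assert sync_regularizer(emb, np.ones((4, 4))) == pytest.approx(0.0)

    def test_two_region_hand_value(self):
        emb = np.array([[0.0, 0.0], [1.0, 1.0]])
        kernel = np.ones((2, 2))
        # ordered pairs (0,1) and (1,0), each kappa * ||diff||^2 = 2
        assert sync_regularizer(emb, kernel) == pytest.approx(4.0)

    def test_linear_in_kernel(self, rng):
        emb = rng.normal(size=(3, 2))
        kernel = np.abs(rng.normal(size=(3, 3)))
        kernel = kernel + kernel.T
        one = sync_regularizer(emb, kernel)
        two = sync_regularizer(emb, 2.0 * kernel)
        assert two == pytest.approx(2.0 * one)

    def test_translation_invariant(self, rng):
        emb = rng.normal(size=(5, 3))
        kernel = np.ones((5, 5))
        shifted = emb + np.array([10.0, -4.0, 2.5])
        assert sync_regularizer(shifted, kernel) == \
            pytest.approx(sync_regularizer(emb, kernel), rel=1e-9)


class TestAnatomicalPenalty:
    def test_zero_at_projection(self, rng):
        params = GraphLayerParams.create(rng, 3, 2, latent_dim=4)
        z = rng.normal(size=4)
        target = value_of(params.project_latent(z))
        got = value_of(anatomical_projection_penalty(target, z, params))
        assert got == pytest.approx(0.0, abs=1e-18)

    def test_squared_residual_convention(self, rng):
        params = GraphLayerParams.create(rng, 1, 2, latent_dim=2)
        params.projections[0]["W"].value[:] = 0.0
        params.projections[0]["b"].value[:] = 0.0
        emb = np.array([[3.0, 4.0]])
        got = value_of(anatomical_projection_penalty(emb, np.zeros(2), params))
        assert got == pytest.approx(25.0)

    def test_invariant_to_region_ordering(self, rng):
        params = GraphLayerParams.create(rng, 4, 3, latent_dim=2)
        z = rng.normal(size=2)
        emb = rng.normal(size=(4, 3))
        base = value_of(anatomical_projection_penalty(emb, z, params))
        perm = [2, 3, 1, 0]
        params2 = GraphLayerParams(
            params.weight, params.bias,
            [params.projections[p] for p in perm], params.activation,
        )
        got = value_of(anatomical_projection_penalty(emb[perm], z, params2))
        assert got == pytest.approx(base, rel=1e-12)
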