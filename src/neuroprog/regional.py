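"""Graph-attention propagation of per-region embeddings and spatial penalties.

Brain regions carry embeddings ``r_v(t)`` that evolve by attention-weighted
message passing over the (directed) region graph:

    r_v(t+1) = sigma( sum_{u in N(v)} alpha_uv W r_u + b ),

with attention ``alpha_uv`` a softmax over the in-neighbourhood of cosine
similarities between the *pre-map* embeddings of u and v.  Two penalties tie
the regional channel to biology and to the subject latent:

* synchronisation — ``sum_{v,w} kappa_vw ||r_v - r_w||^2`` over **ordered**
  pairs (kappa symmetric, so this is a fixed factor-2 convention), penalising
  desynchronisation of compatible regions;
* anatomical projection — ``sum_v ||r_v - A_v z||^2`` anchoring each region
  embedding to a per-region linear projection of the subject latent (squared
  norm throughout, for differentiability).

Regional states are initialised as ``r_v(0) = A_v z(0)`` so the anatomical
prior anchors the channel at baseline; the only coupling back to the subject
latent is the soft projection penalty.

Functions accept numpy arrays or autodiff tensors; embeddings are stacked as
``(n_regions, d)`` or batched ``(batch, n_regions, d)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .cohort import RegionGraph
from .nnet import init_linear

__all__ = [
    "GraphLayerParams",
    "cosine_similarity",
    "attention_coefficients",
    "propagate_regions",
    "sync_regularizer",
    "anatomical_projection_penalty",
]

_STAB = 1e-12  # cosine denominator stabiliser; zero vectors map to sim ~ 0


@dataclass
class GraphLayerParams:
    """Shared message weight/bias, activation, and per-region projections A_v."""

    weight: Tensor          # (d, d)
    bias: Tensor            # (d,)
    projections: list       # per region: dict with 'W' (k, d), 'b' (d,)
    activation: str = "tanh"

    @classmethod
    def create(cls, rng: np.random.Generator, n_regions: int, embed_dim: int,
               latent_dim: int, activation: str = "tanh") -> "GraphLayerParams":
        lin = init_linear(rng, embed_dim, embed_dim)
        return cls(
            weight=lin["W"],
            bias=lin["b"],
            projections=[init_linear(rng, latent_dim, embed_dim)
                         for _ in range(n_regions)],
            activation=activation,
        )

    def parameters(self) -> dict[str, Tensor]:
        out = {"graph.W": self.weight, "graph.b": self.bias}
        for v, proj in enumerate(self.projections):
            out[f"graph.A{v}.W"] = proj["W"]
            out[f"graph.A{v}.b"] = proj["b"]
        return out

    def project_latent(self, z):
        """Stack of A_v z for all regions: (n_regions, d) or (B, R, d)."""
        cols = [z @ p["W"] + p["b"] for p in self.projections]
        return ad.stack(cols, axis=-2)


def cosine_similarity(a, b):
    """a.b / (||a|| ||b|| + 1e-12); operates on the last axis."""
    num = ad.asum(a * b, axis=-1)
    den = ad.sqrt(ad.asum(a * a, axis=-1)) * ad.sqrt(ad.asum(b * b, axis=-1))
    return num / (den + _STAB)


def attention_coefficients(embeddings, graph: RegionGraph):
    """Per-node attention over in-neighbours from cosine similarities.

    Returns ``{v_index: (neighbor_indices, weights)}`` with weights summing
    to 1.  Isolated nodes get an empty neighbour list; propagation then
    falls back to a bias-only update for them.
    """
    idx = {r: i for i, r in enumerate(graph.region_ids)}
    out = {}
    for v_id in graph.region_ids:
        v = idx[v_id]
        nbrs = [idx[u] for u in graph.in_neighbors(v_id)]
        if not nbrs:
            out[v] = (np.array([], dtype=int), np.array([]))
            continue
        r_v = embeddings[..., v, :]
        sims = ad.stack(
            [cosine_similarity(embeddings[..., u, :], r_v) for u in nbrs],
            axis=-1,
        )
        out[v] = (np.array(nbrs, dtype=int), ad.softmax(sims, axis=-1))
    return out


def propagate_regions(embeddings, graph: RegionGraph, params: GraphLayerParams):
    """One message-passing step; deterministic, shape-preserving."""
    if not np.all(np.isfinite(ad.value_of(embeddings))):
        raise ValueError("propagate_regions: non-finite region embeddings")
    attn = attention_coefficients(embeddings, graph)
    act = {"tanh": ad.tanh, "identity": lambda x: x}[params.activation]
    new = []
    for v in range(graph.n_regions):
        nbrs, weights = attn[v]
        msg = params.bias
        for j, u in enumerate(nbrs):
            w_uv = weights[..., j]
            if ad.value_of(w_uv).ndim > 0:  # batched: broadcast over embed dim
                w_uv = w_uv[..., None]
            msg = msg + w_uv * (embeddings[..., u, :] @ params.weight)
        new.append(act(msg))
    return ad.stack(new, axis=-2)


def sync_regularizer(embeddings, kernel):
    """sum over ordered pairs (v, w) of kappa_vw ||r_v - r_w||^2 (>= 0)."""
    kernel = np.asarray(kernel, dtype=float)
    n = kernel.shape[0]
    shape = ad.value_of(embeddings).shape
    if shape[-2] != n:
        raise ValueError("kernel size does not match region count")
    d = shape[-1]
    lead = shape[:-2]
    r1 = embeddings.reshape(*lead, n, 1, d)
    r2 = embeddings.reshape(*lead, 1, n, d)
    diff = r1 - r2
    sq = ad.asum(diff * diff, axis=-1)  # (..., n, n)
    return ad.asum(sq * kernel)


def anatomical_projection_penalty(embeddings, z, params: GraphLayerParams):
    """sum_v ||r_v - A_v z||^2 — soft anchor of regions to the subject latent."""
    target = params.project_latent(z)
    diff = embeddings - target
    return ad.asum(diff * diff)
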