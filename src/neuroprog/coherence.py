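"""Clinical coherence constraints: biomarkers, templates, modalities,
counterfactuals and the canonical disease manifold.

These are the population-level and cross-channel regularisers of the
alignment suite.  All time integrals are evaluated with the trapezoidal
rule on a dense trajectory grid (exact for affine integrands, second-order
on smooth ones); reference biomarker curves and subtype cognitive templates
are stored as piecewise-linear knots and linearly interpolated.

* biomarker alignment — decoded regional biomarkers Gamma(r_v(t)) track
  population-level reference trajectories b̄_v(t);
* template alignment — the cognitive readout O(z(t)) of a subject follows
  the piecewise-linear template of its clinical subtype;
* modality consistency — macro-scale (imaging) and micro-scale (omics)
  embeddings agree through a learned linear alignment map A;
* counterfactual coherence — under a treatment at t_a, the shifted latent
  path z(t) + Delta_a(t - t_a) must reproduce observed post-treatment
  outcomes through O (a regression regulariser, not a causal estimator);
  the shift is scale * (1 - exp(-tau/length)) * direction for tau >= 0 and
  exactly zero before onset;
* manifold projection — latent states stay close to the span of a small
  set of clinical basis vectors; the loss is the squared least-squares
  residual, hence invariant to any re-parameterisation of the basis that
  spans the same subspace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "PiecewiseCurve",
    "TreatmentShift",
    "CoherenceSpecs",
    "quadrature",
    "biomarker_alignment_loss",
    "template_alignment_loss",
    "modality_consistency_loss",
    "counterfactual_loss",
    "manifold_projection_loss",
]


@dataclass
class PiecewiseCurve:
    """Piecewise-linear curve through time-sorted (time, value) knots."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("curve knot times must be strictly increasing")

    def __call__(self, t):
        return np.interp(np.asarray(t, dtype=float), self.times, self.values)


@dataclass
class TreatmentShift:
    """Latent shift Delta_a(tau) = scale * (1 - exp(-tau/length)) * direction.

    Hard zero for tau < 0 (no anticipation of treatment).
    """

    scale: Tensor
    length: float
    direction: Tensor  # (k,)

    @classmethod
    def create(cls, latent_dim: int, scale: float = 0.0,
               length: float = 1.0, direction=None) -> "TreatmentShift":
        if direction is None:
            direction = np.zeros(latent_dim)
        return cls(Tensor(np.asarray(scale, float)), float(length),
                   Tensor(np.asarray(direction, float)))

    def parameters(self) -> dict[str, Tensor]:
        return {"shift.scale": self.scale, "shift.direction": self.direction}

    def __call__(self, tau):
        """Shift vectors for elapsed times `tau` (array (T,) -> (T, k))."""
        tau = np.asarray(tau, dtype=float)
        envelope = np.where(tau >= 0, 1.0 - np.exp(-np.maximum(tau, 0.0) / self.length), 0.0)
        return (self.scale * self.direction) * envelope[..., None]


@dataclass
class CoherenceSpecs:
    """Reference material for the five coherence constraints."""

    biomarker_decoder: dict | None = None       # Gamma: linear d -> 1 ({'W','b'})
    reference_curves: dict[str, PiecewiseCurve] = field(default_factory=dict)
    templates: dict[int, PiecewiseCurve] = field(default_factory=dict)
    alignment_map: Optional[Tensor] = None      # A: micro -> macro
    treatment_shifts: dict[str, TreatmentShift] = field(default_factory=dict)
    manifold_basis: Optional[np.ndarray] = None  # (K, k), rows independent

    def decode_biomarker(self, r):
        """Gamma(r_v): scalar biomarker prediction from a region embedding."""
        if self.biomarker_decoder is None:
            raise ValueError("no biomarker decoder configured")
        return ad.asum(r * self.biomarker_decoder["W"], axis=-1) + \
            self.biomarker_decoder["b"]


def quadrature(values_on_grid, grid) -> float:
    """Trapezoidal integral of sampled values over an increasing grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2:
        raise ValueError("quadrature needs a grid of >= 2 points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("quadrature grid must be strictly increasing")
    dt = np.diff(grid)
    v = values_on_grid
    extra = ad.value_of(v).ndim - 1  # time on axis 0; sum trailing axes too
    dt = dt.reshape((-1,) + (1,) * extra)
    return ad.asum((v[1:] + v[:-1]) * (0.5 * dt))


def biomarker_alignment_loss(regional_trajectory, specs: CoherenceSpecs,
                             grid, variables=None):
    """sum_v integral of (Gamma(r_v(t)) - b̄_v(t))^2 dt.

    `regional_trajectory` is (T, n_regions, d) region embeddings on `grid`;
    `variables` names the reference curve for each region (defaults to the
    dict order of `specs.reference_curves`).  A region without a reference
    curve is an error naming the variable.
    """
    n_regions = ad.value_of(regional_trajectory).shape[-2]
    if variables is None:
        variables = list(specs.reference_curves)
    if len(variables) != n_regions:
        raise ValueError(
            f"{n_regions} regions but {len(variables)} reference variables"
        )
    total = 0.0
    for v, name in enumerate(variables):
        if name not in specs.reference_curves:
            raise KeyError(f"no reference curve for variable '{name}'")
        pred = specs.decode_biomarker(regional_trajectory[:, v, :])
        resid = pred - specs.reference_curves[name](grid)
        total = total + quadrature(resid * resid, grid)
    return total


def template_alignment_loss(latent_states, subtype: int, specs: CoherenceSpecs,
                            observation_head, grid):
    """integral of (O(z(t)) - T_k(t))^2 dt for the subject's subtype k."""
    if subtype not in specs.templates:
        raise KeyError(f"unknown subtype '{subtype}'")
    readout = observation_head.readout(latent_states)
    resid = readout - specs.templates[subtype](grid)
    return quadrature(resid * resid, grid)


def modality_consistency_loss(macro_embedding, micro_embedding,
                              specs: CoherenceSpecs):
    """||Z_macro - A(Z_micro)||^2 with the learned alignment map A."""
    if specs.alignment_map is None:
        raise ValueError("no alignment map configured")
    diff = macro_embedding - micro_embedding @ specs.alignment_map
    return ad.asum(diff * diff)


def counterfactual_loss(latent_states, grid, onset_time: float,
                        post_outcomes, shift: TreatmentShift,
                        observation_head):
    """Post-onset fit of the shifted trajectory to observed treated outcomes.

    Builds z^(a)(t) = z(t) + Delta_a(t - t_a) (identity before onset) and
    integrates (O(z^(a)(t)) - y^(a)(t))^2 over [t_a, T], with the observed
    post-onset outcomes linearly interpolated onto the grid.
    """
    grid = np.asarray(grid, dtype=float)
    if not post_outcomes:
        raise ValueError("counterfactual loss needs post-onset outcomes")
    if onset_time > grid[-1]:
        raise ValueError("treatment onset lies beyond the trajectory horizon")
    mask = grid >= onset_time
    sub_grid = grid[mask]
    if len(sub_grid) < 2:
        raise ValueError("not enough grid points after treatment onset")
    z_post = latent_states[np.nonzero(mask)[0]]
    z_shifted = z_post + shift(sub_grid - onset_time)
    pred = observation_head.readout(z_shifted)
    times = np.array([t for t, _ in post_outcomes], dtype=float)
    vals = np.array([y for _, y in post_outcomes], dtype=float)
    order = np.argsort(times)
    target = np.interp(sub_grid, times[order], vals[order])
    resid = pred - target
    return quadrature(resid * resid, sub_grid)


def manifold_projection_loss(latent_states, basis):
    """Squared residual of each state off the span of the basis vectors.

    `basis` is (K, k) with linearly independent rows (K <= k).  Coefficients
    alpha(t) are the least-squares projection; the loss sums the squared
    residual norms over time.  Raises on a rank-deficient basis.
    """
    basis = np.asarray(ad.value_of(basis), dtype=float)
    if basis.ndim != 2:
        raise ValueError("basis must be a (K, k) matrix")
    if np.linalg.matrix_rank(basis) < basis.shape[0]:
        raise ValueError("manifold basis is rank-deficient")
    # projector onto span(basis): P = B^T (B B^T)^{-1} B
    gram_inv = np.linalg.inv(basis @ basis.T)
    projector = basis.T @ gram_inv @ basis  # (k, k)
    resid = latent_states - latent_states @ projector
    return ad.asum(resid * resid)
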