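"""Continuous-time latent trajectory model.

A subject's disease state is a latent vector ``z(t)`` in R^k that evolves
under a parameterised flow field ``dz/dt = g(z, t; psi)``, where ``psi`` is a
subject-specific conditioning vector.  The flow field is either an explicit
linear field (used for closed-form checks and as the synthetic ground truth)
or a small feed-forward network over ``(z, t, psi, u)`` with the exogenous
modulator ``u(t)`` entering as an extra input channel (zero when absent).

Integration is deliberately fixed-step classical Runge–Kutta (RK4): at desk
scale, bit-for-bit reproducibility across runs matters more than the speed an
adaptive solver would buy.  Query times are answered by linear interpolation
on the dense step grid.  Time is rescaled internally to [0, 1] over the
cohort horizon before entering the network (``time_scale``) for conditioning
stability; all times in the public API are in original units (years).

Fixed points of the flow (``g(z) = 0``) are stationary disease states — e.g.
a "disease attractor" the trajectory drifts toward; `find_fixed_points` is a
multi-start root-search diagnostic for inspecting the fitted field.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional

import numpy as np
from scipy import optimize

from . import autodiff as ad
from .autodiff import Tensor
from .nnet import apply_mlp, init_mlp

__all__ = [
    "LinearFlowField",
    "MLPFlowField",
    "DynamicsParams",
    "LatentTrajectory",
    "flow_field",
    "integrate_trajectory",
    "rk4_path",
    "find_fixed_points",
]


class LinearFlowField:
    """Explicit affine field dz/dt = (z - center) @ A^T  (+ no psi coupling).

    With ``A = -I`` and ``center = 0`` this is plain exponential decay toward
    the origin; with ``center = z*`` the trajectory relaxes toward the
    attractor ``z*`` whenever A is stable.
    """

    def __init__(self, matrix, center=None):
        self.matrix = np.asarray(matrix, dtype=float)
        k = self.matrix.shape[0]
        self.center = np.zeros(k) if center is None else np.asarray(center, float)

    def __call__(self, z, t, psi=None, u=None):
        return (z - self.center) @ self.matrix.T


class CallableFlowField:
    """Adapter for an arbitrary z -> dz/dt function (diagnostics, tests)."""

    def __init__(self, fn: Callable):
        self.fn = fn

    def __call__(self, z, t, psi=None, u=None):
        return self.fn(z)


class MLPFlowField:
    """Learned field g(z, t; psi, u) as a feed-forward net over the concat.

    Whether the field should see wall-clock time at all is an open modelling
    question; here t (rescaled by `time_scale`) is an input and can be
    ablated by zeroing its column.
    """

    def __init__(self, rng: np.random.Generator, latent_dim: int,
                 cond_dim: int, hidden_widths=(16,), u_dim: int = 0,
                 time_scale: float = 1.0, activation: str = "tanh"):
        self.latent_dim = latent_dim
        self.cond_dim = cond_dim
        self.u_dim = u_dim
        self.time_scale = float(time_scale)
        n_in = latent_dim + 1 + cond_dim + u_dim
        self.mlp = init_mlp(rng, [n_in, *hidden_widths, latent_dim], activation)

    def __call__(self, z, t, psi=None, u=None):
        batched = ad.value_of(z).ndim == 2
        n = ad.value_of(z).shape[0] if batched else None

        def ensure(x, dim):
            if x is None:
                shape = (n, dim) if batched else (dim,)
                return np.zeros(shape)
            return x

        tcol = np.full((n, 1) if batched else (1,), t / self.time_scale)
        parts = [z, tcol]
        if self.cond_dim:
            parts.append(ensure(psi, self.cond_dim))
        if self.u_dim:
            parts.append(ensure(u, self.u_dim))
        return apply_mlp(ad.concatenate(parts, axis=-1), self.mlp)


@dataclass
class DynamicsParams:
    """Flow field plus solver settings (fixed-step RK4 with step `step`)."""

    field: object
    step: float = 0.05
    latent_dim: int = 4

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError(f"solver step must be > 0, got {self.step}")
        if self.latent_dim < 1:
            raise ValueError(f"latent_dim must be >= 1, got {self.latent_dim}")


@dataclass
class LatentTrajectory:
    """Latent states on a query-time grid plus the dense solver grid."""

    subject_id: Optional[str]
    times: np.ndarray
    states: np.ndarray  # (len(times), k)
    conditioning: Optional[np.ndarray] = None
    dense_times: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    dense_states: np.ndarray = dc_field(default_factory=lambda: np.empty((0, 0)))


def flow_field(z, t, psi, params: DynamicsParams, u=None):
    """Evaluate the latent velocity dz/dt at (z, t, psi)."""
    zv = ad.value_of(z)
    if not np.all(np.isfinite(zv)):
        raise ValueError("flow_field: non-finite latent state")
    out = params.field(z, t, psi, u)
    if not ad.is_tensor(out) and not np.all(np.isfinite(np.asarray(out))):
        raise FloatingPointError(f"flow_field: non-finite velocity at t={t}")
    return out


def rk4_path(f, z0, t_grid):
    """Classical RK4 along `t_grid`; returns the state at every grid point.

    Works identically on plain numpy states and autodiff tensors, so the
    training loop differentiates through the very same solver the public
    API uses.
    """
    states = [z0]
    z = z0
    for t0, t1 in zip(t_grid[:-1], t_grid[1:]):
        h = t1 - t0
        k1 = f(z, t0)
        k2 = f(z + (0.5 * h) * k1, t0 + 0.5 * h)
        k3 = f(z + (0.5 * h) * k2, t0 + 0.5 * h)
        k4 = f(z + h * k3, t1)
        z = z + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(ad.value_of(z))):
            raise FloatingPointError(
                f"trajectory integration blew up at t={t1:.6g}"
            )
        states.append(z)
    return states


def _dense_grid(t_start: float, t_end: float, step: float) -> np.ndarray:
    if t_end <= t_start:
        return np.array([t_start])
    n = int(np.ceil((t_end - t_start) / step - 1e-12))
    grid = t_start + step * np.arange(n + 1)
    if grid[-1] < t_end - 1e-12:
        grid = np.append(grid, t_end)
    else:
        grid[-1] = max(grid[-1], t_end)
    return grid


def integrate_trajectory(
    z0,
    psi,
    query_times,
    params: DynamicsParams,
    u_fn: Optional[Callable[[float], np.ndarray]] = None,
    t_start: float = 0.0,
    subject_id: Optional[str] = None,
) -> LatentTrajectory:
    """Integrate the flow from ``z(t_start) = z0`` and read off query times.

    The solver marches a dense grid of spacing `params.step` from `t_start`
    to the last query time and linearly interpolates states to the (strictly
    increasing) `query_times`.  Deterministic: no adaptivity, no randomness.
    """
    query_times = np.asarray(query_times, dtype=float)
    if query_times.ndim != 1 or len(query_times) == 0:
        raise ValueError("query_times must be a non-empty 1-d array")
    if np.any(np.diff(query_times) <= 0):
        raise ValueError("query_times must be strictly increasing")
    if query_times[0] < t_start:
        raise ValueError("query_times must start at or after t_start")

    def f(z, t):
        u = None if u_fn is None else u_fn(t)
        return flow_field(z, t, psi, params, u=u)

    grid = _dense_grid(t_start, float(query_times[-1]), params.step)
    states = rk4_path(f, np.asarray(z0, dtype=float), grid)
    dense = np.stack([ad.value_of(s) for s in states])

    out = np.empty((len(query_times), dense.shape[-1]))
    for j in range(dense.shape[-1]):
        out[:, j] = np.interp(query_times, grid, dense[:, j])
    return LatentTrajectory(
        subject_id=subject_id,
        times=query_times,
        states=out,
        conditioning=None if psi is None else np.asarray(psi, float),
        dense_times=grid,
        dense_states=dense,
    )


def find_fixed_points(
    params: DynamicsParams,
    psi,
    search_box: tuple[float, float],
    n_starts: int = 32,
    seed: int = 0,
    t: float = 0.0,
    tol: float = 1e-6,
    dedup: float = 1e-4,
) -> list[np.ndarray]:
    """Multi-start root search for stationary states of the flow field.

    Returns deduplicated points with ``||g(z)|| <= tol``; every returned
    point is re-verified by direct evaluation.  Diagnostic only — the latent
    dimension must be small (k <= 8).
    """
    k = params.latent_dim
    if k > 8:
        raise ValueError("fixed-point search is a diagnostic for k <= 8")
    lo, hi = search_box
    rng = np.random.default_rng(seed)

    def residual(z):
        return np.asarray(ad.value_of(flow_field(z, t, psi, params)), float)

    found: list[np.ndarray] = []
    for _ in range(n_starts):
        z_init = rng.uniform(lo, hi, size=k)
        sol = optimize.root(residual, z_init, method="hybr")
        if not sol.success:
            continue
        z_star = sol.x
        if np.linalg.norm(residual(z_star)) > tol:
            continue
        if any(np.linalg.norm(z_star - p) < dedup for p in found):
            continue
        found.append(z_star)
    return found
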