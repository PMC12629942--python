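"""Synthetic longitudinal cohort generator with known ground truth.

Real multimodal progression cohorts (ADNI-like: irregular visit schedules,
ordinal clinical stages, declining cognition on severity scales, sigmoid
biomarker trajectories, pathology spreading over a region network) cannot be
redistributed, so every component of the model is exercised against cohorts
generated here, where the generating process is known exactly.

Two mechanistic pieces:

* **Regional pathology ODE** — per-region pathology load ``h_v(t)`` evolving
  as ``dh_v/dt = -lambda_v h_v + sum_{u in N(v)} alpha_uv sigma(h_u)
  + beta_v x_v(t)``: intrinsic clearance, nonlinear spread from in-neighbour
  regions, and an exogenous input channel (used e.g. as a treatment
  indicator).  Integrated with fixed-step RK4.

* **Latent progression** — a subject-level latent state ``z(t)`` relaxing
  toward a "disease attractor" ``z*`` under a stable linear flow
  ``dz/dt = -a (z - z*)``.  A 1-d progression score ``p(t) = g . z(t)``
  (g the unit progression direction) is then monotone increasing, which
  yields nondecreasing stage sequences: the clinical expectation the
  alignment constraints encode.  Observables:

  - cognitive score  ``y = u* . z + c* + eta`` with ``u* = -g``: a
    cognition scale that *declines* as disease advances (MMSE-style),
    consistent with the descent constraint on the cognitive field;
  - ordinal stage    = number of fixed increasing thresholds below ``p``;
  - biomarkers       = per-variable logistic functions of ``p`` (staggered
    midpoints emulate the spreading order across regions) plus noise;
  - baseline modality blocks = per-modality linear maps of ``z(0)`` + noise.

Everything is an exact function of (config, seed): the same seed reproduces
the cohort byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .cohort import (
    Cohort,
    ModalityBlock,
    ObservationRecord,
    RegionGraph,
    Subject,
    TreatmentEvent,
    save_cohort,
)
from .dynamics import rk4_path

__all__ = [
    "RegionSimParams",
    "GroundTruth",
    "SimConfig",
    "simulate_regional_pathology",
    "default_region_graph",
    "generate_cohort",
    "inject_treatment_effect",
    "write_simulation",
]

_NONLINEARITIES: dict[str, Callable] = {
    "tanh": np.tanh,
    "identity": lambda h: h,
    "sigmoid": lambda h: 1.0 / (1.0 + np.exp(-h)),
}


@dataclass
class RegionSimParams:
    """Parameters of the regional pathology ODE.

    decay_rates
        Intrinsic clearance rates lambda_v (1/year), strictly positive.
    coupling
        Matrix with entry [u, v] = alpha_uv, the directed spread weight from
        region u into region v (zero where no edge).
    input_gains
        Per-region gains beta_v on the exogenous input x_v(t).
    input_signal
        Function t -> per-region input vector; defaults to zero.
    nonlinearity
        Name of sigma applied to neighbour pathology before spreading.
    """

    decay_rates: np.ndarray
    coupling: np.ndarray
    input_gains: Optional[np.ndarray] = None
    input_signal: Optional[Callable[[float], np.ndarray]] = None
    nonlinearity: str = "tanh"

    def __post_init__(self):
        self.decay_rates = np.asarray(self.decay_rates, dtype=float)
        self.coupling = np.asarray(self.coupling, dtype=float)
        if np.any(self.decay_rates <= 0):
            raise ValueError("decay rates lambda_v must be strictly positive")
        if not np.all(np.isfinite(self.coupling)):
            raise ValueError("coupling weights must be finite")
        if self.nonlinearity not in _NONLINEARITIES:
            raise ValueError(f"unknown nonlinearity '{self.nonlinearity}'")


def simulate_regional_pathology(
    graph: RegionGraph | None,
    params: RegionSimParams,
    initial_state,
    time_grid,
    step: float,
) -> np.ndarray:
    """Integrate the regional pathology ODE on `time_grid` (fixed-step RK4).

    `graph` restricts the coupling to its edges when given (entries of
    `params.coupling` off the edge set are ignored); with ``graph=None`` the
    coupling matrix is used as-is.  Returns an array of shape
    ``(len(time_grid), n_regions)``.  Deterministic; raises on blow-up,
    naming the time.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    if np.any(np.diff(time_grid) <= 0):
        raise ValueError("time_grid must be strictly increasing")
    if step <= 0:
        raise ValueError("step must be > 0")
    h0 = np.asarray(initial_state, dtype=float)
    lam = params.decay_rates
    alpha = params.coupling.copy()
    if graph is not None:
        mask = graph.adjacency() != 0
        alpha = np.where(mask, alpha, 0.0)
    beta = params.input_gains
    x_fn = params.input_signal
    sigma = _NONLINEARITIES[params.nonlinearity]

    def f(h, t):
        drive = sigma(h) @ alpha  # Sigma_u alpha_uv * sigma(h_u), per v
        out = -lam * h + drive
        if beta is not None and x_fn is not None:
            out = out + np.asarray(beta, float) * np.asarray(x_fn(t), float)
        return out

    t0, t_end = float(time_grid[0]), float(time_grid[-1])
    n = max(int(np.ceil((t_end - t0) / step - 1e-12)), 1)
    dense = t0 + (t_end - t0) * np.arange(n + 1) / n
    states = np.stack(rk4_path(f, h0, dense))
    out = np.empty((len(time_grid), len(h0)))
    for j in range(len(h0)):
        out[:, j] = np.interp(time_grid, dense, states[:, j])
    return out


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort.

    Defaults emulate a small ADNI-like longitudinal cohort: a few hundred
    subjects followed for 5 years with 3–8 irregular visits each, four
    ordinal stages, modest observation noise.
    """

    n_subjects: int = 200
    latent_dim: int = 4
    stage_count: int = 4
    time_horizon: float = 5.0
    visits_min: int = 3
    visits_max: int = 8
    img_dim: int = 12
    omics_dim: int = 10
    demo_dim: int = 4
    n_regions: int = 6
    drift_rate: float = 0.5          # 1/year relaxation toward the attractor
    attractor_score: float = 3.0     # progression score at the attractor
    baseline_score_range: tuple = (-1.0, 1.5)
    off_axis_sd: float = 0.5         # latent spread orthogonal to u*
    stage_thresholds: tuple = (0.0, 1.0, 2.0)
    cognitive_intercept: float = 1.0
    cognitive_noise_sd: float = 0.1
    biomarker_noise_sd: float = 0.05
    modality_noise_sd: float = 0.05
    biomarker_midpoints: Optional[tuple] = None   # default: staggered over score range
    biomarker_slope: float = 2.0
    stage_label_fraction: float = 1.0
    n_template_knots: int = 21

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if len(self.stage_thresholds) != self.stage_count - 1:
            raise ValueError(
                "need stage_count - 1 thresholds, got "
                f"{len(self.stage_thresholds)} for {self.stage_count} stages"
            )
        if any(b <= a for a, b in zip(self.stage_thresholds,
                                      self.stage_thresholds[1:])):
            raise ValueError("stage thresholds must be strictly increasing")


@dataclass
class GroundTruth:
    """Everything needed to score a fitted model against the generator.

    The progression direction g drives severity: stages count the fixed
    thresholds the score g . z(t) has crossed.  The cognitive direction is
    its negative, u* = -g, so the cognitive score u* . z + c* declines as
    disease advances (MMSE-style orientation) — consistent with the descent
    constraint the alignment suite places on the cognitive field.
    """

    true_z0: dict[str, np.ndarray]
    attractor: np.ndarray
    drift_rate: float
    progression_direction: np.ndarray    # g, unit vector
    cognitive_direction: np.ndarray      # u* = -g
    cognitive_intercept: float           # c*
    stage_thresholds: np.ndarray
    biomarker_midpoints: np.ndarray
    biomarker_slope: float
    noise_spec: dict[str, float]
    stage_anchors: np.ndarray            # (L+1, k) stage-conditional mean latents
    reference_curve_times: np.ndarray    # knots for population curves
    reference_biomarker_curves: np.ndarray  # (n_knots, n_bio)
    cognitive_template: np.ndarray       # (n_knots,) population-mean true score

    def latent_at(self, subject_id: str, times) -> np.ndarray:
        """Closed-form true latent trajectory z(t) for one subject."""
        t = np.asarray(times, dtype=float)[:, None]
        z0 = self.true_z0[subject_id]
        return self.attractor + np.exp(-self.drift_rate * t) * (z0 - self.attractor)

    def progression(self, subject_id: str, times) -> np.ndarray:
        return self.latent_at(subject_id, times) @ self.progression_direction

    def noiseless_cognitive(self, subject_id: str, times) -> np.ndarray:
        return (self.latent_at(subject_id, times) @ self.cognitive_direction
                + self.cognitive_intercept)

    def stages(self, subject_id: str, times) -> np.ndarray:
        p = self.progression(subject_id, times)
        return (p[:, None] > self.stage_thresholds[None, :]).sum(axis=1)


def default_region_graph(n_regions: int, rng: np.random.Generator) -> RegionGraph:
    """Ring of regions plus a few random shortcuts; kernel from adjacency.

    The compatibility kernel is the symmetrised adjacency plus a small
    baseline so every pair has nonzero compatibility.
    """
    ids = [f"R{i}" for i in range(n_regions)]
    edges = []
    for i in range(n_regions):
        edges.append((ids[i], ids[(i + 1) % n_regions], 1.0))
    n_extra = max(n_regions // 2, 1)
    for _ in range(n_extra):
        i, j = rng.choice(n_regions, size=2, replace=False)
        if (ids[i], ids[j], 1.0) not in edges and i != j:
            edges.append((ids[i], ids[j], round(float(rng.uniform(0.3, 0.9)), 3)))
    adj = np.zeros((n_regions, n_regions))
    idx = {r: i for i, r in enumerate(ids)}
    for s, d, w in edges:
        adj[idx[s], idx[d]] = w
    kernel = 0.5 * (adj + adj.T) + 0.1
    np.fill_diagonal(kernel, 0.0)
    return RegionGraph(ids, edges, kernel)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: SimConfig, seed: int) -> tuple[Cohort, GroundTruth]:
    """Draw a full synthetic cohort plus its ground truth.

    The latent flow is ``dz/dt = -a (z - z*)`` with baseline states placed
    below the attractor along the cognitive direction, so the progression
    score rises monotonically through the stage thresholds.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    k = cfg.latent_dim

    # ground-truth geometry: g drives severity upward, cognition declines
    g_dir = rng.normal(size=k)
    g_dir /= np.linalg.norm(g_dir)
    u_star = -g_dir
    attractor = cfg.attractor_score * g_dir
    thresholds = np.asarray(cfg.stage_thresholds, dtype=float)
    if cfg.biomarker_midpoints is None:
        lo, hi = -0.5, cfg.attractor_score * 0.85
        midpoints = np.linspace(lo, hi, cfg.n_regions)
    else:
        midpoints = np.asarray(cfg.biomarker_midpoints, dtype=float)

    # modality loading matrices (baseline features are linear in z(0))
    map_img = rng.normal(0.0, 1.0, size=(cfg.img_dim, k))
    map_omics = rng.normal(0.0, 1.0, size=(cfg.omics_dim, k))
    map_demo = rng.normal(0.0, 1.0, size=(cfg.demo_dim, k))

    graph = default_region_graph(cfg.n_regions, rng)

    subjects: dict[str, Subject] = {}
    true_z0: dict[str, np.ndarray] = {}
    for i in range(cfg.n_subjects):
        sid = f"S{i:04d}"
        # baseline latent: chosen progression score + orthogonal spread
        p0 = rng.uniform(*cfg.baseline_score_range)
        w = rng.normal(0.0, cfg.off_axis_sd, size=k)
        w -= (w @ g_dir) * g_dir
        z0 = p0 * g_dir + w
        true_z0[sid] = z0

        n_visits = int(rng.integers(cfg.visits_min, cfg.visits_max + 1))
        later = np.sort(rng.uniform(0.0, cfg.time_horizon, size=n_visits - 1))
        times = np.concatenate([[0.0], later])
        while np.any(np.diff(times) <= 0):  # measure-zero duplicate guard
            later = np.sort(rng.uniform(0.0, cfg.time_horizon, size=n_visits - 1))
            times = np.concatenate([[0.0], later])

        decay = np.exp(-cfg.drift_rate * times)[:, None]
        z_t = attractor + decay * (z0 - attractor)
        prog = z_t @ g_dir
        y_true = z_t @ u_star + cfg.cognitive_intercept
        y_obs = y_true + rng.normal(0.0, cfg.cognitive_noise_sd, size=len(times))
        stages = (prog[:, None] > thresholds[None, :]).sum(axis=1)
        bio_true = _sigmoid(
            cfg.biomarker_slope * (prog[:, None] - midpoints[None, :])
        )
        bio_obs = bio_true + rng.normal(
            0.0, cfg.biomarker_noise_sd, size=bio_true.shape
        )
        labeled = rng.random(len(times)) < cfg.stage_label_fraction

        block = ModalityBlock(
            imaging=map_img @ z0
            + rng.normal(0.0, cfg.modality_noise_sd, size=cfg.img_dim),
            omics=map_omics @ z0
            + rng.normal(0.0, cfg.modality_noise_sd, size=cfg.omics_dim),
            demographics=map_demo @ z0
            + rng.normal(0.0, cfg.modality_noise_sd, size=cfg.demo_dim),
        )
        visits = [
            ObservationRecord(
                subject_id=sid,
                time=float(t),
                cognitive_score=float(y),
                stage_label=int(s) if lab else None,
                biomarkers=b.copy(),
            )
            for t, y, s, b, lab in zip(times, y_obs, stages, bio_obs, labeled)
        ]
        subjects[sid] = Subject(sid, block, visits)

    cohort = Cohort(
        subjects=subjects,
        stage_count=cfg.stage_count,
        region_graph=graph,
        time_horizon=cfg.time_horizon,
    )

    # population-level reference curves on a uniform knot grid
    knot_t = np.linspace(0.0, cfg.time_horizon, cfg.n_template_knots)
    z0_mat = np.stack(list(true_z0.values()))  # (n, k)
    p0_all = z0_mat @ g_dir  # (n,)
    prog_all = cfg.attractor_score + np.exp(
        -cfg.drift_rate * knot_t
    )[:, None] * (p0_all[None, :] - cfg.attractor_score)  # (knots, n)
    ref_bio = _sigmoid(
        cfg.biomarker_slope * (prog_all[:, :, None] - midpoints[None, None, :])
    ).mean(axis=1)  # (knots, n_bio)
    template = cfg.cognitive_intercept - prog_all.mean(axis=1)

    # stage-conditional mean latents (anchors) from the noiseless truth
    anchor_sum = np.zeros((cfg.stage_count, k))
    anchor_n = np.zeros(cfg.stage_count)
    for sid, subj in subjects.items():
        times = np.array([v.time for v in subj.visits])
        z_t = attractor + np.exp(-cfg.drift_rate * times)[:, None] * (
            true_z0[sid] - attractor
        )
        st = ((z_t @ g_dir)[:, None] > thresholds[None, :]).sum(axis=1)
        for s_lab, z in zip(st, z_t):
            anchor_sum[s_lab] += z
            anchor_n[s_lab] += 1
    anchors = np.where(
        anchor_n[:, None] > 0, anchor_sum / np.maximum(anchor_n, 1)[:, None], 0.0
    )

    truth = GroundTruth(
        true_z0=true_z0,
        attractor=attractor,
        drift_rate=cfg.drift_rate,
        progression_direction=g_dir,
        cognitive_direction=u_star,
        cognitive_intercept=cfg.cognitive_intercept,
        stage_thresholds=thresholds,
        biomarker_midpoints=midpoints,
        biomarker_slope=cfg.biomarker_slope,
        noise_spec={
            "cognitive": cfg.cognitive_noise_sd,
            "biomarker": cfg.biomarker_noise_sd,
            "modality": cfg.modality_noise_sd,
        },
        stage_anchors=anchors,
        reference_curve_times=knot_t,
        reference_biomarker_curves=ref_bio,
        cognitive_template=template,
    )
    return cohort, truth


def inject_treatment_effect(
    cohort: Cohort,
    ground_truth: GroundTruth,
    effect_size: float,
    onset_quantile: float = 0.4,
    seed: int = 0,
    treated_fraction: float = 0.3,
    treatment_code: str = "A",
) -> Cohort:
    """Shift post-onset cognitive outcomes of a treated subset.

    For each treated subject the onset time is ``t_a = onset_quantile * T``
    and every post-onset cognitive score is shifted by
    ``effect_size * (1 - exp(-(t - t_a)))`` — zero at onset, saturating at
    `effect_size`.  The treatment-event table is populated either way.
    Returns a modified deep copy; the input cohort is untouched.
    """
    if not np.isfinite(effect_size):
        raise ValueError("effect_size must be finite")
    import copy

    out = copy.deepcopy(cohort)
    rng = np.random.default_rng(seed)
    ids = sorted(out.subjects)
    n_treat = int(round(treated_fraction * len(ids)))
    treated = sorted(rng.choice(ids, size=n_treat, replace=False).tolist())
    t_a = onset_quantile * out.time_horizon
    for sid in treated:
        subj = out.subjects[sid]
        ev = TreatmentEvent(sid, treatment_code, float(t_a))
        for v in subj.visits:
            if v.time >= t_a and v.cognitive_score is not None:
                v.cognitive_score += effect_size * (1.0 - np.exp(-(v.time - t_a)))
                ev.post_outcomes.append((v.time, v.cognitive_score))
        subj.treatments.append(ev)
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def truth_to_dict(truth: GroundTruth) -> dict:
    d = dataclasses.asdict(truth)
    d["true_z0"] = {sid: z.tolist() for sid, z in truth.true_z0.items()}
    for key, val in d.items():
        if isinstance(val, np.ndarray):
            d[key] = val.tolist()
    return d


def write_simulation(cohort: Cohort, truth: GroundTruth, out_dir) -> None:
    """Write baseline/visits/treatments CSVs, graph.json and truth.json."""
    out = Path(out_dir)
    save_cohort(cohort, out)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_to_dict(truth), fh, indent=1)
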