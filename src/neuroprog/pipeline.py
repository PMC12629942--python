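"""End-to-end model assembly, composite objective, training and evaluation.

The full model couples, per subject: modality encoders -> initial latent
state and conditioning vector -> fixed-step RK4 integration of the learned
flow field on a dense time grid -> visit-level readouts (memory-augmented
outcome decoder, stage simplex head) plus a graph-attention regional channel
anchored to the latent trajectory.  The training objective is a weighted sum
of the squared-error outcome prediction term and the fourteen alignment /
regularisation terms defined across the library modules; every term is
reported unweighted in the per-epoch history, and terms whose reference data
are absent (no stage labels, no reference curves, no treated subjects, no
manifold basis) contribute exactly zero.

Sum-type terms are normalised by the number of subjects in the batch so the
objective is batch-size independent.  Optimisation is Adam on a flat
parameter dictionary; everything is seeded and bit-for-bit reproducible for
a fixed (config, seed) pair.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats as sp_stats
from sklearn import metrics as sk_metrics

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .cohort import Cohort
from .coherence import (
    CoherenceSpecs,
    PiecewiseCurve,
    TreatmentShift,
    counterfactual_loss,
    manifold_projection_loss,
    quadrature,
)
from .decoding import ContrastiveConfig, MemoryParams, contrastive_loss, decode_output, update_memory
from .dynamics import MLPFlowField, _dense_grid, rk4_path
from .encoders import (
    EncoderParams,
    augment_latent,
    condition_vector,
    encode_baseline,
    initial_latent,
    modality_embeddings,
)
from .nnet import init_linear
from .regional import (
    GraphLayerParams,
    anatomical_projection_penalty,
    propagate_regions,
    sync_regularizer,
)
from .stage_cognition import (
    AnchorSet,
    CognitiveField,
    SoftStageHead,
    ordinal_regularizer,
    stage_probabilities,
)
from .synthetic import GroundTruth

__all__ = [
    "DEFAULT_CONFIG",
    "LossWeights",
    "FitReport",
    "MetricsReport",
    "ProgressionModel",
    "build_model",
    "composite_objective",
    "train",
    "evaluate_stage_metrics",
    "anchor_correlation",
    "monotonicity_violation_mass",
    "coherence_from_truth",
    "merge_config",
]

TERM_NAMES = [
    "prediction", "contrastive", "sync", "anatomical", "stage_kl", "anchor",
    "ordinal", "direction", "monotonicity", "disentangle", "biomarker",
    "template", "consistency", "counterfactual", "projection",
]

DEFAULT_CONFIG: dict = {
    "latent_dim": 4,
    "encoder": {
        "img_widths": [8, 8],
        "omics_widths": [8, 8],
        "demo_widths": [4, 4],
        "cond_dim": 4,
        "activation": "gelu",
    },
    "augment": {"noise_sd": 0.05},
    "dynamics": {"hidden_widths": [16], "step": 0.1, "activation": "tanh"},
    "graph": {"embed_dim": 4, "steps": 6},
    "memory": {"dim": 4},
    "contrastive": {"delta": 1, "tau": 0.5, "literal_denominator": False},
    "weights": {
        "prediction": 1.0, "stage_kl": 1.0,
        "contrastive": 0.1, "sync": 0.1, "anatomical": 0.1, "anchor": 0.1,
        "ordinal": 0.1, "direction": 0.1, "monotonicity": 0.1,
        "disentangle": 0.1, "biomarker": 0.1, "template": 0.1,
        "consistency": 0.1, "counterfactual": 0.1, "projection": 0.1,
    },
    "train": {"epochs": 50, "batch_size": 16, "lr": 1e-2,
              "weight_decay": 0.0, "cognitive_ridge": 0.8},
    "decoder_shares_readout": True,
    "anchors_trainable": True,
}


def merge_config(overrides: Optional[dict]) -> dict:
    """Deep-merge user overrides into the default configuration."""
    def deep(base, over):
        out = dict(base)
        for key, val in (over or {}).items():
            if isinstance(val, dict) and isinstance(out.get(key), dict):
                out[key] = deep(out[key], val)
            else:
                out[key] = val
        return out

    return deep(DEFAULT_CONFIG, overrides)


def config_hash(config: dict) -> str:
    return hashlib.sha1(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


@dataclass
class LossWeights:
    """Nonnegative weight per objective term."""

    values: dict[str, float]

    def __post_init__(self):
        unknown = set(self.values) - set(TERM_NAMES)
        if unknown:
            raise ValueError(f"unknown loss terms: {sorted(unknown)}")
        if any(w < 0 for w in self.values.values()):
            raise ValueError("loss weights must be nonnegative")

    def __getitem__(self, name: str) -> float:
        return float(self.values.get(name, 0.0))


@dataclass
class FitReport:
    history: list[dict]
    seed: int
    config_hash: str
    diverged: bool = False


@dataclass
class MetricsReport:
    accuracy: float
    recall_macro: float
    f1_macro: float
    auc_ovr_macro: float
    confusion: list
    spearman: Optional[float] = None
    mse: Optional[float] = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Cohort -> padded arrays
# ---------------------------------------------------------------------------

class CohortArrays:
    """Padded per-visit arrays for vectorised batch forwards."""

    def __init__(self, cohort: Cohort):
        self.cohort = cohort
        self.ids = sorted(cohort.subjects)
        subs = [cohort.subjects[s] for s in self.ids]
        n = len(subs)
        self.x_img = np.stack([s.baseline.imaging for s in subs])
        self.x_omics = np.stack([s.baseline.omics for s in subs])
        self.x_demo = np.stack([s.baseline.demographics for s in subs])
        self.x_full = np.concatenate(
            [self.x_img, self.x_omics, self.x_demo], axis=1
        )
        v_max = max(len(s.visits) for s in subs)
        self.times = np.zeros((n, v_max))
        self.vmask = np.zeros((n, v_max), dtype=bool)
        self.y = np.zeros((n, v_max))
        self.ymask = np.zeros((n, v_max), dtype=bool)
        self.stage = np.full((n, v_max), -1, dtype=int)
        m = 0
        for s in subs:
            for v in s.visits:
                if v.biomarkers is not None:
                    m = max(m, len(v.biomarkers))
        self.n_bio = m
        self.onset = np.full(n, np.nan)
        self.treat_code: list[Optional[str]] = [None] * n
        self.post_outcomes: list[list] = [[] for _ in range(n)]
        for i, s in enumerate(subs):
            for j, v in enumerate(s.visits):
                self.times[i, j] = v.time
                self.vmask[i, j] = True
                if v.cognitive_score is not None:
                    self.y[i, j] = v.cognitive_score
                    self.ymask[i, j] = True
                if v.stage_label is not None:
                    self.stage[i, j] = v.stage_label
            if s.treatments:
                ev = s.treatments[0]
                self.onset[i] = ev.onset_time
                self.treat_code[i] = ev.treatment_code
                self.post_outcomes[i] = list(ev.post_outcomes)
        self.n_subjects = n
        self.v_max = v_max
        self.horizon = max(cohort.time_horizon, 1e-9)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class ProgressionModel:
    """All trainable components plus the frozen reference material."""

    def __init__(self, config: dict, data: CohortArrays, seed: int,
                 coherence: Optional[CoherenceSpecs] = None,
                 anchors: Optional[np.ndarray] = None):
        cfg = merge_config(config)
        self.config = cfg
        rng = np.random.default_rng(seed)
        k = cfg["latent_dim"]
        self.latent_dim = k
        self.horizon = data.horizon
        self.stage_count = data.cohort.stage_count
        graph = data.cohort.region_graph
        self.graph = graph

        enc = cfg["encoder"]
        self.encoder = EncoderParams.create(
            rng,
            img_dim=data.x_img.shape[1],
            omics_dim=data.x_omics.shape[1],
            demo_dim=data.x_demo.shape[1],
            latent_dim=k,
            img_widths=tuple(enc["img_widths"]),
            omics_widths=tuple(enc["omics_widths"]),
            demo_widths=tuple(enc["demo_widths"]),
            cond_dim=enc["cond_dim"],
            noise_sd=cfg["augment"]["noise_sd"],
            activation=enc["activation"],
        )
        dyn = cfg["dynamics"]
        self.flow = MLPFlowField(
            rng, latent_dim=k, cond_dim=enc["cond_dim"],
            hidden_widths=tuple(dyn["hidden_widths"]), u_dim=1,
            time_scale=self.horizon, activation=dyn["activation"],
        )
        self.step = float(dyn["step"])  # years
        self.grid = _dense_grid(0.0, self.horizon, self.step)

        if graph is not None:
            self.graph_layer = GraphLayerParams.create(
                rng, graph.n_regions, cfg["graph"]["embed_dim"], k
            )
            self.graph_steps = int(cfg["graph"]["steps"])
        else:
            self.graph_layer = None
            self.graph_steps = 0

        self.memory = MemoryParams.create(rng, k, cfg["memory"]["dim"])
        self.stage_head = SoftStageHead.create(rng, self.stage_count, k)
        self.cognitive = CognitiveField.create(rng, k)
        if anchors is not None:
            self.anchor_set = AnchorSet.create(self.stage_count, k,
                                               anchors=np.asarray(anchors))
        else:
            self.anchor_set = AnchorSet.create(self.stage_count, k)
        self.anchors_trainable = bool(cfg["anchors_trainable"]) and anchors is None

        self.decoder_shares_readout = bool(cfg["decoder_shares_readout"])
        self.contrastive = ContrastiveConfig(
            delta=cfg["contrastive"]["delta"],
            tau=cfg["contrastive"]["tau"],
            literal_denominator=cfg["contrastive"]["literal_denominator"],
        )

        spec = coherence if coherence is not None else CoherenceSpecs()
        if spec.biomarker_decoder is None and graph is not None:
            d = cfg["graph"]["embed_dim"]
            lin = init_linear(rng, d, 1)
            spec.biomarker_decoder = {"W": Tensor(lin["W"].value[:, 0]),
                                      "b": Tensor(np.zeros(()))}
        if spec.alignment_map is None:
            micro = enc["omics_widths"][-1]
            macro = enc["img_widths"][-1]
            spec.alignment_map = Tensor(
                rng.normal(0.0, np.sqrt(1.0 / micro), size=(micro, macro))
            )
        codes = {c for c in data.treat_code if c is not None}
        for code in sorted(codes):
            if code not in spec.treatment_shifts:
                spec.treatment_shifts[code] = TreatmentShift.create(k)
        self.coherence = spec

    # -- parameter plumbing ------------------------------------------------

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        out.update(self.encoder.parameters())
        from .nnet import mlp_parameters

        out.update(mlp_parameters(self.flow.mlp, "flow"))
        if self.graph_layer is not None:
            out.update(self.graph_layer.parameters())
        out.update(self.memory.parameters())
        out.update(self.stage_head.parameters())
        out.update(self.cognitive.parameters())
        if self.anchors_trainable:
            out.update(self.anchor_set.parameters())
        if self.coherence.biomarker_decoder is not None:
            out["bio.W"] = self.coherence.biomarker_decoder["W"]
            out["bio.b"] = self.coherence.biomarker_decoder["b"]
        if self.coherence.alignment_map is not None:
            out["align.A"] = self.coherence.alignment_map
        for code, shift in self.coherence.treatment_shifts.items():
            for name, p in shift.parameters().items():
                out[f"{name}.{code}"] = p
        return out

    def state_dict(self) -> dict:
        return {k: v.value.tolist() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict):
        params = self.parameters()
        for key, val in state.items():
            if key in params:
                params[key].value = np.asarray(val, dtype=float).reshape(
                    params[key].value.shape
                )

    def snapshot(self) -> dict:
        return {k: v.value.copy() for k, v in self.parameters().items()}

    def restore(self, snap: dict):
        for k, v in self.parameters().items():
            v.value = snap[k].copy()


def coherence_from_truth(truth: GroundTruth, basis=None) -> CoherenceSpecs:
    """Reference curves / templates built from a simulator's ground truth.

    Population-level biomarker curves become the per-region reference
    trajectories; the population-mean noiseless cognitive curve becomes the
    single subtype template.  The canonical disease manifold is derived from
    the supplied clinical stage anchors: its basis is the ordinal
    progression axis (last anchor minus first, normalised), so latent
    trajectories are softly confined to the clinically meaningful axis.
    Stage anchors themselves are handled separately (model parameters,
    optionally pinned to these priors).
    """
    knots = truth.reference_curve_times
    curves = {
        f"bio_{j}": PiecewiseCurve(knots, truth.reference_biomarker_curves[:, j])
        for j in range(truth.reference_biomarker_curves.shape[1])
    }
    templates = {0: PiecewiseCurve(knots, truth.cognitive_template)}
    if basis is None:
        axis = truth.stage_anchors[-1] - truth.stage_anchors[0]
        norm = np.linalg.norm(axis)
        if norm > 0:
            basis = (axis / norm)[None, :]
    return CoherenceSpecs(
        reference_curves=curves,
        templates=templates,
        manifold_basis=None if basis is None else np.asarray(basis, float),
    )


def build_model(cohort: Cohort, config: Optional[dict], seed: int,
                coherence: Optional[CoherenceSpecs] = None,
                anchors: Optional[np.ndarray] = None,
                ) -> tuple[ProgressionModel, CohortArrays]:
    data = CohortArrays(cohort)
    model = ProgressionModel(config or {}, data, seed,
                             coherence=coherence, anchors=anchors)
    return model, data


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------

def _interp_weights(grid: np.ndarray, t: np.ndarray):
    lo = np.clip(np.searchsorted(grid, t, side="right") - 1, 0, len(grid) - 2)
    frac = (t - grid[lo]) / (grid[lo + 1] - grid[lo])
    return lo, np.clip(frac, 0.0, 1.0)


def _forward_batch(model: ProgressionModel, data: CohortArrays,
                   idx: np.ndarray):
    """Shared trunk: encode, integrate, gather visit latents.

    Returns a dict of tensors/arrays consumed by the objective terms and by
    evaluation.
    """
    x_img = data.x_img[idx]
    x_om = data.x_omics[idx]
    x_dm = data.x_demo[idx]
    h0 = encode_baseline(x_img, x_om, x_dm, model.encoder)
    z0 = initial_latent(h0, model.encoder)
    psi = condition_vector(data.x_full[idx], model.encoder)
    macro, micro = modality_embeddings(x_img, x_om, model.encoder)

    grid = model.grid
    onset = data.onset[idx]  # nan when untreated
    treated = ~np.isnan(onset)

    def u_of(t):
        u = (treated & (t >= np.where(treated, onset, np.inf))).astype(float)
        return u[:, None]

    def f(z, t):
        return model.flow(z, t, psi, u_of(t))

    states = rk4_path(f, z0, grid)
    z_dense = ad.stack(states, axis=0)  # (G, B, k)
    velocities = ad.stack(
        [model.flow(s, t, psi, u_of(t)) for s, t in zip(states, grid)], axis=0
    )

    times = data.times[idx]
    vmask = data.vmask[idx]
    lo, frac = _interp_weights(grid, times)
    b_mat = np.broadcast_to(np.arange(len(idx))[:, None], times.shape)
    z_a = z_dense[lo, b_mat]
    z_b = z_dense[lo + 1, b_mat]
    z_vis = z_a * (1.0 - frac)[..., None] + z_b * frac[..., None]  # (B, V, k)

    return {
        "idx": idx, "z0": z0, "psi": psi, "macro": macro, "micro": micro,
        "z_dense": z_dense, "velocities": velocities, "grid": grid,
        "z_vis": z_vis, "times": times, "vmask": vmask,
        "onset": onset, "treated": treated,
    }


def _visit_predictions(model: ProgressionModel, fwd: dict):
    """Memory recurrence over visits; returns (B, V) predicted outcomes."""
    z_vis, vmask = fwd["z_vis"], fwd["vmask"]
    n, v_max = vmask.shape
    memory = Tensor(model.memory.initial_memory((n,)))
    preds = []
    for j in range(v_max):
        z_j = z_vis[:, j, :]
        new_mem = update_memory(memory, z_j, model.memory)
        keep = vmask[:, j].astype(float)[:, None]
        memory = keep * new_mem + (1.0 - keep) * memory
        head = model.cognitive if model.decoder_shares_readout else None
        preds.append(decode_output(z_j, memory, model.memory,
                                   observation_head=head))
    return ad.stack(preds, axis=1)  # (B, V)


def _contrastive_batched(model: ProgressionModel, z_vis, vmask, idx, seed: int):
    """Vectorised temporal InfoNCE identical in math and negative sampling
    to :func:`neuroprog.decoding.contrastive_loss` with subject-id keys
    (asserted equivalent in the test suite)."""
    delta = model.contrastive.delta
    n_v = vmask.sum(axis=1)
    valid = np.nonzero(n_v >= delta + 1)[0]
    if len(valid) < 2:
        return 0.0

    # seeded, per-subject latent augmentation (gate + Gaussian perturbation)
    noise = np.zeros(ad.value_of(z_vis).shape)
    sd = model.encoder.noise_sd
    if sd > 0:
        for b in valid:
            rng_b = np.random.default_rng(int((seed * 1009 + idx[b]) % (2**31)))
            noise[b] = rng_b.normal(0.0, sd, size=noise[b].shape)
    z_aug = z_vis + model.encoder.gate * ad.tanh(z_vis) + noise

    b_a, t_a, b_neg, t_neg = [], [], [], []
    for i in valid:
        others = [j for j in valid if j != i]
        for t in range(int(n_v[i]) - delta):
            b_a.append(i)
            t_a.append(t)
            row_b, row_t = [], []
            for j in others:
                rng_n = np.random.default_rng(
                    [seed, int(idx[i]), int(idx[j]), t]
                )
                row_b.append(j)
                row_t.append(int(rng_n.integers(int(n_v[j]))))
            b_neg.append(row_b)
            t_neg.append(row_t)
    b_a = np.array(b_a)
    t_a = np.array(t_a)
    b_neg = np.array(b_neg)
    t_neg = np.array(t_neg)

    from .regional import cosine_similarity

    k = model.latent_dim
    anchor = z_aug[b_a, t_a]                      # (Na, k)
    pos = z_aug[b_a, t_a + delta]                 # (Na, k)
    neg = z_aug[b_neg, t_neg]                     # (Na, m-1, k)
    inv_tau = 1.0 / model.contrastive.tau
    s_pos = cosine_similarity(anchor, pos) * inv_tau
    s_neg = cosine_similarity(anchor.reshape(-1, 1, k), neg) * inv_tau
    e_pos = ad.exp(s_pos)
    denom = ad.asum(ad.exp(s_neg), axis=-1)
    if not model.contrastive.literal_denominator:
        denom = denom + e_pos
    return ad.amean(ad.log(denom) - s_pos)


# ---------------------------------------------------------------------------
# Composite objective
# ---------------------------------------------------------------------------

def composite_objective(model: ProgressionModel, data: CohortArrays,
                        idx, weights: LossWeights, seed: int = 0):
    """Total training loss on a batch plus the unweighted per-term breakdown.

    ``idx`` indexes subjects in `data`.  Terms without reference data in
    the batch contribute exactly 0.  Raises if any term goes non-finite,
    naming the term.
    """
    idx = np.asarray(idx, dtype=int)
    n_b = len(idx)
    fwd = _forward_batch(model, data, idx)
    z_vis, vmask = fwd["z_vis"], fwd["vmask"]
    terms: dict[str, object] = {}

    # outcome prediction (y-hat vs observed cognitive score)
    y = data.y[idx]
    ymask = data.ymask[idx] & vmask
    preds = _visit_predictions(model, fwd)
    if ymask.any():
        resid = (preds - y) * ymask.astype(float)
        terms["prediction"] = ad.asum(resid * resid) / ymask.sum()
    else:
        terms["prediction"] = 0.0

    # stage supervision on the simplex head
    stage = data.stage[idx]
    smask = (stage >= 0) & vmask
    probs = stage_probabilities(z_vis, model.stage_head)  # (B, V, L+1)
    if smask.any():
        b_i, v_i = np.nonzero(smask)
        p_true = probs[b_i, v_i, stage[b_i, v_i]]
        p_val = ad.value_of(p_true)
        if np.any(p_val <= 0):
            raise FloatingPointError("stage probabilities underflowed to zero")
        terms["stage_kl"] = -ad.asum(ad.log(p_true)) / smask.sum()
        mu = model.anchor_set.anchors[stage[b_i, v_i]]
        diff = z_vis[b_i, v_i] - mu
        terms["anchor"] = ad.asum(diff * diff) / smask.sum()
    else:
        terms["stage_kl"] = 0.0
        terms["anchor"] = 0.0

    terms["ordinal"] = ordinal_regularizer(model.anchor_set) \
        if model.stage_count > 1 else 0.0

    # monotonicity of non-baseline stage probabilities between visits
    pair_mask = vmask[:, 1:] & vmask[:, :-1]
    if pair_mask.any() and model.stage_count > 1:
        delta = probs[:, 1:, 1:] - probs[:, :-1, 1:]
        viol = ad.relu(-delta) * pair_mask.astype(float)[..., None]
        terms["monotonicity"] = ad.asum(viol) / n_b
    else:
        terms["monotonicity"] = 0.0

    # cognitive-field direction: trajectories must descend the field
    inner = ad.asum(fwd["velocities"] * model.cognitive.direction, axis=-1)
    terms["direction"] = ad.amean(ad.relu(inner))

    # temporal contrastive over per-subject visit sequences (vectorised
    # evaluation of the same objective/sampling as `contrastive_loss`)
    terms["contrastive"] = _contrastive_batched(model, z_vis, vmask, idx, seed)

    # subject-level disentanglement: last labeled visit vs its stage
    reps, labels = [], []
    for b in range(n_b):
        lab = np.nonzero(smask[b])[0]
        if len(lab):
            reps.append(z_vis[b, lab[-1], :])
            labels.append(stage[b, lab[-1]])
    dis = 0.0
    labels_arr = np.asarray(labels)
    for i in range(len(reps)):
        for j in range(len(reps)):
            if i == j or labels_arr[i] == labels_arr[j]:
                continue
            diff = reps[i] - reps[j]
            dis = dis + ad.exp(-ad.asum(diff * diff))
    terms["disentangle"] = dis / n_b if len(reps) > 1 else 0.0

    # regional channel: sync / anatomical / biomarker
    if model.graph_layer is not None and model.graph_steps > 0:
        rg_times = np.linspace(0.0, model.horizon, model.graph_steps + 1)
        lo, frac = _interp_weights(fwd["grid"], rg_times)
        z_rg = [
            fwd["z_dense"][lo[s]] * (1.0 - frac[s])
            + fwd["z_dense"][lo[s] + 1] * frac[s]
            for s in range(len(rg_times))
        ]  # list of (B, k)
        kernel = model.graph.kernel
        r = model.graph_layer.project_latent(z_rg[0])  # (B, R, d)
        sync_total = sync_regularizer(r, kernel)
        anat_total = 0.0
        r_states = [r]
        for s in range(1, len(rg_times)):
            r = propagate_regions(r, model.graph, model.graph_layer)
            sync_total = sync_total + sync_regularizer(r, kernel)
            anat_total = anat_total + anatomical_projection_penalty(
                r, z_rg[s], model.graph_layer
            )
            r_states.append(r)
        n_states = len(r_states)
        terms["sync"] = sync_total / (n_b * n_states)
        terms["anatomical"] = anat_total / (n_b * max(n_states - 1, 1))

        if data.n_bio and model.coherence.reference_curves:
            bio_total = 0.0
            names = sorted(model.coherence.reference_curves)
            r_stack = ad.stack(r_states, axis=0)  # (S+1, B, R, d)
            for v, name in enumerate(names[: model.graph.n_regions]):
                pred = model.coherence.decode_biomarker(r_stack[:, :, v, :])
                target = model.coherence.reference_curves[name](rg_times)
                resid = pred - target[:, None]
                bio_total = bio_total + quadrature(resid * resid, rg_times)
            terms["biomarker"] = bio_total / n_b
        else:
            terms["biomarker"] = 0.0
    else:
        terms["sync"] = terms["anatomical"] = terms["biomarker"] = 0.0

    # subtype template alignment of the cognitive readout
    if model.coherence.templates:
        template = model.coherence.templates[0]
        readout = model.cognitive.readout(fwd["z_dense"])  # (G, B)
        resid = readout - template(fwd["grid"])[:, None]
        terms["template"] = quadrature(resid * resid, fwd["grid"]) / n_b
    else:
        terms["template"] = 0.0

    # cross-modality consistency
    if model.coherence.alignment_map is not None:
        diff = fwd["macro"] - fwd["micro"] @ model.coherence.alignment_map
        terms["consistency"] = ad.asum(diff * diff) / n_b
    else:
        terms["consistency"] = 0.0

    # counterfactual coherence for treated subjects
    cf_total, n_cf = 0.0, 0
    for b in np.nonzero(fwd["treated"])[0]:
        gi = int(idx[b])
        outcomes = data.post_outcomes[gi]
        if not outcomes:
            continue
        code = data.treat_code[gi]
        shift = model.coherence.treatment_shifts[code]
        cf_total = cf_total + counterfactual_loss(
            fwd["z_dense"][:, b, :], fwd["grid"], float(fwd["onset"][b]),
            outcomes, shift, model.cognitive,
        )
        n_cf += 1
    terms["counterfactual"] = cf_total / n_cf if n_cf else 0.0

    # canonical manifold projection
    if model.coherence.manifold_basis is not None:
        flat = fwd["z_dense"].reshape(-1, model.latent_dim)
        terms["projection"] = manifold_projection_loss(
            flat, model.coherence.manifold_basis
        ) / n_b
    else:
        terms["projection"] = 0.0

    total = Tensor(np.zeros(()))
    breakdown = {}
    for name in TERM_NAMES:
        term = terms[name]
        val = float(ad.value_of(term))
        if not np.isfinite(val):
            raise FloatingPointError(f"objective term '{name}' is non-finite")
        breakdown[name] = val
        w = weights[name]
        if w != 0.0 and isinstance(term, Tensor):
            total = total + w * term
        elif w != 0.0:
            total = total + Tensor(np.asarray(w * val))
    return total, breakdown


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def train(cohort: Cohort, config: Optional[dict] = None, seed: int = 0,
          coherence: Optional[CoherenceSpecs] = None,
          anchors: Optional[np.ndarray] = None,
          ) -> tuple[FitReport, ProgressionModel]:
    """Fit the full model on a cohort; deterministic for fixed seed/config.

    Returns the per-epoch unweighted loss history (every term plus the
    weighted total) and the fitted model.  On divergence the parameters are
    rolled back to the last finite epoch and the report is flagged.
    """
    cfg = merge_config(config)
    model, data = build_model(cohort, cfg, seed, coherence=coherence,
                              anchors=anchors)
    weights = LossWeights(dict(cfg["weights"]))
    tr = cfg["train"]
    epochs, batch_size = int(tr["epochs"]), int(tr["batch_size"])
    wd = {k: float(tr.get("weight_decay", 0.0)) for k in model.parameters()}
    # ridge shrinkage on the cognitive-field direction: its components along
    # collapsed latent axes are under-determined and must decay, not freeze
    wd["cog.u"] = wd.get("cog.u", 0.0) + float(tr.get("cognitive_ridge", 0.0))
    optimiser = Adam(model.parameters(), lr=float(tr["lr"]), weight_decay=wd)
    rng = np.random.default_rng(seed)

    history: list[dict] = []
    diverged = False
    for epoch in range(epochs):
        order = rng.permutation(data.n_subjects)
        snap = model.snapshot()
        epoch_terms = {name: 0.0 for name in TERM_NAMES}
        epoch_total, n_batches = 0.0, 0
        try:
            for start in range(0, data.n_subjects, batch_size):
                idx = order[start: start + batch_size]
                if len(idx) < 2:
                    continue
                batch_seed = int((seed * 100003 + epoch * 1009 + start) % (2**31))
                optimiser.zero_grad()
                total, breakdown = composite_objective(
                    model, data, idx, weights, seed=batch_seed
                )
                total.backward()
                optimiser.step()
                for name, val in breakdown.items():
                    epoch_terms[name] += val
                epoch_total += float(total.value)
                n_batches += 1
        except FloatingPointError:
            model.restore(snap)
            diverged = True
            break
        record = {name: val / max(n_batches, 1)
                  for name, val in epoch_terms.items()}
        record["total"] = epoch_total / max(n_batches, 1)
        history.append(record)

    report = FitReport(history=history, seed=seed,
                       config_hash=config_hash(cfg), diverged=diverged)
    return report, model


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def predict_visits(model: ProgressionModel, cohort: Cohort) -> dict:
    """Numpy per-visit predictions for a whole cohort (no gradients kept)."""
    data = CohortArrays(cohort)
    idx = np.arange(data.n_subjects)
    fwd = _forward_batch(model, data, idx)
    preds = ad.value_of(_visit_predictions(model, fwd))
    probs = ad.value_of(stage_probabilities(fwd["z_vis"], model.stage_head))
    z_vis = ad.value_of(fwd["z_vis"])
    return {
        "data": data, "vmask": data.vmask, "times": data.times,
        "y": data.y, "ymask": data.ymask, "stage": data.stage,
        "pred": preds, "probs": probs, "z_vis": z_vis,
    }


def evaluate_stage_metrics(model: ProgressionModel, cohort: Cohort,
                           ) -> MetricsReport:
    """Visit-level stage classification metrics (macro-averaged).

    Hard predictions come from the argmax stage head sharing the simplex
    head's weights; AUC is one-vs-rest, macro-averaged over the stages
    actually present with both positives and negatives.
    """
    out = predict_visits(model, cohort)
    mask = (out["stage"] >= 0) & out["vmask"]
    if not mask.any():
        raise ValueError("cohort has no stage labels to evaluate")
    y_true = out["stage"][mask]
    probs = out["probs"][mask]
    hard = model.stage_head.to_hard_head()
    from .decoding import classify_stage

    y_pred = classify_stage(out["z_vis"][mask], hard)
    labels = list(range(model.stage_count))
    acc = sk_metrics.accuracy_score(y_true, y_pred)
    rec = sk_metrics.recall_score(y_true, y_pred, labels=labels,
                                  average="macro", zero_division=0)
    f1 = sk_metrics.f1_score(y_true, y_pred, labels=labels,
                             average="macro", zero_division=0)
    aucs = []
    for lab in labels:
        pos = y_true == lab
        if pos.any() and (~pos).any():
            aucs.append(sk_metrics.roc_auc_score(pos, probs[:, lab]))
    auc = float(np.mean(aucs)) if aucs else float("nan")
    conf = sk_metrics.confusion_matrix(y_true, y_pred, labels=labels)
    return MetricsReport(
        accuracy=float(acc), recall_macro=float(rec), f1_macro=float(f1),
        auc_ovr_macro=auc, confusion=conf.tolist(),
    )


def anchor_correlation(model: ProgressionModel, cohort: Cohort,
                       anchor_values: dict[str, np.ndarray],
                       ) -> tuple[float, float]:
    """Spearman rho (average-rank ties) and MSE of the predicted cognitive
    readout against per-visit anchor-variable values.

    `anchor_values` maps subject id -> per-visit values aligned with that
    subject's visit order.
    """
    out = predict_visits(model, cohort)
    data: CohortArrays = out["data"]
    pred_list, target_list = [], []
    for i, sid in enumerate(data.ids):
        if sid not in anchor_values:
            continue
        vals = np.asarray(anchor_values[sid], dtype=float)
        n_v = int(data.vmask[i].sum())
        if len(vals) != n_v:
            raise ValueError(f"anchor values for {sid} misaligned with visits")
        pred_list.append(out["pred"][i, :n_v])
        target_list.append(vals)
    pred = np.concatenate(pred_list) if pred_list else np.empty(0)
    target = np.concatenate(target_list) if target_list else np.empty(0)
    if len(pred) < 3:
        raise ValueError("anchor correlation needs >= 3 visit values")
    rho = sp_stats.spearmanr(pred, target).statistic
    mse = float(np.mean((pred - target) ** 2))
    return float(rho), mse


def run_recovery_experiment(seed: int = 42, sim_overrides: Optional[dict] = None,
                            config_overrides: Optional[dict] = None,
                            cohort_seed: int = 42) -> dict:
    """Ground-truth recovery on a synthetic cohort.

    Generates the default synthetic cohort (the study conditions fix its
    seed; `cohort_seed` overrides), trains with the alignment constraints
    enabled (stage anchors pinned to the cohort's archetypal stage latents,
    i.e. supplied clinical priors) under training randomness driven by
    `seed`, and scores on held-out subjects: cosine alignment of the fitted
    cognitive direction with the generator's, stage macro-F1, and Spearman
    correlation of the predicted cognitive readout with the true noiseless
    cognitive score.
    """
    from .cohort import split_cohort
    from .synthetic import SimConfig, generate_cohort

    sim_cfg = SimConfig(**(sim_overrides or {}))
    cohort, truth = generate_cohort(sim_cfg, cohort_seed)
    train_c, _val_c, test_c = split_cohort(cohort, (0.8, 0.1, 0.1), cohort_seed)
    coherence = coherence_from_truth(truth)
    report, model = train(train_c, config_overrides, seed,
                          coherence=coherence, anchors=truth.stage_anchors)

    metrics = evaluate_stage_metrics(model, test_c)
    u_fit = model.cognitive.direction.value
    u_true = truth.cognitive_direction
    cosine = float(
        u_fit @ u_true / (np.linalg.norm(u_fit) * np.linalg.norm(u_true) + 1e-12)
    )
    test_data = CohortArrays(test_c)
    anchor_vals = {
        sid: truth.noiseless_cognitive(
            sid, [v.time for v in test_c.subjects[sid].visits]
        )
        for sid in test_data.ids
    }
    rho, mse = anchor_correlation(model, test_c, anchor_vals)
    return {
        "cosine_u": cosine,
        "abs_cosine_u": abs(cosine),
        "f1_macro": metrics.f1_macro,
        "accuracy": metrics.accuracy,
        "auc": metrics.auc_ovr_macro,
        "spearman": float(rho),
        "mse": float(mse),
        "report": report,
        "model": model,
        "truth": truth,
        "test_cohort": test_c,
    }


def run_dose_response(seed: int = 0, mono_weights=(0.0, 1.0, 10.0),
                      n_subjects: int = 120, epochs: int = 30) -> list[float]:
    """Held-out monotonicity-violation mass across monotonicity weights.

    Trains one model per weight with everything else fixed (same cohort,
    split, seeds, other weights) and returns the violation masses in the
    order of `mono_weights`.  Increasing the weight should not increase the
    held-out violation mass.
    """
    from .cohort import split_cohort
    from .synthetic import SimConfig, generate_cohort

    cohort, truth = generate_cohort(SimConfig(n_subjects=n_subjects), seed)
    train_c, _val, test_c = split_cohort(cohort, (0.8, 0.1, 0.1), seed)
    masses = []
    for w in mono_weights:
        coherence = coherence_from_truth(truth)
        cfg = {"weights": {"monotonicity": float(w)},
               "train": {"epochs": epochs}}
        _report, model = train(train_c, cfg, seed, coherence=coherence,
                               anchors=truth.stage_anchors)
        masses.append(monotonicity_violation_mass(model, test_c))
    return masses


def monotonicity_violation_mass(model: ProgressionModel, cohort: Cohort,
                                ) -> float:
    """Mean per-subject mass of decreases in non-baseline stage
    probabilities between consecutive visits (the dose the monotonicity
    weight is meant to suppress)."""
    out = predict_visits(model, cohort)
    probs, vmask = out["probs"], out["vmask"]
    pair = vmask[:, 1:] & vmask[:, :-1]
    delta = probs[:, 1:, 1:] - probs[:, :-1, 1:]
    viol = np.maximum(-delta, 0.0) * pair[..., None]
    return float(viol.sum() / probs.shape[0])
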