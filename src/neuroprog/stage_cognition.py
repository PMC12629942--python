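"""Stage-aware latent supervision and cognition-guided regularisers.

This is the first half of the clinical-alignment constraint suite: it ties
the latent space to ordinal stage annotations and to cognitive scores.

* soft stage head — softmax(W z + b) onto the probability simplex over the
  L+1 stages, supervised with KL divergence against the one-hot true stage
  (equivalently cross-entropy, -log p[true]);
* anchor geometry — archetypal latent vectors mu_0..mu_L per stage pull
  labeled latents toward their stage anchor, while an ordinal regulariser
  keeps consecutive anchors evenly spaced along a shift vector delta;
* cognitive field — a linear map C(z) = u.z + c predicting the cognitive
  score; the direction penalty is a hinge on <dz/dt, u>, the differentiable
  surrogate of the requirement that trajectories descend the cognitive
  field (the underlying constraint is a strict inequality, not a loss);
* monotonicity — predicted probabilities of the non-baseline stages
  (l >= 1) must not decrease between consecutive visits; violations are
  penalised by their mass;
* disentanglement — different-label latent pairs are pushed apart by a
  Gaussian kernel exp(-||z_i - z_j||^2) on the squared distance.  Intra-
  class compactness is delegated to the anchor term; an accompanying
  semantic codebook can be stored for interpretation but does not enter the
  penalty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "SoftStageHead",
    "AnchorSet",
    "CognitiveField",
    "SemanticCodebook",
    "stage_probabilities",
    "stage_kl_loss",
    "anchor_loss",
    "ordinal_regularizer",
    "cognitive_direction_penalty",
    "monotonicity_penalty",
    "disentangle_penalty",
]

KL_CAP = 1e3  # cap on -log p[true] when the predicted probability underflows


@dataclass
class SoftStageHead:
    """Simplex projection parameters W ((L+1) x k) and b (L+1)."""

    weight: Tensor
    bias: Tensor

    @classmethod
    def create(cls, rng: np.random.Generator, stage_count: int,
               latent_dim: int) -> "SoftStageHead":
        scale = np.sqrt(2.0 / (latent_dim + stage_count))
        return cls(
            weight=Tensor(rng.normal(0.0, scale, size=(stage_count, latent_dim))),
            bias=Tensor(np.zeros(stage_count)),
        )

    def parameters(self) -> dict[str, Tensor]:
        return {"stage.W": self.weight, "stage.b": self.bias}

    def to_hard_head(self):
        """Share weights with the hard argmax classifier (omega_l, nu_l)."""
        from .decoding import HardStageHead

        return HardStageHead(self.weight.value.copy(), self.bias.value.copy())


@dataclass
class AnchorSet:
    """Stage anchors mu_0..mu_L and the ordinal shift vector delta."""

    anchors: Tensor  # (L+1, k)
    shift: Tensor    # (k,)

    @classmethod
    def create(cls, stage_count: int, latent_dim: int,
               anchors: np.ndarray | None = None,
               shift: np.ndarray | None = None) -> "AnchorSet":
        if anchors is None:
            anchors = np.zeros((stage_count, latent_dim))
        if shift is None:
            shift = np.zeros(latent_dim)
        return cls(Tensor(np.asarray(anchors, float)),
                   Tensor(np.asarray(shift, float)))

    def parameters(self) -> dict[str, Tensor]:
        return {"anchors.mu": self.anchors, "anchors.shift": self.shift}


@dataclass
class CognitiveField:
    """Linear cognitive field C(z) = u . z + c."""

    direction: Tensor  # u, (k,)
    intercept: Tensor  # c, scalar

    @classmethod
    def create(cls, rng: np.random.Generator, latent_dim: int) -> "CognitiveField":
        # zero init: the direction grows only along latent axes that carry a
        # persistent cognitive gradient, not along the initial transient
        return cls(
            direction=Tensor(np.zeros(latent_dim)),
            intercept=Tensor(np.zeros(())),
        )

    def parameters(self) -> dict[str, Tensor]:
        return {"cog.u": self.direction, "cog.c": self.intercept}

    def readout(self, z):
        """Predicted cognitive score; z may be (k,) or batched (..., k)."""
        return ad.asum(z * self.direction, axis=-1) + self.intercept


@dataclass
class SemanticCodebook:
    """Code vectors zeta_1..zeta_M with per-subject symbolic labels.

    Stored for interpretation only: the disentanglement penalty uses just
    the labels, never the code vectors.
    """

    codes: np.ndarray
    labels: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def stage_probabilities(z, head: SoftStageHead):
    """softmax(W z + b): a point on the stage probability simplex.

    z may be a single latent (k,) -> (L+1,), or batched (n, k) -> (n, L+1).
    """
    logits = z @ head.weight.T + head.bias
    return ad.softmax(logits, axis=-1)


def stage_kl_loss(probabilities, true_stage: int):
    """KL(one-hot(true) || p) = -log p[true] (0 log 0 taken as 0).

    Exact zeros in p[true] are capped at ``KL_CAP`` with a warning rather
    than propagating infinities.
    """
    p_true = probabilities[..., int(true_stage)]
    p_val = ad.value_of(p_true)
    if np.any(p_val <= 0):
        warnings.warn("stage probability underflow; KL capped", RuntimeWarning)
        safe = np.where(p_val > 0, p_val, 1.0)
        return np.minimum(np.where(p_val > 0, -np.log(safe), KL_CAP), KL_CAP)
    return -ad.log(p_true)


def anchor_loss(latents, true_stages, anchor_set: AnchorSet):
    """sum_i ||z_i - mu_{s_i}||^2 over stage-labeled instances.

    `true_stages` may contain None / negative entries for unlabeled
    instances; those contribute exactly 0.
    """
    stages = np.array(
        [-1 if s is None else int(s) for s in np.atleast_1d(true_stages)]
    )
    labeled = np.nonzero(stages >= 0)[0]
    if len(labeled) == 0:
        return 0.0
    z_sel = latents[labeled] if ad.is_tensor(latents) else np.atleast_2d(latents)[labeled]
    mu_sel = anchor_set.anchors[stages[labeled]]
    diff = z_sel - mu_sel
    return ad.asum(diff * diff)


def ordinal_regularizer(anchor_set: AnchorSet):
    """sum_{s=1..L} ||mu_s - mu_{s-1} - delta||^2 — even ordinal spacing."""
    n_stages = ad.value_of(anchor_set.anchors).shape[0]
    if n_stages < 2:
        warnings.warn("ordinal regulariser undefined for a single stage",
                      RuntimeWarning)
        return 0.0
    steps = anchor_set.anchors[1:] - anchor_set.anchors[:-1] - anchor_set.shift
    return ad.asum(steps * steps)


def cognitive_direction_penalty(velocities, field: CognitiveField):
    """mean over grid points of max(0, <dz/dt, u>).

    Since C is linear its gradient is u everywhere, so descent of the
    cognitive field means <dz/dt, u> <= 0; positive parts are penalised.
    `velocities` holds dz/dt at trajectory grid points, shape (..., k).
    """
    inner = ad.asum(velocities * field.direction, axis=-1)
    return ad.amean(ad.relu(inner))


def monotonicity_penalty(probability_series, dt_weights=None):
    """Mass of decreases in the non-baseline stage probabilities.

    `probability_series` is (T, L+1) stage probabilities at consecutive
    observed visits (T >= 2).  Stage 0 is excluded: only stages l >= 1 are
    required to be nondecreasing.  Optional `dt_weights` are ignored for
    the mass itself (the penalty sums raw decreases between consecutive
    visits, whatever their spacing).
    """
    if ad.value_of(probability_series).shape[0] < 2:
        raise ValueError("monotonicity penalty needs >= 2 time points")
    delta = probability_series[1:] - probability_series[:-1]
    return ad.asum(ad.relu(-delta[..., 1:]))


def disentangle_penalty(latents, labels):
    """sum over ordered pairs with different labels of exp(-||z_i - z_j||^2)."""
    labels = np.asarray(labels)
    n = len(labels)
    total = 0.0
    any_pair = False
    for i in range(n):
        for j in range(n):
            if i == j or labels[i] == labels[j]:
                continue
            any_pair = True
            diff = latents[i] - latents[j]
            total = total + ad.exp(-ad.asum(diff * diff))
    return total if any_pair else 0.0
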