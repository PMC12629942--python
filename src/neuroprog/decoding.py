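"""Memory-augmented decoding, hard stage classification, contrastive loss.

A per-subject memory vector accumulates temporal context through a gated
convex recurrence ``M' = (1 - g) * M + g * phi_m(z)`` (gate in (0,1), so the
update is a contraction toward ``phi_m(z)`` for fixed z).  The visit-level
outcome predictor decodes ``(z, M)`` jointly; by default it decomposes as
the persistent cognitive readout ``O(z) = u.z + c`` plus a learned linear
memory correction, so outcome supervision also trains the cognitive field.

Stage classification is a linear argmax head over the latent state; ties
break toward the *lowest* stage index (clinical conservatism).  The
temporal contrastive objective is an InfoNCE-style softmax over cosine
similarities: the positive pair is the same subject at a fixed index offset
``delta``; negatives are one random visit from each other subject in the
batch.  The positive term is included in the denominator so the loss is
bounded below by zero and the all-similar symmetric case equals ``ln(n)``;
a literal variant whose denominator contains only negatives is available
behind ``literal_denominator``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nnet import init_linear
from .regional import cosine_similarity

__all__ = [
    "MemoryParams",
    "HardStageHead",
    "ContrastiveConfig",
    "update_memory",
    "decode_output",
    "classify_stage",
    "contrastive_loss",
]


@dataclass
class MemoryParams:
    """Gate and candidate maps of the memory recurrence, plus the decoder.

    The decoder D(z, M) = w_z . z + w_M . M + b is its own head, distinct
    from the persistent cognitive readout O used by the coherence terms.
    """

    gate_map: dict      # linear z -> d_m, squashed to (0,1)
    cand_map: dict      # phi_m: linear z -> d_m
    z_readout: Tensor    # (k,) decoder weights on the latent state
    mem_readout: Tensor  # (d_m,) decoder weights on M
    readout_bias: Tensor  # scalar decoder bias
    memory_dim: int = 4

    @classmethod
    def create(cls, rng: np.random.Generator, latent_dim: int,
               memory_dim: int = 4) -> "MemoryParams":
        return cls(
            gate_map=init_linear(rng, latent_dim, memory_dim),
            cand_map=init_linear(rng, latent_dim, memory_dim),
            z_readout=Tensor(np.zeros(latent_dim)),
            mem_readout=Tensor(np.zeros(memory_dim)),
            readout_bias=Tensor(np.zeros(())),
            memory_dim=memory_dim,
        )

    def parameters(self) -> dict[str, Tensor]:
        return {
            "mem.gate.W": self.gate_map["W"], "mem.gate.b": self.gate_map["b"],
            "mem.cand.W": self.cand_map["W"], "mem.cand.b": self.cand_map["b"],
            "mem.zread": self.z_readout,
            "mem.readout": self.mem_readout, "mem.bias": self.readout_bias,
        }

    def initial_memory(self, batch_shape=()):
        return np.zeros((*batch_shape, self.memory_dim))


def update_memory(memory, z, params: MemoryParams, gate_override=None):
    """Gated convex update M' = (1-g) * M + g * phi_m(z).

    ``gate_override`` pins the gate to a constant (diagnostics/tests);
    otherwise g = sigmoid of a linear map of z, elementwise in (0, 1).
    """
    if gate_override is not None:
        g = gate_override
    else:
        g = ad.sigmoid(z @ params.gate_map["W"] + params.gate_map["b"])
    cand = z @ params.cand_map["W"] + params.cand_map["b"]
    return (1.0 - g) * memory + g * cand


def decode_output(z, memory, params: MemoryParams, observation_head=None):
    """Visit-level predicted outcome from (z, M); deterministic.

    With `observation_head` (the persistent cognitive readout O, exposing
    ``readout(z)``) the prediction is ``O(z) + w_M . M + b`` — the
    observation model plus a memory-borne temporal correction.  Without it
    the latent pathway uses the decoder's own weights: ``w_z . z +
    w_M . M + b``.
    """
    pred = (ad.asum(memory * params.mem_readout, axis=-1)
            + params.readout_bias)
    if observation_head is not None:
        return pred + observation_head.readout(z)
    return pred + ad.asum(z * params.z_readout, axis=-1)


@dataclass
class HardStageHead:
    """Per-stage linear scores omega_l . z + nu_l, argmax with low-stage ties."""

    weights: np.ndarray  # (L+1, k)
    biases: np.ndarray   # (L+1,)

    def __post_init__(self):
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        self.biases = np.asarray(self.biases, dtype=float)
        if self.weights.shape[0] != self.biases.shape[0]:
            raise ValueError("stage head needs one bias per stage row")


def classify_stage(z, head: HardStageHead) -> np.ndarray:
    """argmax_l omega_l . z + nu_l; ties broken toward the lowest stage.

    Accepts a single latent vector (returns int) or a (batch, k) matrix
    (returns int array).
    """
    z = np.asarray(ad.value_of(z), dtype=float)
    scores = z @ head.weights.T + head.biases
    # np.argmax already returns the first (lowest) index among exact ties
    out = np.argmax(scores, axis=-1)
    return int(out) if out.ndim == 0 else out


@dataclass
class ContrastiveConfig:
    delta: int = 1          # temporal index offset of the positive pair
    tau: float = 0.5        # softmax temperature
    literal_denominator: bool = False  # negatives-only denominator variant

    def __post_init__(self):
        if self.delta < 1:
            raise ValueError("temporal offset delta must be >= 1")
        if self.tau <= 0:
            raise ValueError("temperature tau must be > 0")


def contrastive_loss(latent_batch, config: ContrastiveConfig, seed: int = 0,
                     keys=None):
    """Temporal InfoNCE over a batch of per-subject latent trajectories.

    `latent_batch` is a list of per-subject state sequences (arrays or
    tensors of shape (n_i, k), n_i >= delta + 1).  For every subject and
    every anchor index t, the positive is the same subject at ``t + delta``;
    negatives are one uniformly drawn (seeded) visit from each other
    subject.  Returns the mean over anchors of

        -log exp(s_pos / tau) / (exp(s_pos / tau) + sum_j exp(s_neg_j / tau))

    (positive included in the denominator unless ``literal_denominator``).

    `keys` optionally gives a stable integer identity per subject; negative
    draws are then a function of (seed, anchor key, negative key, t) so the
    loss is invariant to the order of subjects in the batch.
    """
    n_subj = len(latent_batch)
    if n_subj < 2:
        raise ValueError("contrastive loss needs >= 2 subjects (no negatives)")
    for seq in latent_batch:
        if ad.value_of(seq).shape[0] < config.delta + 1:
            raise ValueError(
                f"every trajectory needs >= {config.delta + 1} states"
            )
    if keys is None:
        keys = list(range(n_subj))
    inv_tau = 1.0 / config.tau
    terms = []
    for i, seq in enumerate(latent_batch):
        n_i = ad.value_of(seq).shape[0]
        for t in range(n_i - config.delta):
            anchor = seq[t]
            s_pos = cosine_similarity(anchor, seq[t + config.delta])
            exps = [] if config.literal_denominator else [ad.exp(s_pos * inv_tau)]
            for j, other in enumerate(latent_batch):
                if j == i:
                    continue
                rng = np.random.default_rng([seed, keys[i], keys[j], t])
                t_neg = int(rng.integers(ad.value_of(other).shape[0]))
                s_neg = cosine_similarity(anchor, other[t_neg])
                exps.append(ad.exp(s_neg * inv_tau))
            denom = exps[0]
            for e in exps[1:]:
                denom = denom + e
            terms.append(-(ad.log(ad.exp(s_pos * inv_tau) / denom)))
    total = terms[0]
    for term in terms[1:]:
        total = total + term
    return total / len(terms)
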