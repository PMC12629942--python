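"""Multi-modal baseline encoders, subject conditioning, latent augmentation.

Each modality block (imaging, omics, demographics) passes through its own
small feed-forward map; the outputs are concatenated into the shared initial
hidden state ``h(0)``, from which a learned linear map produces the initial
latent state ``z(0)``.  A separate embedder turns the full concatenated
baseline vector into the subject conditioning vector ``psi`` that modulates
the flow field.  The augmentation map ``z -> z + xi * tanh(z) + eps``
provides a gated smooth perturbation plus Gaussian noise for representation
robustness; ``xi`` starts at zero so augmentation begins as the identity.

All maps are permutation-equivariant across subjects (rows are independent),
and every function here accepts plain numpy arrays or autodiff tensors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nnet import apply_linear, apply_mlp, init_linear, init_mlp, mlp_parameters

__all__ = ["EncoderParams", "encode_baseline", "condition_vector", "augment_latent"]


@dataclass
class EncoderParams:
    """Per-modality encoder maps plus the conditioning embedder and gate.

    Built with :meth:`create`; widths lists exclude the input width (e.g.
    ``img_widths=[8, 8]`` is a 2-layer map ending at width 8).
    """

    img_mlp: dict
    omics_mlp: dict
    demo_mlp: dict
    cond_mlp: dict
    z0_map: dict            # linear h(0) -> z(0)
    gate: Tensor            # xi, per-latent-dimension augmentation gate
    noise_sd: float = 0.0

    @classmethod
    def create(
        cls,
        rng: np.random.Generator,
        img_dim: int,
        omics_dim: int,
        demo_dim: int,
        latent_dim: int,
        img_widths=(8, 8),
        omics_widths=(8, 8),
        demo_widths=(4, 4),
        cond_dim: int = 4,
        noise_sd: float = 0.0,
        activation: str = "gelu",
    ) -> "EncoderParams":
        if noise_sd < 0:
            raise ValueError("augmentation noise SD must be >= 0")
        full_dim = img_dim + omics_dim + demo_dim
        hidden = img_widths[-1] + omics_widths[-1] + demo_widths[-1]
        return cls(
            img_mlp=init_mlp(rng, [img_dim, *img_widths], activation),
            omics_mlp=init_mlp(rng, [omics_dim, *omics_widths], activation),
            demo_mlp=init_mlp(rng, [demo_dim, *demo_widths], activation),
            cond_mlp=init_mlp(rng, [full_dim, cond_dim], "identity"),
            z0_map=init_linear(rng, hidden, latent_dim),
            gate=Tensor(np.zeros(latent_dim)),
            noise_sd=float(noise_sd),
        )

    def parameters(self) -> dict[str, Tensor]:
        out = {}
        for name, mlp in (("enc.img", self.img_mlp), ("enc.omics", self.omics_mlp),
                          ("enc.demo", self.demo_mlp), ("enc.cond", self.cond_mlp)):
            out.update(mlp_parameters(mlp, name))
        out["enc.z0.W"] = self.z0_map["W"]
        out["enc.z0.b"] = self.z0_map["b"]
        out["enc.gate"] = self.gate
        return out


def _check_width(x, expected: int, modality: str):
    width = ad.value_of(x).shape[-1]
    if width != expected:
        raise ValueError(
            f"{modality} features have width {width}, encoder expects {expected}"
        )


def encode_baseline(imaging, omics, demographics, params: EncoderParams):
    """Initial hidden state h(0): concat of the three per-modality outputs.

    Inputs may be single vectors or (batch, dim) matrices.  The output width
    is the sum of the three encoder output widths.
    """
    _check_width(imaging, params.img_mlp["widths"][0], "imaging")
    _check_width(omics, params.omics_mlp["widths"][0], "omics")
    _check_width(demographics, params.demo_mlp["widths"][0], "demographics")
    parts = [
        apply_mlp(imaging, params.img_mlp),
        apply_mlp(omics, params.omics_mlp),
        apply_mlp(demographics, params.demo_mlp),
    ]
    return ad.concatenate(parts, axis=-1)


def modality_embeddings(imaging, omics, params: EncoderParams):
    """(macro, micro) embedding pair for the cross-modality coherence term.

    Macro-scale = imaging-encoder output, micro-scale = omics-encoder output.
    """
    return apply_mlp(imaging, params.img_mlp), apply_mlp(omics, params.omics_mlp)


def initial_latent(h0, params: EncoderParams):
    """z(0) as a learned linear readout of the shared hidden state h(0)."""
    return apply_linear(h0, params.z0_map)


def condition_vector(baseline_features, params: EncoderParams):
    """Subject conditioning vector psi from the full baseline feature vector."""
    _check_width(baseline_features, params.cond_mlp["widths"][0], "baseline")
    return apply_mlp(baseline_features, params.cond_mlp)


def augment_latent(z, params: EncoderParams, seed: int | None = None):
    """Gated smooth perturbation plus seeded Gaussian noise.

    ``z~ = z + xi * tanh(z) + eps`` with ``eps ~ N(0, noise_sd^2 I)``.  With
    the gate at zero and ``noise_sd = 0`` this is the identity.  The draw is
    reproducible for a fixed seed.
    """
    zv = ad.value_of(z)
    if not np.all(np.isfinite(zv)):
        raise ValueError("augment_latent: non-finite latent input")
    out = z + params.gate * ad.tanh(z)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, params.noise_sd, size=zv.shape)
    return out
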