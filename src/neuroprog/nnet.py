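"""Tiny feed-forward building blocks shared by the encoder and dynamics code.

Parameters live in flat ``dict[str, Tensor]`` namespaces so a single Adam
instance can update the whole model; `apply_mlp` works on plain numpy input
or autodiff tensors alike.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["init_linear", "init_mlp", "apply_linear", "apply_mlp"]

_ACTIVATIONS = {
    "tanh": ad.tanh,
    "gelu": ad.gelu,
    "relu": ad.relu,
    "identity": lambda x: x,
}


def init_linear(rng: np.random.Generator, n_in: int, n_out: int,
                scale: float | None = None) -> dict:
    """Glorot-scaled weight matrix and zero bias."""
    if scale is None:
        scale = float(np.sqrt(2.0 / (n_in + n_out)))
    return {
        "W": Tensor(rng.normal(0.0, scale, size=(n_in, n_out))),
        "b": Tensor(np.zeros(n_out)),
    }


def apply_linear(x, layer: dict):
    return x @ layer["W"] + layer["b"]


def init_mlp(rng: np.random.Generator, widths: list[int],
             activation: str = "gelu") -> dict:
    """`widths` = [n_in, hidden..., n_out]; activation applied between layers."""
    if any(w < 1 for w in widths):
        raise ValueError(f"layer widths must be positive, got {widths}")
    layers = [init_linear(rng, a, b) for a, b in zip(widths, widths[1:])]
    return {"layers": layers, "activation": activation, "widths": list(widths)}


def apply_mlp(x, mlp: dict):
    act = _ACTIVATIONS[mlp["activation"]]
    h = x
    for i, layer in enumerate(mlp["layers"]):
        h = apply_linear(h, layer)
        if i < len(mlp["layers"]) - 1:
            h = act(h)
    return h


def mlp_parameters(mlp: dict, prefix: str) -> dict:
    """Flatten an MLP's tensors into {name: Tensor} for the optimiser."""
    out = {}
    for i, layer in enumerate(mlp["layers"]):
        out[f"{prefix}.{i}.W"] = layer["W"]
        out[f"{prefix}.{i}.b"] = layer["b"]
    return out
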