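"""Minimal reverse-mode automatic differentiation over numpy arrays.

The progression model is trained by gradient descent on a composite objective
built from many small penalty terms.  All of those terms are ordinary numpy
expressions; this module provides the :class:`Tensor` wrapper that records the
computation graph and back-propagates gradients through it, together with a
handful of functional helpers that dispatch transparently between plain numpy
arrays and tensors.  Loss functions elsewhere in the package are written once
against these helpers and therefore work both as cheap numpy evaluations (for
validation, diagnostics and tests) and as differentiable graph nodes (for
training).

Only the operations the model actually uses are implemented: elementwise
arithmetic, matmul, reductions, smooth nonlinearities, indexing/concatenation
and a numerically stabilised softmax.  Gradients follow numpy broadcasting
rules; broadcast dimensions are summed out on the way back.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "value_of",
    "is_tensor",
    "tanh",
    "exp",
    "log",
    "sqrt",
    "relu",
    "sigmoid",
    "gelu",
    "square",
    "asum",
    "amean",
    "concatenate",
    "stack",
    "softmax",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float numpy array."""

    __slots__ = ("value", "grad", "_parents", "_backward")

    # make ndarray <op> Tensor defer to the reflected Tensor methods
    __array_ufunc__ = None

    def __init__(self, value, parents=(), backward=None):
        self.value = np.asarray(value, dtype=float)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph mechanics ---------------------------------------------------

    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.value.copy())

    def item(self) -> float:
        return float(self.value)

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.value)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs from unrolled ODEs get deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in topo:
            node.grad = np.zeros_like(node.value)
        self.grad = np.asarray(grad, dtype=float).reshape(self.value.shape)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.value + other.value, (self, other))

        def back(g):
            self.grad += _unbroadcast(g, self.value.shape)
            other.grad += _unbroadcast(g, other.value.shape)

        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, (self,))
        out._backward = lambda g: self.__iadd_grad(-g)
        return out

    def __iadd_grad(self, g):
        self.grad += _unbroadcast(g, self.value.shape)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.value * other.value, (self, other))

        def back(g):
            self.grad += _unbroadcast(g * other.value, self.value.shape)
            other.grad += _unbroadcast(g * self.value, other.value.shape)

        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.value / other.value, (self, other))

        def back(g):
            self.grad += _unbroadcast(g / other.value, self.value.shape)
            other.grad += _unbroadcast(
                -g * self.value / other.value**2, other.value.shape
            )

        out._backward = back
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = Tensor(self.value**exponent, (self,))

        def back(g):
            self.grad += _unbroadcast(
                g * exponent * self.value ** (exponent - 1), self.value.shape
            )

        out._backward = back
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.value @ other.value, (self, other))

        def back(g):
            a, b = self.value, other.value
            if a.ndim == 1 and b.ndim == 1:
                self.grad += g * b
                other.grad += g * a
            elif a.ndim == 1:
                self.grad += b @ g
                other.grad += np.outer(a, g)
            elif b.ndim == 1:
                self.grad += np.outer(g, b)
                other.grad += a.T @ g
            else:
                self.grad += _unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape)
                other.grad += _unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape)

        out._backward = back
        return out

    def __rmatmul__(self, other):
        return as_tensor(other) @ self

    # -- reductions & shaping ---------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.value.sum(axis=axis, keepdims=keepdims), (self,))

        def back(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self.grad += np.broadcast_to(g, self.value.shape)

        out._backward = back
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape):
        out = Tensor(self.value.reshape(*shape), (self,))
        out._backward = lambda g: self.__iadd_grad(g.reshape(self.value.shape))
        return out

    @property
    def T(self):
        out = Tensor(self.value.T, (self,))
        out._backward = lambda g: self.__iadd_grad(g.T)
        return out

    def __getitem__(self, idx):
        out = Tensor(self.value[idx], (self,))

        def back(g):
            scatter = np.zeros_like(self.value)
            np.add.at(scatter, idx, g)
            self.grad += scatter

        out._backward = back
        return out

    # -- nonlinearities ----------------------------------------------------

    def tanh(self):
        v = np.tanh(self.value)
        out = Tensor(v, (self,))
        out._backward = lambda g: self.__iadd_grad(g * (1.0 - v**2))
        return out

    def exp(self):
        v = np.exp(self.value)
        out = Tensor(v, (self,))
        out._backward = lambda g: self.__iadd_grad(g * v)
        return out

    def log(self):
        out = Tensor(np.log(self.value), (self,))
        out._backward = lambda g: self.__iadd_grad(g / self.value)
        return out

    def sqrt(self):
        v = np.sqrt(self.value)
        out = Tensor(v, (self,))
        out._backward = lambda g: self.__iadd_grad(g * 0.5 / v)
        return out

    def relu(self):
        mask = self.value > 0
        out = Tensor(self.value * mask, (self,))
        out._backward = lambda g: self.__iadd_grad(g * mask)
        return out

    def sigmoid(self):
        v = 1.0 / (1.0 + np.exp(-self.value))
        out = Tensor(v, (self,))
        out._backward = lambda g: self.__iadd_grad(g * v * (1.0 - v))
        return out


# -- dispatch helpers: work on Tensor or plain numpy -----------------------


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def value_of(x):
    """The underlying numpy value whether or not `x` is a Tensor."""
    return x.value if isinstance(x, Tensor) else np.asarray(x, dtype=float)


def tanh(x):
    return x.tanh() if isinstance(x, Tensor) else np.tanh(x)


def exp(x):
    return x.exp() if isinstance(x, Tensor) else np.exp(x)


def log(x):
    return x.log() if isinstance(x, Tensor) else np.log(x)


def sqrt(x):
    return x.sqrt() if isinstance(x, Tensor) else np.sqrt(x)


def relu(x):
    return x.relu() if isinstance(x, Tensor) else np.maximum(x, 0.0)


def sigmoid(x):
    if isinstance(x, Tensor):
        return x.sigmoid()
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def gelu(x):
    """tanh-form Gaussian error linear unit (smooth, autodiff-friendly)."""
    c = np.sqrt(2.0 / np.pi)
    return 0.5 * x * (1.0 + tanh(c * (x + 0.044715 * x * x * x)))


def square(x):
    return x * x


def asum(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.sum(axis=axis, keepdims=keepdims)
    return np.sum(x, axis=axis, keepdims=keepdims)


def amean(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.mean(axis=axis, keepdims=keepdims)
    return np.mean(x, axis=axis, keepdims=keepdims)


def concatenate(parts: Sequence, axis=0):
    if not any(isinstance(p, Tensor) for p in parts):
        return np.concatenate(parts, axis=axis)
    parts = [as_tensor(p) for p in parts]
    out = Tensor(np.concatenate([p.value for p in parts], axis=axis), tuple(parts))
    sizes = [p.value.shape[axis] for p in parts]

    def back(g):
        offset = 0
        for p, size in zip(parts, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offset, offset + size)
            p.grad += g[tuple(sl)]
            offset += size

    out._backward = back
    return out


def stack(parts: Sequence, axis=0):
    if not any(isinstance(p, Tensor) for p in parts):
        return np.stack(parts, axis=axis)
    parts = [as_tensor(p) for p in parts]
    out = Tensor(np.stack([p.value for p in parts], axis=axis), tuple(parts))

    def back(g):
        for i, p in enumerate(parts):
            p.grad += np.take(g, i, axis=axis)

    out._backward = back
    return out


def softmax(x, axis=-1):
    """Numerically stabilised softmax along `axis`."""
    shift = value_of(x).max(axis=axis, keepdims=True)  # constant w.r.t. grad
    e = exp(x - shift)
    return e / asum(e, axis=axis, keepdims=True)


class Adam:
    """Adam optimiser over a flat dict of parameter Tensors.

    `weight_decay` is decoupled (AdamW-style): components that carry no
    persistent gradient signal decay toward zero instead of freezing at
    whatever the transient left behind.  It may be a single rate for all
    parameters or a dict of per-parameter-name rates (missing names get 0).
    """

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay=0.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        if not isinstance(weight_decay, dict):
            weight_decay = {k: float(weight_decay) for k in params}
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.value) for k, p in params.items()}

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            m = self._m[key] = b1 * self._m[key] + (1 - b1) * g
            v = self._v[key] = b2 * self._v[key] + (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            decay = self.weight_decay.get(key, 0.0)
            if decay:
                p.value -= self.lr * decay * p.value
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None
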