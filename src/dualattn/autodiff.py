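"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The engine provides exactly the primitives the window-attention backbone
needs: broadcasting arithmetic, matmul, shape ops (reshape / transpose /
roll / slice / concat), reductions, elementwise nonlinearities, and an
integer gather for the relative-position bias table.  Gradients are
accumulated by topological-sort backpropagation, micrograd-style.

All data is kept in float64 by default so that finite-difference gradient
verification resolves well below the tolerances used in the tests.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf as _erf

__all__ = [
    "Tensor",
    "as_tensor",
    "softmax",
    "log_softmax",
    "layer_norm",
    "gelu",
    "cross_entropy",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # collapse extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An n-d array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _prev: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._prev = _prev if self.requires_grad else ()
        self._backward = _backward

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    # ------------------------------------------------------------------
    # arithmetic
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor(self.data + other.data, _prev=(self, other), _backward=backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return Tensor(-self.data, _prev=(self,), _backward=backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor(self.data * other.data, _prev=(self, other), _backward=backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) * self**-1.0

    def __pow__(self, p: float) -> "Tensor":
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1.0))

        return Tensor(self.data**p, _prev=(self,), _backward=backward)

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g @ b.data.swapaxes(-1, -2), a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(a.data.swapaxes(-1, -2) @ g, b.shape))

        return Tensor(self.data @ other.data, _prev=(self, other), _backward=backward)

    # ------------------------------------------------------------------
    # shape ops
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.reshape(orig))

        return Tensor(self.data.reshape(shape), _prev=(self,), _backward=backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return Tensor(self.data.transpose(axes), _prev=(self,), _backward=backward)

    def swapaxes(self, a1: int, a2: int) -> "Tensor":
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.swapaxes(a1, a2))

        return Tensor(self.data.swapaxes(a1, a2), _prev=(self,), _backward=backward)

    def roll(self, shift: Sequence[int] | int, axis: Sequence[int] | int) -> "Tensor":
        def backward(g, a=self):
            if a.requires_grad:
                neg = tuple(-s for s in shift) if isinstance(shift, (tuple, list)) else -shift
                a._accum(np.roll(g, neg, axis=axis))

        return Tensor(np.roll(self.data, shift, axis=axis), _prev=(self,), _backward=backward)

    def __getitem__(self, key) -> "Tensor":
        def backward(g, a=self):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, key, g)
                a._accum(full)

        return Tensor(self.data[key], _prev=(self,), _backward=backward)

    # ------------------------------------------------------------------
    # reductions and elementwise
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g, a=self):
            if a.requires_grad:
                gg = np.asarray(g)
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,), _backward=backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g, a=self, od=out_data):
            if a.requires_grad:
                a._accum(g * od)

        return Tensor(out_data, _prev=(self,), _backward=backward)

    def log(self) -> "Tensor":
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor(np.log(self.data), _prev=(self,), _backward=backward)

    def take(self, index: np.ndarray) -> "Tensor":
        """Gather rows by an integer array along axis 0 (scatter-add backward)."""
        index = np.asarray(index)

        def backward(g, a=self):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, index, g)
                a._accum(full)

        return Tensor(self.data[index], _prev=(self,), _backward=backward)

    # ------------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep graphs exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))

        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ----------------------------------------------------------------------
# neural-network functionals


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Row-stochastic softmax with max-subtraction for numerical stability."""
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))  # detached max
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last (channel) axis with learned affine."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * (var + eps) ** -0.5 * gamma + beta


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    xd = x.data
    cdf = 0.5 * (1.0 + _erf(xd / math.sqrt(2.0)))
    out_data = xd * cdf

    def backward(g, a=x, cdf=cdf, xd=xd):
        if a.requires_grad:
            pdf = np.exp(-0.5 * xd * xd) / math.sqrt(2.0 * math.pi)
            a._accum(g * (cdf + xd * pdf))

    return Tensor(out_data, _prev=(x,), _backward=backward)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under ``logits``.

    ``logits`` has shape (N, num_classes); labels is a length-N int array.
    """
    labels = np.asarray(labels, dtype=np.intp)
    n = logits.shape[0]
    lsm = log_softmax(logits, axis=-1)
    picked = lsm[np.arange(n), labels]
    return -picked.mean()
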