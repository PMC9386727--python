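"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Provides exactly the primitives the dual-pathway protein model needs:
broadcast-aware arithmetic, matmul, pointwise nonlinearities (tanh, sigmoid,
exact GELU), reductions, reshaping, slicing, padding, concatenation and an
embedding gather.  Everything is float64.  A :class:`Tensor` records its
parents and a backward closure; :meth:`Tensor.backward` runs a topological
sweep accumulating gradients into every tensor with ``requires_grad``.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "concat",
    "pad_axis1",
    "gelu",
    "softmax_lastaxis",
]

_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from size 1
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------ utils
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        assert np.isscalar(exponent)
        out_data = self.data ** exponent

        def backward(g, a=self, e=exponent, od=out_data):
            if a.requires_grad:
                a._accumulate(g * e * a.data ** (e - 1.0))

        return Tensor(out_data, parents=(self,), backward=backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accumulate(_unbroadcast(gb, b.data.shape))

        return Tensor(np.matmul(self.data, other.data), parents=(self, other), backward=backward)

    # ----------------------------------------------------------- nonlinearity
    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g, a=self, od=out_data):
            if a.requires_grad:
                a._accumulate(g * (1.0 - od * od))

        return Tensor(out_data, parents=(self,), backward=backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, a=self, od=out_data):
            if a.requires_grad:
                a._accumulate(g * od * (1.0 - od))

        return Tensor(out_data, parents=(self,), backward=backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, od=out_data):
            if a.requires_grad:
                a._accumulate(g * od)

        return Tensor(out_data, parents=(self,), backward=backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(g / a.data)

        return Tensor(np.log(self.data), parents=(self,), backward=backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through unclamped entries."""
        mask = (self.data > lo) & (self.data < hi)

        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accumulate(g * m)

        return Tensor(np.clip(self.data, lo, hi), parents=(self,), backward=backward)

    # -------------------------------------------------------------- reduction
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self, ax=axis, kd=keepdims):
            if not a.requires_grad:
                return
            if ax is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
                return
            if not kd:
                g = np.expand_dims(g, ax)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

        return Tensor(out_data, parents=(self,), backward=backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------- structural
    def reshape(self, *shape):
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(g.reshape(a.data.shape))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=backward)

    def transpose(self, *axes):
        axes = axes or None
        inv = np.argsort(axes) if axes else None

        def backward(g, a=self, inv=inv):
            if a.requires_grad:
                a._accumulate(g.transpose(inv) if inv is not None else g.T)

        return Tensor(self.data.transpose(axes), parents=(self,), backward=backward)

    def __getitem__(self, key):
        def backward(g, a=self, k=key):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                full[k] += g
                a._accumulate(full)

        return Tensor(self.data[key], parents=(self,), backward=backward)

    def take_rows(self, indices: np.ndarray):
        """Embedding gather: rows of a 2-D table selected by an integer array."""
        indices = np.asarray(indices)

        def backward(g, a=self, idx=indices):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx.ravel(), g.reshape(-1, g.shape[-1]))
                a._accumulate(full)

        return Tensor(self.data[indices], parents=(self,), backward=backward)

    # --------------------------------------------------------------- backward
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


# ------------------------------------------------------------------ functions

def concat(tensors: list, axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g, ts=tuple(tensors), ax=axis, offs=offsets):
        for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[ax] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def pad_axis1(x: Tensor, before: int, after: int) -> Tensor:
    """Zero-pad a (B, L, C) tensor along the sequence axis."""
    widths = ((0, 0), (before, after), (0, 0))
    out_data = np.pad(x.data, widths)

    def backward(g, a=x, b=before, L=x.data.shape[1]):
        if a.requires_grad:
            a._accumulate(g[:, b:b + L, :])

    return Tensor(out_data, parents=(x,), backward=backward)


def gelu(x: Tensor) -> Tensor:
    """Exact Gaussian Error Linear Unit, x * Phi(x)."""
    xd = x.data
    phi_cdf = 0.5 * (1.0 + erf(xd / _SQRT2))
    out_data = xd * phi_cdf

    def backward(g, a=x, cdf=phi_cdf):
        if a.requires_grad:
            pdf = _INV_SQRT_2PI * np.exp(-0.5 * a.data * a.data)
            a._accumulate(g * (cdf + a.data * pdf))

    return Tensor(out_data, parents=(x,), backward=backward)


def softmax_lastaxis(x: Tensor) -> Tensor:
    """Numerically stable softmax over the trailing axis."""
    shift = Tensor(x.data.max(axis=-1, keepdims=True))  # constant shift
    e = (x - shift).exp()
    return e / e.sum(axis=-1, keepdims=True)
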