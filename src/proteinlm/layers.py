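"""Neural-network layers and the Adam optimizer on top of the autodiff engine.

Initialization is fan-in-scaled Gaussian (std = 1/sqrt(fan_in)) drawn from a
caller-supplied :class:`numpy.random.Generator`, so a model built twice from
the same seed is bit-identical.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from .autodiff import Tensor, pad_axis1

__all__ = ["Module", "Dense", "Embedding", "Conv1d", "LayerNorm", "Adam"]


def _fan_in_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)


class Module:
    """Base class: children and parameters are discovered by attribute scan."""

    def named_parameters(self, prefix: str = "") -> "OrderedDict[str, Tensor]":
        out: OrderedDict[str, Tensor] = OrderedDict()
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if prefix else name
            if isinstance(value, Tensor) and value.requires_grad:
                out[full] = value
            elif isinstance(value, Module):
                out.update(value.named_parameters(prefix=full + "/"))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(prefix=f"{full}{i}/"))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out[f"{full}{i}"] = item
        return out

    def parameters(self) -> list:
        return list(self.named_parameters().values())

    def count_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.W = Tensor(_fan_in_init(rng, (d_in, d_out), d_in), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class Embedding(Module):
    def __init__(self, n_symbols: int, d_out: int, rng: np.random.Generator):
        self.E = Tensor(rng.normal(0.0, 1.0, size=(n_symbols, d_out)), requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.E.take_rows(np.asarray(ids))


class Conv1d(Module):
    """Same-padded, stride-1, optionally dilated 1-D convolution on (B, L, C).

    Implemented as a sum of shifted position-wise matmuls, one per kernel tap,
    which keeps it inside the autodiff primitive set.
    """

    def __init__(self, d_in: int, d_out: int, kernel: int, dilation: int,
                 rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same-padding")
        self.kernel = kernel
        self.dilation = dilation
        fan_in = d_in * kernel
        self.W = Tensor(_fan_in_init(rng, (kernel, d_in, d_out), fan_in), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    @property
    def receptive_field(self) -> int:
        return (self.kernel - 1) * self.dilation + 1

    def __call__(self, x: Tensor) -> Tensor:
        L = x.shape[1]
        half = ((self.kernel - 1) // 2) * self.dilation
        xp = pad_axis1(x, half, half)
        out = None
        for t in range(self.kernel):
            shifted = xp[:, t * self.dilation:t * self.dilation + L, :]
            term = shifted @ self.W[t]
            out = term if out is None else out + term
        return out + self.b


class LayerNorm(Module):
    """Normalize over the trailing feature axis with learnable gain/offset."""

    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return xc * inv * self.gamma + self.beta


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params: list, lr: float = 2e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
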