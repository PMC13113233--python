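"""Neural-network building blocks on the autodiff engine.

Layers hold their parameters as ``Tensor`` objects with ``requires_grad=True``;
:class:`Module` collects them recursively for the optimizer and for state-dict
(de)serialization.  Initialization draws from a NumPy ``Generator`` passed in
explicitly, so a single integer seed pins every weight in a model.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Tensor, im2col, softmax, stack

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "LayerNorm",
    "MultiheadSelfAttention",
    "GRU",
    "AdamW",
    "clip_grad_norm",
]


class Module:
    """Base class providing parameter discovery and state-dict round trips."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            if name.startswith("_"):  # private attrs (e.g. cached graph nodes)
                continue
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(
                f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}"
            )
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}"
                )
            p.data = arr.copy()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    """Affine map ``y = x @ W + b`` with W of shape (in_features, out_features)."""

    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator,
        bias: bool = True,
    ):
        self.W = Tensor(
            _glorot(rng, in_features, out_features, (in_features, out_features)),
            requires_grad=True,
        )
        self.b = (
            Tensor(np.zeros(out_features), requires_grad=True) if bias else None
        )

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        return y + self.b if self.b is not None else y


class Conv2d(Module):
    """2-D convolution via im2col; weight stored as (out, in*kh*kw)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: tuple[int, int] = (1, 1),
        padding: tuple[int, int] = (1, 1),
    ):
        k = kernel_size
        fan_in = in_channels * k * k
        self.kernel_size = k
        self.stride = stride
        self.padding = padding
        self.W = Tensor(
            _glorot(rng, fan_in, out_channels, (out_channels, fan_in)),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(out_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B = x.shape[0]
        k = self.kernel_size
        cols, (ho, wo) = im2col(x, k, k, self.stride, self.padding)
        out = self.W @ cols  # (B, out, Ho*Wo) via broadcasting
        out = out + self.b.reshape(1, -1, 1)
        return out.reshape(B, self.W.shape[0], ho, wo)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta


class MultiheadSelfAttention(Module):
    """Standard scaled dot-product self-attention over the time axis."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads != 0:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim = dim
        self.heads = heads
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.o = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, d = x.shape
        h, dh = self.heads, d // self.heads

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, T, h, dh).transpose((0, 2, 1, 3))

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.T) * (1.0 / math.sqrt(dh))  # (B, h, T, T)
        att = softmax(scores, axis=-1)
        out = att @ v  # (B, h, T, dh)
        out = out.transpose((0, 2, 1, 3)).reshape(B, T, d)
        return self.o(out)


class GRUCellParams(Module):
    """One GRU layer's parameters: gates ordered (reset, update, candidate)."""

    def __init__(self, input_size: int, hidden: int, rng: np.random.Generator):
        self.Wx = Tensor(
            _glorot(rng, input_size, 3 * hidden, (input_size, 3 * hidden)),
            requires_grad=True,
        )
        self.Wh = Tensor(
            _glorot(rng, hidden, 3 * hidden, (hidden, 3 * hidden)),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(3 * hidden), requires_grad=True)
        self.hidden = hidden

    def step(self, x: Tensor, h: Tensor) -> Tensor:
        H = self.hidden
        gi = x @ self.Wx + self.b
        gh = h @ self.Wh
        r = (gi[:, 0:H] + gh[:, 0:H]).sigmoid()
        z = (gi[:, H : 2 * H] + gh[:, H : 2 * H]).sigmoid()
        n = (gi[:, 2 * H : 3 * H] + r * gh[:, 2 * H : 3 * H]).tanh()
        return (1.0 - z) * n + z * h


class GRU(Module):
    """Stacked unidirectional GRU; input (B, T, C) -> outputs (B, T, H)."""

    def __init__(
        self, input_size: int, hidden: int, layers: int, rng: np.random.Generator
    ):
        self.layers = [
            GRUCellParams(input_size if i == 0 else hidden, hidden, rng)
            for i in range(layers)
        ]
        self.hidden = hidden

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        B, T, _ = x.shape
        seq = [x[:, t, :] for t in range(T)]
        h_last = None
        for cell in self.layers:
            h = Tensor(np.zeros((B, cell.hidden)))
            outputs = []
            for t in range(T):
                h = cell.step(seq[t], h)
                outputs.append(h)
            seq = outputs
            h_last = h
        return stack(seq, axis=1), h_last


class AdamW:
    """Adam with decoupled weight decay (Loshchilov & Hutter)."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1.0 - b1) * g
            self.v[i] = b2 * self.v[i] + (1.0 - b2) * g**2
            m_hat = self.m[i] / bc1
            v_hat = self.v[i] / bc2
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def clip_grad_norm(params: list[Tensor], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is <= ``max_norm``.

    Returns the pre-clip global norm.
    """
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad**2).sum())
    norm = math.sqrt(total)
    if norm > max_norm and norm > 0.0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return norm
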