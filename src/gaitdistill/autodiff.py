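"""Reverse-mode automatic differentiation on NumPy arrays.

A small define-by-run engine: :class:`Tensor` wraps an ``ndarray`` and records
the operations applied to it; :meth:`Tensor.backward` walks the recorded graph
in reverse topological order and accumulates gradients.  It supports exactly
the operations the package needs — broadcast arithmetic, (batched) matrix
products, reductions, the usual pointwise nonlinearities, slicing, reshaping,
stacking and an image-to-column unfolding for convolutions.  Everything is
float64.

Gradients are accumulated on every node reached by the backward pass (not only
leaves), which lets callers read sensitivities of intermediate activations —
used for the diagonal Fisher estimate of the anchor activations.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "concatenate", "stack", "im2col", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray plus the closure that back-propagates through its creation."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @classmethod
    def _from_op(cls, data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- introspection -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in visited and parent.requires_grad:
                    stack.append((parent, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _accum(node: "Tensor", grad: np.ndarray) -> None:
        if not node.requires_grad:
            return
        node.grad = grad if node.grad is None else node.grad + grad

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g, a=self, b=other):
            Tensor._accum(a, _unbroadcast(g, a.shape))
            Tensor._accum(b, _unbroadcast(g, b.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g, a=self):
            Tensor._accum(a, -g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g, a=self, b=other):
            Tensor._accum(a, _unbroadcast(g * b.data, a.shape))
            Tensor._accum(b, _unbroadcast(g * a.data, b.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g, a=self, b=other):
            Tensor._accum(a, _unbroadcast(g / b.data, a.shape))
            Tensor._accum(b, _unbroadcast(-g * a.data / b.data**2, b.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data**exponent

        def backward(g, a=self, n=float(exponent)):
            Tensor._accum(a, g * n * a.data ** (n - 1.0))

        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        if self.ndim < 2 or other.ndim < 2:
            raise ValueError("matmul requires operands with ndim >= 2")
        out_data = np.matmul(self.data, other.data)

        def backward(g, a=self, b=other):
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            Tensor._accum(a, _unbroadcast(ga, a.shape))
            Tensor._accum(b, _unbroadcast(gb, b.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    def __rmatmul__(self, other) -> "Tensor":
        return as_tensor(other) @ self

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self, axis=axis, keepdims=keepdims):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            Tensor._accum(a, np.broadcast_to(g, a.shape).copy())

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- pointwise nonlinearities -------------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g, a=self, y=out_data):
            Tensor._accum(a, g * y)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g, a=self):
            Tensor._accum(a, g / a.data)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    def sqrt(self) -> "Tensor":
        out_data = np.sqrt(self.data)

        def backward(g, a=self, y=out_data):
            Tensor._accum(a, g / (2.0 * y))

        return Tensor._from_op(out_data, (self,), backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(g, a=self, y=out_data):
            Tensor._accum(a, g * (1.0 - y**2))

        return Tensor._from_op(out_data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, a=self, y=out_data):
            Tensor._accum(a, g * y * (1.0 - y))

        return Tensor._from_op(out_data, (self,), backward)

    def softplus(self) -> "Tensor":
        # log(1 + e^x), computed stably
        out_data = np.logaddexp(0.0, self.data)

        def backward(g, a=self):
            Tensor._accum(a, g / (1.0 + np.exp(-a.data)))

        return Tensor._from_op(out_data, (self,), backward)

    def sin(self) -> "Tensor":
        def backward(g, a=self):
            Tensor._accum(a, g * np.cos(a.data))

        return Tensor._from_op(np.sin(self.data), (self,), backward)

    def cos(self) -> "Tensor":
        def backward(g, a=self):
            Tensor._accum(a, -g * np.sin(a.data))

        return Tensor._from_op(np.cos(self.data), (self,), backward)

    # -- shape manipulation --------------------------------------------------
    @property
    def T(self) -> "Tensor":
        """Swap the last two axes (matrix transpose, batched)."""
        out_data = np.swapaxes(self.data, -1, -2)

        def backward(g, a=self):
            Tensor._accum(a, np.swapaxes(g, -1, -2))

        return Tensor._from_op(out_data, (self,), backward)

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        axes = tuple(axes)
        inverse = tuple(np.argsort(axes))

        def backward(g, a=self, inv=inverse):
            Tensor._accum(a, np.transpose(g, inv))

        return Tensor._from_op(np.transpose(self.data, axes), (self,), backward)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g, a=self):
            Tensor._accum(a, g.reshape(a.shape))

        return Tensor._from_op(self.data.reshape(shape), (self,), backward)

    def __getitem__(self, index) -> "Tensor":
        out_data = self.data[index]

        def backward(g, a=self, index=index):
            full = np.zeros_like(a.data)
            np.add.at(full, index, g)
            Tensor._accum(a, full)

        return Tensor._from_op(out_data, (self,), backward)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, parts=tensors, offs=offsets, axis=axis):
        for t, lo, hi in zip(parts, offs[:-1], offs[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            Tensor._accum(t, g[tuple(sl)])

    return Tensor._from_op(out_data, tensors, backward)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g, parts=tensors, axis=axis):
        for i, t in enumerate(parts):
            Tensor._accum(t, np.take(g, i, axis=axis))

    return Tensor._from_op(out_data, tensors, backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x.data.max(axis=axis, keepdims=True)  # constant shift for stability
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def im2col(
    x: Tensor, kh: int, kw: int, stride: tuple[int, int], pad: tuple[int, int]
) -> tuple[Tensor, tuple[int, int]]:
    """Unfold ``x`` of shape (B, C, H, W) into columns (B, C*kh*kw, Ho*Wo).

    Returns the column tensor and the output spatial shape ``(Ho, Wo)``.
    """
    sh, sw = stride
    ph, pw = pad
    B, C, H, W = x.shape
    Hp, Wp = H + 2 * ph, W + 2 * pw
    Ho = (Hp - kh) // sh + 1
    Wo = (Wp - kw) // sw + 1
    padded = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    windows = np.lib.stride_tricks.sliding_window_view(padded, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::sh, ::sw]  # (B, C, Ho, Wo, kh, kw)
    cols = windows.transpose(0, 1, 4, 5, 2, 3).reshape(B, C * kh * kw, Ho * Wo)

    def backward(g, a=x):
        g6 = g.reshape(B, C, kh, kw, Ho, Wo)
        gpad = np.zeros((B, C, Hp, Wp))
        for i in range(kh):
            for j in range(kw):
                gpad[:, :, i : i + Ho * sh : sh, j : j + Wo * sw : sw] += g6[
                    :, :, i, j
                ]
        Tensor._accum(a, gpad[:, :, ph : ph + H, pw : pw + W])

    col_t = Tensor._from_op(cols, (x,), backward)
    return col_t, (Ho, Wo)
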