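"""Reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it on a dynamic graph; :meth:`Tensor.backward` walks the graph in reverse
topological order and accumulates gradients into every tensor that requires
them.  Gradients are retained on intermediate tensors as well, which is what
class-activation mapping needs.

The primitive set is deliberately small: elementwise arithmetic, matmul,
shape ops (reshape / transpose / slice / roll / concatenate), reductions,
the activations used by the models, numerically stable (log-)softmax, and a
stride-1 same-padding 2-D convolution.  Everything else (layer norm, batch
norm, attention) is composed from these primitives, so it differentiates
automatically.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy import special as _special

__all__ = ["Tensor", "astensor", "concatenate", "conv2d"]

_INV_SQRT2 = float(1.0 / np.sqrt(2.0))
_INV_SQRT2PI = float(1.0 / np.sqrt(2.0 * np.pi))


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if arr.dtype.kind in "iub":
            arr = arr.astype(np.float32)
        self.data: np.ndarray = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ------------------------------------------------------------------ util
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every graph ancestor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs can be deep)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        self.grad = _acc(self.grad, np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(astensor(other), -1.0))

    def __rsub__(self, other):
        return add(astensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(astensor(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    # ------------------------------------------------------------- shape ops
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _acc(old: np.ndarray | None, new: np.ndarray) -> np.ndarray:
    return new if old is None else old + new


def _node(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ------------------------------------------------------------------- basics

def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.grad = _acc(a.grad, _unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.grad = _acc(b.grad, _unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a.grad = _acc(a.grad, _unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.grad = _acc(b.grad, _unbroadcast(g * a.data, b.data.shape))

    return _node(out_data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = astensor(a)
    p = float(p)
    out_data = a.data ** p

    def backward(g):
        if a.requires_grad:
            a.grad = _acc(a.grad, g * p * a.data ** (p - 1.0))

    return _node(out_data, (a,), backward)


def exp(a) -> Tensor:
    a = astensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a.grad = _acc(a.grad, g * out_data)

    return _node(out_data, (a,), backward)


def log(a) -> Tensor:
    a = astensor(a)
    out_data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a.grad = _acc(a.grad, g / a.data)

    return _node(out_data, (a,), backward)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    if a.ndim < 2 or b.ndim < 2:
        raise ValueError("matmul requires operands with ndim >= 2")
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a.grad = _acc(a.grad, _unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b.grad = _acc(b.grad, _unbroadcast(gb, b.data.shape))

    return _node(out_data, (a, b), backward)


# ---------------------------------------------------------------- shape ops

def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    a = astensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a.grad = _acc(a.grad, g.reshape(a.data.shape))

    return _node(out_data, (a,), backward)


def transpose(a: Tensor, axes: tuple[int, ...]) -> Tensor:
    a = astensor(a)
    out_data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a.grad = _acc(a.grad, g.transpose(inv))

    return _node(out_data, (a,), backward)


def getitem(a: Tensor, idx) -> Tensor:
    a = astensor(a)
    out_data = a.data[idx]

    def backward(g):
        if a.requires_grad:
            gi = np.zeros_like(a.data)
            np.add.at(gi, idx, g)
            a.grad = _acc(a.grad, gi)

    return _node(out_data, (a,), backward)


def roll(a: Tensor, shift: tuple[int, ...], axis: tuple[int, ...]) -> Tensor:
    a = astensor(a)
    out_data = np.roll(a.data, shift, axis=axis)
    neg = tuple(-s for s in shift)

    def backward(g):
        if a.requires_grad:
            a.grad = _acc(a.grad, np.roll(g, neg, axis=axis))

    return _node(out_data, (a,), backward)


def concatenate(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = [astensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.grad = _acc(t.grad, g[tuple(sl)])

    return _node(out_data, ts, backward)


# --------------------------------------------------------------- reductions

def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = astensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if a.requires_grad:
            if axis is None:
                grad = np.broadcast_to(g, a.data.shape)
            else:
                gk = g if keepdims else np.expand_dims(g, axis)
                grad = np.broadcast_to(gk, a.data.shape)
            a.grad = _acc(a.grad, np.ascontiguousarray(grad))

    return _node(out_data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = astensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


# -------------------------------------------------------------- activations

def relu(a: Tensor) -> Tensor:
    a = astensor(a)
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g):
        if a.requires_grad:
            a.grad = _acc(a.grad, g * mask)

    return _node(out_data, (a,), backward)


def gelu(a: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    a = astensor(a)
    cdf = 0.5 * (1.0 + _special.erf(a.data * _INV_SQRT2))
    out_data = a.data * cdf

    def backward(g):
        if a.requires_grad:
            pdf = _INV_SQRT2PI * np.exp(-0.5 * a.data * a.data)
            a.grad = _acc(a.grad, g * (cdf + a.data * pdf))

    return _node(out_data, (a,), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    a = astensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            a.grad = _acc(a.grad, s * (g - dot))

    return _node(s, (a,), backward)


def log_softmax(a: Tensor, axis: int = -1) -> Tensor:
    a = astensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse

    def backward(g):
        if a.requires_grad:
            sm = np.exp(out_data)
            a.grad = _acc(a.grad, g - sm * g.sum(axis=axis, keepdims=True))

    return _node(out_data, (a,), backward)


# ------------------------------------------------------------- convolution

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1, zero-padded 'same' 2-D convolution (cross-correlation).

    ``x``: (N, C, H, W); ``w``: (O, C, kh, kw) with odd kernel sides;
    ``b``: (O,) or None.  Output: (N, O, H, W).
    """
    x, w = astensor(x), astensor(w)
    kh, kw = w.data.shape[-2:]
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv2d requires odd kernel sides")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    out_data = np.einsum("nchwij,ocij->nohw", cols, w.data, optimize=True)
    parents: list[Tensor] = [x, w]
    if b is not None:
        b = astensor(b)
        out_data = out_data + b.data[None, :, None, None]
        parents.append(b)

    def backward(g):
        if b is not None and b.requires_grad:
            b.grad = _acc(b.grad, g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.einsum("nohw,nchwij->ocij", g, cols, optimize=True)
            w.grad = _acc(w.grad, gw)
        if x.requires_grad:
            gp = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
            gcols = np.lib.stride_tricks.sliding_window_view(gp, (kh, kw), axis=(2, 3))
            wflip = w.data[:, :, ::-1, ::-1]
            gx_pad = np.einsum("nohwij,ocij->nchw", gcols, wflip, optimize=True)
            H, W = x.data.shape[-2:]
            a_grad = gx_pad[:, :, ph:ph + H, pw:pw + W]
            x.grad = _acc(x.grad, np.ascontiguousarray(a_grad))

    return _node(out_data, parents, backward)
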