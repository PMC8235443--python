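"""Reverse-mode automatic differentiation on NumPy arrays.

This is the numerical core the package's encoder/decoder/classifier
networks are built on.  It implements exactly the operations those
networks need: broadcast arithmetic, matrix products, elementwise
nonlinearities, reductions, reshape/concatenate, zero-padded stride-1
convolutions (2-D and grouped 1-D), 2x max-pooling, nearest-neighbour
upsampling, and a numerically stable binary cross-entropy on logits.

A :class:`Tensor` wraps an ``ndarray`` and records its parents plus a
backward closure; calling :meth:`Tensor.backward` on a scalar performs a
topological sweep accumulating gradients into ``.grad``.  Gradients of
every op are checked against central finite differences in the test
suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "mul",
    "matmul",
    "exp",
    "log",
    "sigmoid",
    "relu",
    "sum_",
    "mean_",
    "reshape",
    "concat",
    "conv2d",
    "grouped_conv1d",
    "maxpool2d",
    "maxpool1d",
    "upsample2d",
    "upsample1d",
    "bce_with_logits",
]


class Tensor:
    """An ndarray node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bw")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple = (),
        _bw: Callable | None = None,
    ):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=float)
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        # Constants need no history; dropping it keeps inference graphs light.
        self._parents = _parents if self.requires_grad else ()
        self._bw = _bw if self.requires_grad else None
        self.grad: np.ndarray | None = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        for node in topo:
            node.grad = None
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._bw is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._bw(node.grad)):
                if g is None or not parent.requires_grad:
                    continue
                parent.grad = g if parent.grad is None else parent.grad + g

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, as_tensor(np.asarray(-1.0, dtype=self.data.dtype)))

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))

    def __pow__(self, p):
        return pow_(self, p)

    def __truediv__(self, other):
        return mul(self, pow_(as_tensor(other), -1.0))

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient ``g`` down to ``shape`` after NumPy broadcasting."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def bw(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return Tensor(out, _parents=(a, b), _bw=bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data

    def bw(g):
        return (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        )

    return Tensor(out, _parents=(a, b), _bw=bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product of a 2-D batch ``(B, n)`` with weights ``(n, m)``."""
    out = a.data @ b.data

    def bw(g):
        return g @ b.data.T, a.data.T @ g

    return Tensor(out, _parents=(a, b), _bw=bw)


def pow_(t: Tensor, p: float) -> Tensor:
    out = t.data**p

    def bw(g):
        return (g * p * t.data ** (p - 1),)

    return Tensor(out, _parents=(t,), _bw=bw)


def exp(t: Tensor) -> Tensor:
    out = np.exp(t.data)

    def bw(g):
        return (g * out,)

    return Tensor(out, _parents=(t,), _bw=bw)


def log(t: Tensor) -> Tensor:
    out = np.log(t.data)

    def bw(g):
        return (g / t.data,)

    return Tensor(out, _parents=(t,), _bw=bw)


def sigmoid(t: Tensor) -> Tensor:
    out = expit(t.data)

    def bw(g):
        return (g * out * (1.0 - out),)

    return Tensor(out, _parents=(t,), _bw=bw)


def relu(t: Tensor) -> Tensor:
    out = np.maximum(t.data, 0.0)

    def bw(g):
        return (g * (t.data > 0),)

    return Tensor(out, _parents=(t,), _bw=bw)


def sum_(t: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = t.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if axis is None:
            return (np.broadcast_to(g, t.data.shape).copy(),)
        ax = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, tuple(a % t.data.ndim for a in ax))
        return (np.broadcast_to(g, t.data.shape).copy(),)

    return Tensor(out, _parents=(t,), _bw=bw)


def mean_(t: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = t.data.size if axis is None else np.prod(
        [t.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(sum_(t, axis=axis, keepdims=keepdims), as_tensor(np.asarray(1.0 / n, dtype=t.data.dtype)))


def reshape(t: Tensor, shape) -> Tensor:
    out = t.data.reshape(shape)

    def bw(g):
        return (g.reshape(t.data.shape),)

    return Tensor(out, _parents=(t,), _bw=bw)


def concat(ts: Sequence[Tensor], axis: int = -1) -> Tensor:
    out = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, _parents=tuple(ts), _bw=bw)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded stride-1 2-D convolution.

    ``x``: (B, H, W, C) channels-last; ``w``: (k, k, C, F); ``b``: (F,).
    """
    xb, wb = x.data, w.data
    k = wb.shape[0]
    if k % 2 == 0:
        raise ValueError("conv2d supports odd kernel sizes only")
    B, H, W, _ = xb.shape
    p = k // 2
    xp = np.pad(xb, ((0, 0), (p, p), (p, p), (0, 0)))
    out = np.zeros((B, H, W, wb.shape[3]), dtype=xb.dtype)
    for i in range(k):
        for j in range(k):
            out += xp[:, i : i + H, j : j + W, :] @ wb[i, j]
    out += b.data

    def bw(g):
        gb = g.sum(axis=(0, 1, 2))
        gw = np.empty_like(wb)
        gxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                patch = xp[:, i : i + H, j : j + W, :]
                gw[i, j] = np.tensordot(patch, g, axes=([0, 1, 2], [0, 1, 2]))
                gxp[:, i : i + H, j : j + W, :] += g @ wb[i, j].T
        gx = gxp[:, p : p + H, p : p + W, :]
        return gx, gw, gb

    return Tensor(out, _parents=(x, w, b), _bw=bw)


def grouped_conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded stride-1 grouped 1-D convolution.

    ``x``: (B, T, G*cin); ``w``: (k, G, cin, cout); ``b``: (G*cout,).
    Each channel group (here: one accelerometer axis) is convolved with its
    own filter bank and the group outputs are concatenated.
    """
    xb, wb = x.data, w.data
    k, G, cin, cout = wb.shape
    if k % 2 == 0:
        raise ValueError("grouped_conv1d supports odd kernel sizes only")
    B, T, C = xb.shape
    if C != G * cin:
        raise ValueError(f"expected {G * cin} input channels, got {C}")
    p = k // 2
    xp = np.pad(xb, ((0, 0), (p, p), (0, 0)))
    out = np.zeros((B, T, G * cout), dtype=xb.dtype)
    for gi in range(G):
        xg = xp[:, :, gi * cin : (gi + 1) * cin]
        og = out[:, :, gi * cout : (gi + 1) * cout]
        for o in range(k):
            og += xg[:, o : o + T, :] @ wb[o, gi]
    out += b.data

    def bw(g):
        gb = g.sum(axis=(0, 1))
        gw = np.empty_like(wb)
        gxp = np.zeros_like(xp)
        for gi in range(G):
            xg = xp[:, :, gi * cin : (gi + 1) * cin]
            gg = g[:, :, gi * cout : (gi + 1) * cout]
            for o in range(k):
                gw[o, gi] = np.tensordot(xg[:, o : o + T, :], gg, axes=([0, 1], [0, 1]))
                gxp[:, o : o + T, gi * cin : (gi + 1) * cin] += gg @ wb[o, gi].T
        gx = gxp[:, p : p + T, :]
        return gx, gw, gb

    return Tensor(out, _parents=(x, w, b), _bw=bw)


def maxpool2d(t: Tensor) -> Tensor:
    """2x2 max-pooling with stride 2; spatial dims must be even."""
    x = t.data
    B, H, W, C = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2d needs even spatial dims, got {H}x{W}")
    H2, W2 = H // 2, W // 2
    xr = x.reshape(B, H2, 2, W2, 2, C).transpose(0, 1, 3, 5, 2, 4).reshape(B, H2, W2, C, 4)
    idx = xr.argmax(axis=4)
    out = np.take_along_axis(xr, idx[..., None], axis=4)[..., 0]

    def bw(g):
        gz = np.zeros((B, H2, W2, C, 4), dtype=g.dtype)
        np.put_along_axis(gz, idx[..., None], g[..., None], axis=4)
        gx = gz.reshape(B, H2, W2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(B, H, W, C)
        return (gx,)

    return Tensor(out, _parents=(t,), _bw=bw)


def maxpool1d(t: Tensor) -> Tensor:
    """Window-2 max-pooling with stride 2 along the time axis."""
    x = t.data
    B, T, C = x.shape
    if T % 2:
        raise ValueError(f"maxpool1d needs an even length, got {T}")
    T2 = T // 2
    xr = x.reshape(B, T2, 2, C).transpose(0, 1, 3, 2)
    idx = xr.argmax(axis=3)
    out = np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]

    def bw(g):
        gz = np.zeros((B, T2, C, 2), dtype=g.dtype)
        np.put_along_axis(gz, idx[..., None], g[..., None], axis=3)
        gx = gz.transpose(0, 1, 3, 2).reshape(B, T, C)
        return (gx,)

    return Tensor(out, _parents=(t,), _bw=bw)


def upsample2d(t: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    x = t.data
    B, H, W, C = x.shape
    out = np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def bw(g):
        return (g.reshape(B, H, 2, W, 2, C).sum(axis=(2, 4)),)

    return Tensor(out, _parents=(t,), _bw=bw)


def upsample1d(t: Tensor) -> Tensor:
    x = t.data
    B, T, C = x.shape
    out = np.repeat(x, 2, axis=1)

    def bw(g):
        return (g.reshape(B, T, 2, C).sum(axis=2),)

    return Tensor(out, _parents=(t,), _bw=bw)


def bce_with_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    """Batch-mean binary cross-entropy computed stably from logits.

    Mathematically identical to -[y ln p + (1-y) ln(1-p)] with
    p = sigmoid(logits), but never forms log(0).
    """
    l = logits.data
    y = np.asarray(y, dtype=l.dtype)
    per = np.maximum(l, 0.0) - l * y + np.log1p(np.exp(-np.abs(l)))
    out = np.asarray(per.mean(), dtype=l.dtype)

    def bw(g):
        return (g * (expit(l) - y) / l.size,)

    return Tensor(out, _parents=(logits,), _bw=bw)
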