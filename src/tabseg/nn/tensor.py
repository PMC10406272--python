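"""Reverse-mode autodiff on numpy arrays.

Each `Tensor` records, for every parent it needs gradients for, a closure
mapping the output gradient to that parent's gradient contribution.
`backward()` walks the graph in reverse topological order, accumulating into
`.grad` and freeing intermediate buffers as it goes.

Convolutions use a cached gather-index im2col formulation so both the forward
pass and both backward passes are BLAS matmuls plus one bincount scatter.
"""
from __future__ import annotations

import contextlib
from typing import Callable, Optional, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference / validation passes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float32)
        self.data: np.ndarray = arr
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()

    # ---- graph construction -------------------------------------------------
    @staticmethod
    def _result(data: np.ndarray, parents: Sequence[tuple["Tensor", Callable]]) -> "Tensor":
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        if _GRAD_ENABLED:
            needed = tuple((p, fn) for p, fn in parents if p.requires_grad)
        else:
            needed = ()
        out._parents = needed
        out.requires_grad = bool(needed)
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            g = node.grad
            if g is None:
                continue
            for parent, fn in node._parents:
                contrib = fn(g)
                if parent.grad is None:
                    parent.grad = contrib
                else:
                    parent.grad = parent.grad + contrib
            if node._parents:  # free intermediate buffers
                node.grad = None
                node._parents = ()

    # ---- operators ----------------------------------------------------------
    def __add__(self, other):
        return add(self, _ensure(other))

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul(_ensure(other), -1.0))

    def __rsub__(self, other):
        return add(_ensure(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, _ensure(other))

    def __pow__(self, p):
        return power(self, p)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if len(axes) > 1 else axes[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)


def _ensure(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# ---- elementwise ------------------------------------------------------------
def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    return Tensor._result(
        a.data + b.data,
        [(a, lambda g: _unbroadcast(g, a.data.shape)),
         (b, lambda g: _unbroadcast(g, b.data.shape))],
    )


def mul(a: Tensor, b) -> Tensor:
    a = _ensure(a)
    if not isinstance(b, Tensor):
        c = float(b)
        return Tensor._result(a.data * c, [(a, lambda g: g * c)])
    return Tensor._result(
        a.data * b.data,
        [(a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
         (b, lambda g: _unbroadcast(g * a.data, b.data.shape))],
    )


def div(a: Tensor, b: Tensor) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    out = a.data / b.data
    return Tensor._result(
        out,
        [(a, lambda g: _unbroadcast(g / b.data, a.data.shape)),
         (b, lambda g: _unbroadcast(-g * out / b.data, b.data.shape))],
    )


def power(a: Tensor, p: float) -> Tensor:
    a = _ensure(a)
    p = float(p)
    out = a.data ** p
    return Tensor._result(out, [(a, lambda g: g * p * a.data ** (p - 1.0))])


def sqrt(a: Tensor) -> Tensor:
    a = _ensure(a)
    out = np.sqrt(a.data)
    return Tensor._result(out, [(a, lambda g: g * 0.5 / out)])


def relu(a: Tensor) -> Tensor:
    a = _ensure(a)
    mask = a.data > 0
    return Tensor._result(a.data * mask, [(a, lambda g: g * mask)])


def sigmoid(a: Tensor) -> Tensor:
    a = _ensure(a)
    out = 1.0 / (1.0 + np.exp(-a.data))
    return Tensor._result(out, [(a, lambda g: g * out * (1.0 - out))])


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    a = _ensure(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)

    def back(g):
        return y * (g - (g * y).sum(axis=axis, keepdims=True))

    return Tensor._result(y, [(a, back)])


def dropout(a: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0:
        return a
    a = _ensure(a)
    keep = (rng.random(a.data.shape) >= p).astype(a.data.dtype) / (1.0 - p)
    return Tensor._result(a.data * keep, [(a, lambda g: g * keep)])


# ---- reductions & shape -----------------------------------------------------
def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _ensure(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def back(g):
        if axis is None:
            return np.broadcast_to(g, a.data.shape).copy() if np.ndim(g) == 0 else np.full(a.data.shape, g)
        gg = g
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for ax in sorted(a2 % a.data.ndim for a2 in axes):
                gg = np.expand_dims(gg, ax)
        return np.broadcast_to(gg, a.data.shape)

    return Tensor._result(np.asarray(out), [(a, back)])


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _ensure(a)
    if axis is None:
        count = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        count = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(tsum(a, axis, keepdims), 1.0 / count)


def reshape(a: Tensor, shape) -> Tensor:
    a = _ensure(a)
    old = a.data.shape
    return Tensor._result(a.data.reshape(shape), [(a, lambda g: g.reshape(old))])


def transpose(a: Tensor, axes) -> Tensor:
    a = _ensure(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return Tensor._result(a.data.transpose(axes), [(a, lambda g: g.transpose(inv))])


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_ensure(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    out = np.concatenate([t.data for t in tensors], axis=axis)

    def make_back(i):
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        sl = tuple(sl)
        return lambda g: g[sl]

    return Tensor._result(out, [(t, make_back(i)) for i, t in enumerate(tensors)])


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _ensure(a), _ensure(b)

    def back_a(g):
        return _unbroadcast(np.matmul(g, np.swapaxes(b.data, -1, -2)), a.data.shape)

    def back_b(g):
        return _unbroadcast(np.matmul(np.swapaxes(a.data, -1, -2), g), b.data.shape)

    return Tensor._result(np.matmul(a.data, b.data), [(a, back_a), (b, back_b)])


# ---- 3D convolution ---------------------------------------------------------
_IDX_CACHE: dict = {}


def _conv_idx(padded_spatial: tuple[int, int, int], k: int, stride: int):
    """Gather indices: idx[p, kk] = flat index into the padded spatial grid."""
    key = (padded_spatial, k, stride)
    hit = _IDX_CACHE.get(key)
    if hit is not None:
        return hit
    dp, hp, wp = padded_spatial
    out_shape = tuple((s - k) // stride + 1 for s in padded_spatial)
    od, oh, ow = out_shape
    d0 = np.arange(od) * stride
    h0 = np.arange(oh) * stride
    w0 = np.arange(ow) * stride
    starts = (
        d0[:, None, None] * (hp * wp) + h0[None, :, None] * wp + w0[None, None, :]
    ).ravel()
    kd, kh, kw = np.meshgrid(np.arange(k), np.arange(k), np.arange(k), indexing="ij")
    koff = (kd * (hp * wp) + kh * wp + kw).ravel()
    idx = (koff[:, None] + starts[None, :]).astype(np.int64)  # (K, P)
    _IDX_CACHE[key] = (idx, out_shape)
    return idx, out_shape


def _conv3d_forward(x: np.ndarray, w: np.ndarray, stride: int, pad: int):
    n, cin = x.shape[:2]
    cout = w.shape[0]
    k = w.shape[2]
    xp = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3) if pad else x
    padded_spatial = xp.shape[2:]
    idx, out_shape = _conv_idx(padded_spatial, k, stride)
    k3, p_count = idx.shape
    # gather directly into (N, C, K, P): fancy indexing yields a contiguous
    # array, so the following reshape to (N, C*K, P) is free
    cols = xp.reshape(n, cin, -1)[:, :, idx].reshape(n, cin * k3, p_count)
    out = np.matmul(w.reshape(cout, cin * k3), cols)    # (N, Cout, P)
    return out.reshape(n, cout, *out_shape), cols, padded_spatial


def _conv3d_input_grad(
    gout: np.ndarray,
    w: np.ndarray,
    in_spatial: tuple[int, int, int],
    stride: int,
    pad: int,
) -> np.ndarray:
    n = gout.shape[0]
    cout, cin, k = w.shape[0], w.shape[1], w.shape[2]
    padded_spatial = tuple(s + 2 * pad for s in in_spatial)
    idx, out_shape = _conv_idx(padded_spatial, k, stride)
    k3, p_count = idx.shape
    g2 = gout.reshape(n, cout, p_count)
    gcols = np.matmul(w.reshape(cout, cin * k3).T, g2)  # (N, C*K, P)
    gcols = gcols.reshape(n, cin, k3 * p_count)
    flat_idx = idx.ravel()                               # (K*P,) matches gcols layout
    nvox = int(np.prod(padded_spatial))
    gxp = np.empty((n, cin, nvox), dtype=gout.dtype)
    for ni in range(n):
        for ci in range(cin):
            gxp[ni, ci] = np.bincount(
                flat_idx, weights=gcols[ni, ci], minlength=nvox
            )
    gxp = gxp.reshape(n, cin, *padded_spatial)
    if pad:
        sl = (slice(None), slice(None)) + (slice(pad, -pad),) * 3
        gxp = gxp[sl]
    return np.ascontiguousarray(gxp)


def _conv3d_weight_grad(gout: np.ndarray, cols: np.ndarray, w_shape) -> np.ndarray:
    n, cout = gout.shape[:2]
    g2 = gout.reshape(n, cout, -1)
    gw = np.tensordot(g2, cols, axes=([0, 2], [0, 2]))   # (Cout, Cin*K)
    return gw.reshape(w_shape)


def conv3d(x: Tensor, w: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """3D cross-correlation; w has shape (Cout, Cin, k, k, k)."""
    x, w = _ensure(x), _ensure(w)
    out, cols, _ = _conv3d_forward(x.data, w.data, stride, pad)
    in_spatial = x.data.shape[2:]

    def back_x(g):
        return _conv3d_input_grad(g, w.data, in_spatial, stride, pad)

    def back_w(g):
        return _conv3d_weight_grad(g, cols, w.data.shape)

    return Tensor._result(out, [(x, back_x), (w, back_w)])


def conv_transpose3d(x: Tensor, w: Tensor, stride: int = 2) -> Tensor:
    """Transposed 3D convolution (exact adjoint of `conv3d` with pad=0).

    w has shape (Cin, Cout, k, k, k); output side = (in-1)*stride + k.
    """
    x, w = _ensure(x), _ensure(w)
    k = w.data.shape[2]
    in_spatial = x.data.shape[2:]
    out_spatial = tuple((s - 1) * stride + k for s in in_spatial)
    out = _conv3d_input_grad(x.data, w.data, out_spatial, stride, 0)

    def back_x(g):
        o, _, _ = _conv3d_forward(g, w.data, stride, 0)
        return o

    def back_w(g):
        _, gcols, _ = _conv3d_forward(g, w.data, stride, 0)
        return _conv3d_weight_grad(x.data, gcols, w.data.shape)

    return Tensor._result(out, [(x, back_x), (w, back_w)])
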