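"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The package's network is small enough that a dedicated tape-based
engine is simpler and more transparent than a deep-learning framework
dependency. A :class:`Tensor` wraps an ``ndarray`` and records the
operations producing it; :meth:`Tensor.backward` runs the reverse
sweep in topological order. Only the operations the network needs are
implemented: broadcast arithmetic, matmul, ReLU, softmax, spatial
mean, channel concatenation, reflection padding, 2-D convolution
(strided), transposed convolution, and 3x3 stride-1 max pooling.

Convolutions are computed as a single GEMM over an im2col matrix; the
backward pass recomputes the im2col lazily instead of caching it, so
inference-scale forward passes do not hold multi-GB column matrices.
A module-level switch (:func:`no_grad`) disables graph recording for
inference.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """An ndarray plus the tape node that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward: Callable | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents if _GRAD_ENABLED else ()
        self._backward = _backward if _GRAD_ENABLED else None

    # -- basic protocol -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'yes' if self.requires_grad else 'no'})"

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse sweep from this tensor (defaults to d(self)/d(self)=1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs here can be thousands of nodes
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
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node is not self and node._parents:
                node.grad = None  # free intermediate grads early

    # -- operators ------------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other, self.dtype))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other, self.dtype))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_wrap(other, self.dtype), _const(-1.0, self.dtype)))

    def __rsub__(self, other):
        return add(_wrap(other, self.dtype), mul(self, _const(-1.0, self.dtype)))

    def __neg__(self):
        return mul(self, _const(-1.0, self.dtype))

    def __matmul__(self, other):
        return matmul(self, _wrap(other, self.dtype))


def _wrap(x, dtype) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _const(v, dtype) -> Tensor:
    return Tensor(np.asarray(v, dtype=dtype))


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _node(data, parents: Iterable[Tensor], backward: Callable | None) -> Tensor:
    parents = tuple(parents)
    req = any(p.requires_grad or p._parents for p in parents)
    if not (_GRAD_ENABLED and req):
        return Tensor(data)
    return Tensor(data, _parents=parents, _backward=backward)


# ---------------------------------------------------------------------
# elementwise / reduction ops
# ---------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _node(out_data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        x._accumulate(g * mask)

    return _node(out_data, (x,), backward)


def abs_(x: Tensor) -> Tensor:
    sign = np.sign(x.data)
    out_data = np.abs(x.data)

    def backward(g):
        x._accumulate(g * sign)

    return _node(out_data, (x,), backward)


def sum_(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            x._accumulate(np.broadcast_to(g, x.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        x._accumulate(np.broadcast_to(g, x.data.shape).copy())

    return _node(out_data, (x,), backward)


def mean_(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = x.data.size if axis is None else np.prod(
        [x.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(sum_(x, axis=axis, keepdims=keepdims), _const(1.0 / n, x.dtype))


def square(x: Tensor) -> Tensor:
    return mul(x, x)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accumulate(s * (g - dot))

    return _node(s, (x,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        a._accumulate(_unbroadcast(ga, a.data.shape))
        b._accumulate(_unbroadcast(gb, b.data.shape))

    return _node(out_data, (a, b), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return _node(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------
# spatial ops on NCHW feature maps
# ---------------------------------------------------------------------

def _reflect_index(n: int, pad: int) -> np.ndarray:
    """Source index for each position of a reflect-padded axis.

    Uses the periodic fold of true reflection (no edge repeat), which
    stays valid for pads exceeding ``n - 1``; a length-1 axis degrades
    to replication.
    """
    if n == 1:
        return np.zeros(1 + 2 * pad, dtype=int)
    idx = np.mod(np.arange(-pad, n + pad), 2 * (n - 1))
    return np.where(idx >= n, 2 * (n - 1) - idx, idx)


def reflect_pad2d(x: Tensor, pad: int) -> Tensor:
    if pad == 0:
        return x
    N, C, H, W = x.data.shape
    rmap = _reflect_index(H, pad)
    cmap = _reflect_index(W, pad)
    out_data = x.data[:, :, rmap][:, :, :, cmap]

    def backward(g):
        # fold padded gradients back onto their mirrored sources
        tmp = np.zeros((N, C, H, W + 2 * pad), dtype=g.dtype)
        gm = np.moveaxis(g, 2, 0)
        tmpm = np.moveaxis(tmp, 2, 0)
        np.add.at(tmpm, rmap, gm)
        dx = np.zeros((N, C, H, W), dtype=g.dtype)
        tm = np.moveaxis(tmp, 3, 0)
        dxm = np.moveaxis(dx, 3, 0)
        np.add.at(dxm, cmap, tm)
        x._accumulate(dx)

    return _node(out_data, (x,), backward)


def reshape(x: Tensor, shape) -> Tensor:
    out_data = x.data.reshape(shape)

    def backward(g):
        x._accumulate(g.reshape(x.data.shape))

    return _node(out_data, (x,), backward)


def getitem(x: Tensor, idx) -> Tensor:
    """Basic (slice/int) indexing with scatter backward."""
    out_data = x.data[idx]

    def backward(g):
        dx = np.zeros_like(x.data)
        dx[idx] = g
        x._accumulate(dx)

    return _node(out_data, (x,), backward)


def zero_pad2d(x: Tensor, pad: int) -> Tensor:
    if pad == 0:
        return x
    out_data = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))

    def backward(g):
        x._accumulate(g[:, :, pad:-pad, pad:-pad])

    return _node(out_data, (x,), backward)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> tuple[np.ndarray, int, int]:
    """(N, C, H, W) -> (N * Ho * Wo, C * kh * kw) columns plus (Ho, Wo)."""
    N, C, H, W = x.shape
    Ho = (H - kh) // stride + 1
    Wo = (W - kw) // stride + 1
    v = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    v = v[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, kh, kw)
    cols = np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5))
    return cols.reshape(N * Ho * Wo, C * kh * kw), Ho, Wo


def _col2im(dcols: np.ndarray, x_shape: tuple, kh: int, kw: int, stride: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add back into image layout)."""
    N, C, H, W = x_shape
    Ho = (H - kh) // stride + 1
    Wo = (W - kw) // stride + 1
    d = dcols.reshape(N, Ho, Wo, C, kh, kw)
    dx = np.zeros(x_shape, dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += \
                d[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """Valid (unpadded) 2-D convolution; pad beforehand as needed.

    ``w`` has shape (C_out, C_in, kh, kw); ``b`` shape (C_out,). The
    kernel is applied in cross-correlation orientation, the standard
    CNN convention.
    """
    N, C, H, W = x.data.shape
    Co, Ci, kh, kw = w.data.shape
    if Ci != C:
        raise ValueError(f"channel mismatch: input has {C}, kernel expects {Ci}")
    cols, Ho, Wo = _im2col(x.data, kh, kw, stride)
    wmat = w.data.reshape(Co, Ci * kh * kw).T
    out = cols @ wmat
    if b is not None:
        out += b.data[None, :]
    out_data = out.reshape(N, Ho, Wo, Co).transpose(0, 3, 1, 2)

    def backward(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, Co)
        cols_again, _, _ = _im2col(x.data, kh, kw, stride)  # recompute, not cached
        w._accumulate((cols_again.T @ g2).T.reshape(w.data.shape))
        if b is not None:
            b._accumulate(g2.sum(axis=0))
        dcols = g2 @ wmat.T
        x._accumulate(_col2im(dcols, x.data.shape, kh, kw, stride))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 2, padding: int = 1,
                     output_padding: int = 1) -> Tensor:
    """Transposed convolution (fractionally strided), NCHW.

    ``w`` has shape (C_in, C_out, kh, kw). With kernel 3, stride 2,
    padding 1 and output_padding 1 the spatial size exactly doubles.
    Forward is the adjoint of a strided convolution, implemented with
    the same col2im/im2col pair as :func:`conv2d`.
    """
    N, C, H, W = x.data.shape
    Ci, Co, kh, kw = w.data.shape
    if Ci != C:
        raise ValueError(f"channel mismatch: input has {C}, kernel expects {Ci}")
    Hp = (H - 1) * stride + kh + output_padding  # padded output height
    Wp = (W - 1) * stride + kw + output_padding
    Ho = Hp - 2 * padding
    Wo = Wp - 2 * padding
    wmat = w.data.reshape(C, Co * kh * kw)
    xflat = np.ascontiguousarray(x.data.transpose(0, 2, 3, 1)).reshape(-1, C)
    dcols = xflat @ wmat
    full = _col2im(dcols, (N, Co, Hp, Wp), kh, kw, stride)
    out_data = full[:, :, padding:padding + Ho, padding:padding + Wo]
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def backward(g):
        gfull = np.zeros((N, Co, Hp, Wp), dtype=g.dtype)
        gfull[:, :, padding:padding + Ho, padding:padding + Wo] = g
        gcols, _, _ = _im2col(gfull, kh, kw, stride)  # (N*H*W, Co*kh*kw)
        x._accumulate((gcols @ wmat.T).reshape(N, H, W, C).transpose(0, 3, 1, 2))
        w._accumulate((xflat.T @ gcols).reshape(w.data.shape))
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, backward)


def maxpool2d_3x3(x: Tensor) -> Tensor:
    """3x3 max pooling with stride 1 and padding 1 (spatial size kept)."""
    N, C, H, W = x.data.shape
    neg = np.array(-np.inf, dtype=x.data.dtype)
    padded = np.full((N, C, H + 2, W + 2), neg)
    padded[:, :, 1:-1, 1:-1] = x.data
    stack = np.stack([
        padded[:, :, 1 + dr:1 + dr + H, 1 + dc:1 + dc + W]
        for dr in (-1, 0, 1) for dc in (-1, 0, 1)
    ])  # (9, N, C, H, W)
    arg = stack.argmax(axis=0)
    out_data = np.take_along_axis(stack, arg[None], axis=0)[0]

    def backward(g):
        dx = np.zeros_like(x.data)
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)]
        dpad = np.zeros((N, C, H + 2, W + 2), dtype=g.dtype)
        for k, (dr, dc) in enumerate(offsets):
            m = arg == k
            if m.any():
                dpad[:, :, 1 + dr:1 + dr + H, 1 + dc:1 + dc + W] += g * m
        dx += dpad[:, :, 1:-1, 1:-1]
        x._accumulate(dx)

    return _node(out_data, (x,), backward)


def spatial_mean(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C): per-channel spatial average."""
    if x.data.ndim != 4 or x.data.shape[2] * x.data.shape[3] == 0:
        raise ValueError("expected a nonempty NCHW feature map")
    N, C, H, W = x.data.shape
    out_data = x.data.mean(axis=(2, 3))

    def backward(g):
        x._accumulate(np.broadcast_to(g[:, :, None, None] / (H * W), x.data.shape).copy())

    return _node(out_data, (x,), backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """(N, K) @ (K, M) + (M,)."""
    out = matmul(x, w)
    if b is not None:
        out = add(out, b)
    return out
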