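"""Reverse-mode automatic differentiation on numpy arrays.

A compact tape-based engine sufficient for small convolutional networks on
CPU: every op records a closure that accumulates gradients into its inputs;
``Tensor.backward`` runs the tape in reverse topological order.  Convolutions
use im2col and express their input gradient as a second correlation with the
flipped kernel, so no scatter-add is needed on the hot path.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._conv_kernels import HAVE_NUMBA, conv3x3_fwd, conv3x3_gradw

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data)
            if data.dtype.kind != "f":
                data = data.astype(DTYPE)
        self.data = data
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = ()

    # -- infrastructure ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True) \
                if np.ndim(g) else np.full_like(self.data, g)
        else:
            self.grad += g

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic -------------------------------------------------------

    def _coerce(self, other):
        return other if isinstance(other, Tensor) else Tensor(
            np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        other = self._coerce(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.shape))

        return Tensor._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data ** p, (self,), bwd)

    # -- reductions and elementwise ---------------------------------------

    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy()
                            if np.ndim(g) else np.full_like(self.data, g))
            else:
                gg = g
                if not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bwd)

    def reshape(self, *shape):
        old = self.shape

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), bwd)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))

        return Tensor._make(self.data.transpose(*axes), (self,), bwd)

    def __getitem__(self, idx):
        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[idx] = g
                self._accum(full)

        return Tensor._make(self.data[idx], (self,), bwd)

    def matmul(self, other: "Tensor"):
        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), bwd)


# -- structured ops --------------------------------------------------------


def concat(tensors, axis: int = 1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, bwd)


def stack_sum(tensors) -> Tensor:
    """Elementwise sum of same-shaped tensors."""
    def bwd(g):
        for t in tensors:
            if t.requires_grad:
                t._accum(g)

    return Tensor._make(sum(t.data for t in tensors), tensors, bwd)


def softmax(x: Tensor, axis: int) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def l2_normalize(x: Tensor, axis: int = 1, eps: float = 1e-12) -> Tensor:
    norm = ((x * x).sum(axis=axis, keepdims=True) + eps).sqrt()
    return x / norm


def global_avg_pool(x: Tensor) -> Tensor:
    """[B,C,H,W] -> [B,C] spatial mean."""
    return x.mean(axis=(2, 3))


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling; H and W must be even."""
    B, C, H, W = x.shape
    out_data = x.data.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def bwd(g):
        if x.requires_grad:
            x._accum(np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25)

    return Tensor._make(out_data, (x,), bwd)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    B, C, H, W = x.shape
    out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def bwd(g):
        if x.requires_grad:
            x._accum(g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)))

    return Tensor._make(out_data, (x,), bwd)


def _corr2d(x: np.ndarray, wmat: np.ndarray, kh: int, kw: int,
            pad: int) -> np.ndarray:
    """Raw cross-correlation: x [B,C,H,W], wmat [Cout, C*kh*kw] -> [B,Cout,Ho,Wo]."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    B, C, H, W = x.shape
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # B,C,Ho,Wo,kh,kw
    Ho, Wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * kh * kw)
    out = cols @ wmat.T
    return out.reshape(B, Ho, Wo, -1).transpose(0, 3, 1, 2), cols


def _conv1x1(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Pointwise convolution as a channel matmul (no window materialisation)."""
    Cout, Cin = w.shape[:2]
    wmat = w.data.reshape(Cout, Cin)
    out_data = np.tensordot(wmat, x.data, axes=([1], [1])).swapaxes(0, 1)
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        if w.requires_grad:
            gw = np.tensordot(g, x.data, axes=([0, 2, 3], [0, 2, 3]))
            w._accum(gw.reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accum(np.tensordot(wmat.T, g, axes=([1], [1])).swapaxes(0, 1))

    return Tensor._make(out_data, parents, bwd)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, pad: int) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation) with zero padding.

    w has shape [Cout, Cin, kh, kw]; output spatial size H+2p-kh+1.
    """
    Cout, Cin, kh, kw = w.shape
    if kh == 1 and kw == 1 and pad == 0:
        return _conv1x1(x, w, b)
    if kh == 3 and kw == 3 and HAVE_NUMBA and x.data.dtype == np.float32 \
            and w.data.dtype == np.float32:
        return _conv3x3_jit(x, w, b, pad)
    wmat = w.data.reshape(Cout, Cin * kh * kw)
    out_data, cols = _corr2d(x.data, wmat, kh, kw, pad)
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        B, _, Ho, Wo = g.shape
        gmat = g.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, Cout)
        if w.requires_grad:
            w._accum((gmat.T @ cols).reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # full correlation of g with the flipped, channel-transposed kernel
            wflip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            wflip_mat = np.ascontiguousarray(wflip).reshape(Cin, Cout * kh * kw)
            gx, _ = _corr2d(g, wflip_mat, kh, kw, kh - 1)
            p = kh - 1 - pad
            if p > 0:
                gx = gx[:, :, p:-p, p:-p]
            x._accum(gx)

    return Tensor._make(out_data, parents, bwd)


def _conv3x3_jit(x: Tensor, w: Tensor, b: Tensor | None, pad: int) -> Tensor:
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad \
        else x.data
    out_data = conv3x3_fwd(xp, w.data)
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        g = np.ascontiguousarray(g, dtype=np.float32)
        if w.requires_grad:
            w._accum(conv3x3_gradw(xp, g))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            wflip = np.ascontiguousarray(
                w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
            gp = np.pad(g, ((0, 0), (0, 0), (2, 2), (2, 2)))
            gx = conv3x3_fwd(gp, wflip)
            p = 2 - pad
            if p > 0:
                gx = gx[:, :, p:-p, p:-p]
            x._accum(gx)

    return Tensor._make(out_data, parents, bwd)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, mean: np.ndarray,
               var: np.ndarray, eps: float, batch_stats: bool) -> Tensor:
    """Channel batch normalisation as one fused op.

    With batch_stats=True, mean/var are the already-computed statistics of
    x over (B, H, W) and the backward pass uses the full batch-norm
    gradient; otherwise they are running statistics treated as constants.
    """
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, -1, 1, 1)) * inv_std.reshape(1, -1, 1, 1)
    out_data = xhat * gamma.data.reshape(1, -1, 1, 1) \
        + beta.data.reshape(1, -1, 1, 1)

    def bwd(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        gd = gamma.data.reshape(1, -1, 1, 1)
        if not batch_stats:
            x._accum(g * gd * inv_std.reshape(1, -1, 1, 1))
            return
        n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        dxhat = g * gd
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        x._accum((dxhat - s1 / n - xhat * s2 / n)
                 * inv_std.reshape(1, -1, 1, 1))

    return Tensor._make(out_data, (x, gamma, beta), bwd)


def gather_pixels(x: Tensor, index: np.ndarray) -> Tensor:
    """Gather spatial columns of a [B,C,H,W] tensor.

    index is an integer array [A,3] of (batch, row, col); output is [A,C].
    """
    b, r, c = index[:, 0], index[:, 1], index[:, 2]
    out_data = x.data[b, :, r, c]

    def bwd(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            np.add.at(full, (b, slice(None), r, c), g)
            x._accum(full)

    return Tensor._make(out_data, (x,), bwd)
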