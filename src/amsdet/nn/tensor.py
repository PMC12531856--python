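"""Reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float32 ``numpy.ndarray`` together with an optional
gradient and a closure that propagates incoming gradients to its parents.
Calling :meth:`Tensor.backward` on a scalar loss walks the recorded graph in
reverse topological order.  The op set is deliberately small: exactly what a
convolutional detector with attention needs (convolution, batch norm, pooling,
matmul/softmax, elementwise algebra, gather/concat plumbing).

Convolution uses im2col plus a single BLAS matmul per call; the column matrix
is rebuilt during backward instead of cached, trading a strided copy for a
much smaller peak memory footprint.
"""

from __future__ import annotations

import contextlib

import numpy as np

from . import _kernels as _K

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference/decoding)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _as_f32(x):
    a = np.asarray(x, dtype=np.float32)
    return a


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = _as_f32(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def param(data):
        return Tensor(data, requires_grad=True)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self):
        return Tensor(self.data)

    def numpy(self):
        return self.data

    # -- graph machinery ------------------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True) if g.base is not None or g.dtype != np.float32 else g.copy()
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node is not self and not node.requires_grad:
                # free intermediate grads eagerly; parents already updated
                pass

    # -- operator sugar -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return mul(self, pow_(other, -1.0)) if isinstance(other, Tensor) else mul(self, 1.0 / other)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return pow_(self, p)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis, keepdims)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_graph(*ts):
    return _GRAD_ENABLED and any(isinstance(t, Tensor) and (t.requires_grad or t._parents or t._backward) for t in ts)


def _make(data, parents, backward, track):
    if not track:
        return Tensor(data)
    return Tensor(data, parents=tuple(parents), backward=backward)


def _unbroadcast(g, shape):
    """Sum gradient ``g`` down to ``shape`` (reverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# -- elementwise ops ----------------------------------------------------------

def add(a, b):
    a, b = _wrap(a), _wrap(b)
    track = _needs_graph(a, b)
    out_data = a.data + b.data

    def bw(g):
        if a.requires_grad or a._parents or a._backward:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad or b._parents or b._backward:
            b._accum(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), bw, track)


def mul(a, b):
    a, b = _wrap(a), _wrap(b)
    track = _needs_graph(a, b)
    out_data = a.data * b.data

    def bw(g):
        if a.requires_grad or a._parents or a._backward:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad or b._parents or b._backward:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), bw, track)


def pow_(a, p):
    a = _wrap(a)
    track = _needs_graph(a)
    out_data = a.data ** p

    def bw(g):
        a._accum(g * (p * a.data ** (p - 1.0)))

    return _make(out_data, (a,), bw, track)


def exp(a):
    a = _wrap(a)
    track = _needs_graph(a)
    out_data = np.exp(a.data)

    def bw(g):
        a._accum(g * out_data)

    return _make(out_data, (a,), bw, track)


def log(a, eps=0.0):
    a = _wrap(a)
    track = _needs_graph(a)
    out_data = np.log(a.data + eps)

    def bw(g):
        a._accum(g / (a.data + eps))

    return _make(out_data, (a,), bw, track)


def sqrt(a):
    return pow_(a, 0.5)


def atan(a):
    a = _wrap(a)
    track = _needs_graph(a)
    out_data = np.arctan(a.data)

    def bw(g):
        a._accum(g / (1.0 + a.data * a.data))

    return _make(out_data, (a,), bw, track)


def sigmoid(a):
    a = _wrap(a)
    track = _needs_graph(a)
    with np.errstate(over="ignore"):
        out_data = 1.0 / (1.0 + np.exp(-a.data))

    def bw(g):
        a._accum(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), bw, track)


def silu(a):
    a = _wrap(a)
    track = _needs_graph(a)
    if _K.HAVE_NUMBA and a.data.flags.c_contiguous:
        out_data = _K.silu_fwd(a.data)

        def bw(g):
            a._accum(_K.silu_bwd(a.data, np.ascontiguousarray(g)))

        return _make(out_data, (a,), bw, track)
    s = 1.0 / (1.0 + np.exp(-a.data))
    out_data = a.data * s

    def bw(g):
        a._accum(g * (s * (1.0 + a.data * (1.0 - s))))

    return _make(out_data, (a,), bw, track)


def clip(a, lo, hi):
    """Clamp with straight-through-zero gradient outside [lo, hi]."""
    a = _wrap(a)
    track = _needs_graph(a)
    out_data = np.clip(a.data, lo, hi)
    mask = (a.data >= lo) & (a.data <= hi)

    def bw(g):
        a._accum(g * mask)

    return _make(out_data, (a,), bw, track)


def minimum(a, b):
    a, b = _wrap(a), _wrap(b)
    track = _needs_graph(a, b)
    take_a = a.data <= b.data
    out_data = np.where(take_a, a.data, b.data)

    def bw(g):
        if a.requires_grad or a._parents or a._backward:
            a._accum(_unbroadcast(g * take_a, a.data.shape))
        if b.requires_grad or b._parents or b._backward:
            b._accum(_unbroadcast(g * (~take_a), b.data.shape))

    return _make(out_data, (a, b), bw, track)


def maximum(a, b):
    a, b = _wrap(a), _wrap(b)
    track = _needs_graph(a, b)
    take_a = a.data >= b.data
    out_data = np.where(take_a, a.data, b.data)

    def bw(g):
        if a.requires_grad or a._parents or a._backward:
            a._accum(_unbroadcast(g * take_a, a.data.shape))
        if b.requires_grad or b._parents or b._backward:
            b._accum(_unbroadcast(g * (~take_a), b.data.shape))

    return _make(out_data, (a, b), bw, track)


# -- reductions / shape ops ---------------------------------------------------

def sum_(a, axis=None, keepdims=False):
    a = _wrap(a)
    track = _needs_graph(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.data.shape).astype(np.float32))

    return _make(out_data, (a,), bw, track)


def mean_(a, axis=None, keepdims=False):
    a = _wrap(a)
    n = a.data.size if axis is None else np.prod([a.data.shape[i] for i in np.atleast_1d(axis)])
    return mul(sum_(a, axis, keepdims), 1.0 / float(n))


def reshape(a, shape):
    a = _wrap(a)
    track = _needs_graph(a)
    out_data = a.data.reshape(shape)

    def bw(g):
        a._accum(g.reshape(a.data.shape))

    return _make(out_data, (a,), bw, track)


def transpose(a, axes):
    a = _wrap(a)
    track = _needs_graph(a)
    out_data = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def bw(g):
        a._accum(np.transpose(g, inv))

    return _make(out_data, (a,), bw, track)


def concat(tensors, axis=1):
    tensors = [_wrap(t) for t in tensors]
    track = _needs_graph(*tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, s, e in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad or t._parents or t._backward:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(s, e)
                t._accum(g[tuple(idx)])

    return _make(out_data, tuple(tensors), bw, track)


def narrow(a, axis, start, length):
    """Contiguous slice along ``axis`` (used for channel splits)."""
    a = _wrap(a)
    track = _needs_graph(a)
    idx = [slice(None)] * a.data.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    out_data = a.data[idx]

    def bw(g):
        full = np.zeros_like(a.data)
        full[idx] = g
        a._accum(full)

    return _make(out_data, (a,), bw, track)


def gather_rows(a, index):
    """Select rows ``a[index]`` along the first axis (integer array index)."""
    a = _wrap(a)
    track = _needs_graph(a)
    out_data = a.data[index]

    def bw(g):
        full = np.zeros_like(a.data)
        np.add.at(full, index, g)
        a._accum(full)

    return _make(out_data, (a,), bw, track)


def softmax(a, axis=-1):
    a = _wrap(a)
    track = _needs_graph(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        a._accum(out_data * (g - dot))

    return _make(out_data, (a,), bw, track)


def matmul(a, b):
    a, b = _wrap(a), _wrap(b)
    track = _needs_graph(a, b)
    out_data = np.matmul(a.data, b.data)

    def bw(g):
        if a.requires_grad or a._parents or a._backward:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad or b._parents or b._backward:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accum(_unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), bw, track)


# -- spatial ops --------------------------------------------------------------

def _pad_nchw(x, pt, pb, pl, pr):
    if pt == pb == pl == pr == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))


def _im2col(xp, k, stride, ho, wo):
    b, c, hp, wp = xp.shape
    sb, sc, sh, sw = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, shape=(b, c, k, k, ho, wo),
        strides=(sb, sc, sh, sw, sh * stride, sw * stride), writeable=False)
    return np.ascontiguousarray(view).reshape(b, c * k * k, ho * wo)


def conv2d(x, w, bias=None, stride=1, padding=0):
    """2-D convolution, NCHW layout, symmetric zero padding."""
    x, w = _wrap(x), _wrap(w)
    if bias is not None:
        bias = _wrap(bias)
    track = _needs_graph(x, w, bias)
    b, ci, h, wd = x.data.shape
    co, ci_w, k, _ = w.data.shape
    if ci != ci_w:
        raise ValueError(f"conv2d channel mismatch: input {ci} vs weight {ci_w}")
    ho = (h + 2 * padding - k) // stride + 1
    wo = (wd + 2 * padding - k) // stride + 1
    if k == 1 and stride == 1 and padding == 0:
        # pointwise fast path: no column matrix, a single batched GEMM
        xmat = np.ascontiguousarray(x.data).reshape(b, ci, h * wd)
        wmat = w.data.reshape(co, ci)
        out = np.matmul(wmat, xmat)
        if bias is not None:
            out += bias.data.reshape(1, co, 1)
        out_data = out.reshape(b, co, h, wd)

        def bw1(g):
            gmat = g.reshape(b, co, h * wd)
            if w.requires_grad or w._parents or w._backward:
                gw = np.matmul(gmat, xmat.transpose(0, 2, 1)).sum(axis=0)
                w._accum(gw.reshape(w.data.shape))
            if bias is not None and (bias.requires_grad or bias._parents or bias._backward):
                bias._accum(gmat.sum(axis=(0, 2)))
            if x.requires_grad or x._parents or x._backward:
                gx = np.matmul(wmat.T, gmat).reshape(b, ci, h, wd)
                x._accum(gx)

        return _make(out_data, tuple(t for t in (x, w, bias) if t is not None), bw1, track)
    xp = _pad_nchw(x.data, padding, padding, padding, padding)
    cols = _im2col(xp, k, stride, ho, wo)
    wmat = w.data.reshape(co, ci * k * k)
    out = np.matmul(wmat, cols)  # (b, co, ho*wo) via broadcasting
    if bias is not None:
        out += bias.data.reshape(1, co, 1)
    out_data = out.reshape(b, co, ho, wo)

    def bw(g):
        gmat = g.reshape(b, co, ho * wo)
        if w.requires_grad or w._parents or w._backward:
            gw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accum(gw.reshape(w.data.shape))
        if bias is not None and (bias.requires_grad or bias._parents or bias._backward):
            bias._accum(gmat.sum(axis=(0, 2)))
        if x.requires_grad or x._parents or x._backward:
            dcols = np.matmul(wmat.T, gmat).reshape(b, ci, k, k, ho, wo)
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += dcols[:, :, i, j]
            if padding:
                dxp = dxp[:, :, padding:padding + h, padding:padding + wd]
            x._accum(dxp)

    return _make(out_data, tuple(t for t in (x, w, bias) if t is not None), bw, track)


def depthwise_conv2d(x, w, stride=1, padding=0):
    """Depthwise convolution: weight (C, 1, k, k), one kernel per channel."""
    x, w = _wrap(x), _wrap(w)
    track = _needs_graph(x, w)
    b, c, h, wd = x.data.shape
    k = w.data.shape[-1]
    ho = (h + 2 * padding - k) // stride + 1
    wo = (wd + 2 * padding - k) // stride + 1
    xp = _pad_nchw(x.data, padding, padding, padding, padding)
    wr = w.data.reshape(c, k, k)
    out_data = np.zeros((b, c, ho, wo), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            out_data += xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] \
                * wr[None, :, i, j, None, None]

    def bw(g):
        if w.requires_grad or w._parents or w._backward:
            gw = np.empty((c, k, k), dtype=np.float32)
            for i in range(k):
                for j in range(k):
                    gw[:, i, j] = (g * xp[:, :, i:i + stride * ho:stride,
                                          j:j + stride * wo:stride]).sum(axis=(0, 2, 3))
            w._accum(gw.reshape(w.data.shape))
        if x.requires_grad or x._parents or x._backward:
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                        g * wr[None, :, i, j, None, None]
            if padding:
                dxp = dxp[:, :, padding:padding + h, padding:padding + wd]
            x._accum(dxp)

    return _make(out_data, (x, w), bw, track)


def conv1d_channels(x, w, bias=None):
    """1-D convolution along the channel axis with zero padding k//2.

    ``x`` has shape (..., C); the kernel ``w`` has shape (k,) and slides over
    the channel dimension, the same cross-channel mixing used by efficient
    channel attention.
    """
    x, w = _wrap(x), _wrap(w)
    if bias is not None:
        bias = _wrap(bias)
    track = _needs_graph(x, w, bias)
    k = w.data.shape[0]
    p = k // 2
    c = x.data.shape[-1]
    xp = np.pad(x.data, [(0, 0)] * (x.data.ndim - 1) + [(p, p)])
    out = np.zeros_like(x.data)
    for i in range(k):
        out += w.data[i] * xp[..., i:i + c]
    if bias is not None:
        out = out + bias.data

    def bw(g):
        if w.requires_grad or w._parents or w._backward:
            gw = np.array([(g * xp[..., i:i + c]).sum() for i in range(k)], dtype=np.float32)
            w._accum(gw)
        if bias is not None and (bias.requires_grad or bias._parents or bias._backward):
            bias._accum(np.array(g.sum(), dtype=np.float32).reshape(bias.data.shape))
        if x.requires_grad or x._parents or x._backward:
            gp = np.pad(g, [(0, 0)] * (g.ndim - 1) + [(p, p)])
            gx = np.zeros_like(x.data)
            for i in range(k):
                gx += w.data[i] * gp[..., k - 1 - i:k - 1 - i + c]
            x._accum(gx)

    return _make(out, tuple(t for t in (x, w, bias) if t is not None), bw, track)


def batch_norm(x, gamma, beta, running_mean, running_var, training, momentum=0.03, eps=1e-3):
    """Batch normalization over (N, H, W) per channel, NCHW layout.

    ``running_mean``/``running_var`` are plain numpy arrays updated in place
    during training (exponential moving average, torch convention).
    """
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    track = _needs_graph(x, gamma, beta)
    c = x.data.shape[1]
    axes = (0, 2, 3)
    use_numba = _K.HAVE_NUMBA and x.data.flags.c_contiguous
    if training:
        if use_numba:
            mu, var = _K.bn_stats(x.data)
        else:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
        n = x.data.size / c
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mu, var = running_mean, running_var
    mu = np.asarray(mu, dtype=np.float32)
    inv = (1.0 / np.sqrt(var + eps)).astype(np.float32)
    if use_numba:
        out_data = _K.bn_apply(x.data, mu, inv, gamma.data, beta.data)

        def bw(g):
            gx, ggamma, gbeta = _K.bn_bwd(x.data, np.ascontiguousarray(g),
                                          mu, inv, gamma.data, training)
            if gamma.requires_grad:
                gamma._accum(ggamma)
            if beta.requires_grad:
                beta._accum(gbeta)
            if x.requires_grad or x._parents or x._backward:
                x._accum(gx)

        return _make(out_data, (x, gamma, beta), bw, track)
    mu_r = mu.reshape(1, c, 1, 1)
    inv_r = inv.reshape(1, c, 1, 1)
    xhat = (x.data - mu_r) * inv_r
    out_data = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    def bw(g):
        if gamma.requires_grad or gamma._parents or gamma._backward:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad or beta._parents or beta._backward:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad or x._parents or x._backward:
            gx_hat = g * gamma.data.reshape(1, c, 1, 1)
            if training:
                n = x.data.size / c
                s1 = gx_hat.sum(axis=axes, keepdims=True)
                s2 = (gx_hat * xhat).sum(axis=axes, keepdims=True)
                gx = inv_r * (gx_hat - s1 / n - xhat * s2 / n)
            else:
                gx = gx_hat * inv_r
            x._accum(gx.astype(np.float32))

    return _make(out_data, (x, gamma, beta), bw, track)


def batch_norm_silu(x, gamma, beta, running_mean, running_var, training,
                    momentum=0.03, eps=1e-3):
    """Fused batch norm + SiLU (one memory pass each way with numba)."""
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    if not (_K.HAVE_NUMBA and x.data.flags.c_contiguous):
        y = batch_norm(x, gamma, beta, running_mean, running_var, training,
                       momentum, eps)
        return silu(y)
    track = _needs_graph(x, gamma, beta)
    c = x.data.shape[1]
    if training:
        mu, var = _K.bn_stats(x.data)
        n = x.data.size / c
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mu, var = running_mean, running_var
    mu = np.asarray(mu, dtype=np.float32)
    inv = (1.0 / np.sqrt(var + eps)).astype(np.float32)
    out_data = _K.bn_silu_fwd(x.data, mu, inv, gamma.data, beta.data)

    def bw(g):
        gx, ggamma, gbeta = _K.bn_silu_bwd(x.data, np.ascontiguousarray(g),
                                           mu, inv, gamma.data, beta.data, training)
        if gamma.requires_grad:
            gamma._accum(ggamma)
        if beta.requires_grad:
            beta._accum(gbeta)
        if x.requires_grad or x._parents or x._backward:
            x._accum(gx)

    return _make(out_data, (x, gamma, beta), bw, track)


def _pool_views(xp, k, stride, ho, wo):
    for i in range(k):
        for j in range(k):
            yield i, j, xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]


def max_pool2d(x, k, stride, padding=0):
    x = _wrap(x)
    track = _needs_graph(x)
    b, c, h, w = x.data.shape
    ho = (h + 2 * padding - k) // stride + 1
    wo = (w + 2 * padding - k) // stride + 1
    neg = np.float32(-np.inf)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=neg) if padding else x.data
    out_data = np.full((b, c, ho, wo), neg, dtype=np.float32)
    for _, _, v in _pool_views(xp, k, stride, ho, wo):
        np.maximum(out_data, v, out=out_data)

    def bw(g):
        dxp = np.zeros_like(xp)
        assigned = np.zeros(out_data.shape, dtype=bool)
        for i, j, v in _pool_views(xp, k, stride, ho, wo):
            m = (v == out_data) & ~assigned
            assigned |= m
            dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += g * m
        if padding:
            dxp = dxp[:, :, padding:padding + h, padding:padding + w]
        x._accum(dxp)

    return _make(out_data, (x,), bw, track)


def avg_pool2d(x, k, stride, padding=(0, 0, 0, 0)):
    """Average pooling with explicit (top, bottom, left, right) zero padding.

    Padded zeros are included in the divisor (count_include_pad convention).
    """
    x = _wrap(x)
    track = _needs_graph(x)
    pt, pb, pl, pr = padding
    b, c, h, w = x.data.shape
    ho = (h + pt + pb - k) // stride + 1
    wo = (w + pl + pr - k) // stride + 1
    xp = _pad_nchw(x.data, pt, pb, pl, pr)
    out_data = np.zeros((b, c, ho, wo), dtype=np.float32)
    for _, _, v in _pool_views(xp, k, stride, ho, wo):
        out_data += v
    out_data /= k * k

    def bw(g):
        dxp = np.zeros_like(xp)
        gk = g / (k * k)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += gk
        dxp = dxp[:, :, pt:pt + h, pl:pl + w]
        x._accum(dxp)

    return _make(out_data, (x,), bw, track)


def adaptive_avg_pool2d(x, out_hw):
    """Adaptive average pooling: bin i covers [floor(i*H/o), ceil((i+1)*H/o))."""
    x = _wrap(x)
    track = _needs_graph(x)
    b, c, h, w = x.data.shape
    oh, ow = (out_hw, out_hw) if isinstance(out_hw, int) else out_hw
    hs = [(int(np.floor(i * h / oh)), int(np.ceil((i + 1) * h / oh))) for i in range(oh)]
    ws = [(int(np.floor(j * w / ow)), int(np.ceil((j + 1) * w / ow))) for j in range(ow)]
    out_data = np.empty((b, c, oh, ow), dtype=np.float32)
    for i, (h0, h1) in enumerate(hs):
        for j, (w0, w1) in enumerate(ws):
            out_data[:, :, i, j] = x.data[:, :, h0:h1, w0:w1].mean(axis=(2, 3))

    def bw(g):
        dx = np.zeros_like(x.data)
        for i, (h0, h1) in enumerate(hs):
            for j, (w0, w1) in enumerate(ws):
                dx[:, :, h0:h1, w0:w1] += g[:, :, i:i + 1, j:j + 1] / ((h1 - h0) * (w1 - w0))
        x._accum(dx)

    return _make(out_data, (x,), bw, track)


def upsample_nearest2x(x):
    x = _wrap(x)
    track = _needs_graph(x)
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bw(g):
        b, c, h2, w2 = g.shape
        gx = g.reshape(b, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
        x._accum(gx)

    return _make(out_data, (x,), bw, track)
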