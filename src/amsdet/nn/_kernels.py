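"""Optional numba-fused kernels for the memory-bound hot path (batch norm,
SiLU).  Pure-numpy fallbacks keep the package fully functional without numba;
the fused versions do one pass over memory instead of several."""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is expected in practice
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True, fastmath=True)
def bn_stats(x):
    b, c, h, w = x.shape
    mean = np.zeros(c, dtype=np.float32)
    var = np.zeros(c, dtype=np.float32)
    n = b * h * w
    for ci in range(c):
        s = np.float32(0.0)
        for bi in range(b):
            for hi in range(h):
                for wi in range(w):
                    s += x[bi, ci, hi, wi]
        mu = s / n
        q = np.float32(0.0)
        for bi in range(b):
            for hi in range(h):
                for wi in range(w):
                    d = x[bi, ci, hi, wi] - mu
                    q += d * d
        mean[ci] = mu
        var[ci] = q / n
    return mean, var


@njit(cache=True, fastmath=True)
def bn_apply(x, mean, inv, gamma, beta):
    b, c, h, w = x.shape
    out = np.empty_like(x)
    for bi in range(b):
        for ci in range(c):
            a = gamma[ci] * inv[ci]
            d = beta[ci] - mean[ci] * a
            for hi in range(h):
                for wi in range(w):
                    out[bi, ci, hi, wi] = x[bi, ci, hi, wi] * a + d
    return out


@njit(cache=True, fastmath=True)
def bn_bwd(x, g, mean, inv, gamma, training):
    b, c, h, w = x.shape
    n = b * h * w
    s1 = np.zeros(c, dtype=np.float32)
    s2 = np.zeros(c, dtype=np.float32)
    for bi in range(b):
        for ci in range(c):
            for hi in range(h):
                for wi in range(w):
                    gv = g[bi, ci, hi, wi]
                    s1[ci] += gv
                    s2[ci] += gv * (x[bi, ci, hi, wi] - mean[ci]) * inv[ci]
    gx = np.empty_like(x)
    for bi in range(b):
        for ci in range(c):
            a = gamma[ci] * inv[ci]
            if training:
                for hi in range(h):
                    for wi in range(w):
                        xh = (x[bi, ci, hi, wi] - mean[ci]) * inv[ci]
                        gx[bi, ci, hi, wi] = a * (g[bi, ci, hi, wi] - s1[ci] / n - xh * s2[ci] / n)
            else:
                for hi in range(h):
                    for wi in range(w):
                        gx[bi, ci, hi, wi] = a * g[bi, ci, hi, wi]
    # s1, s2*? gradients of beta and gamma: gbeta = s1; ggamma = s2
    return gx, s2, s1


@njit(cache=True, fastmath=True)
def bn_silu_fwd(x, mean, inv, gamma, beta):
    b, c, h, w = x.shape
    out = np.empty_like(x)
    for bi in range(b):
        for ci in range(c):
            a = gamma[ci] * inv[ci]
            d = beta[ci] - mean[ci] * a
            for hi in range(h):
                for wi in range(w):
                    y = x[bi, ci, hi, wi] * a + d
                    out[bi, ci, hi, wi] = y / (np.float32(1.0) + np.exp(-y))
    return out


@njit(cache=True, fastmath=True)
def bn_silu_bwd(x, g, mean, inv, gamma, beta, training):
    b, c, h, w = x.shape
    n = b * h * w
    s1 = np.zeros(c, dtype=np.float32)
    s2 = np.zeros(c, dtype=np.float32)
    one = np.float32(1.0)
    for bi in range(b):
        for ci in range(c):
            a = gamma[ci] * inv[ci]
            d = beta[ci] - mean[ci] * a
            for hi in range(h):
                for wi in range(w):
                    xv = x[bi, ci, hi, wi]
                    y = xv * a + d
                    s = one / (one + np.exp(-y))
                    gy = g[bi, ci, hi, wi] * s * (one + y * (one - s))
                    s1[ci] += gy
                    s2[ci] += gy * (xv - mean[ci]) * inv[ci]
    gx = np.empty_like(x)
    for bi in range(b):
        for ci in range(c):
            a = gamma[ci] * inv[ci]
            d = beta[ci] - mean[ci] * a
            for hi in range(h):
                for wi in range(w):
                    xv = x[bi, ci, hi, wi]
                    y = xv * a + d
                    s = one / (one + np.exp(-y))
                    gy = g[bi, ci, hi, wi] * s * (one + y * (one - s))
                    if training:
                        xh = (xv - mean[ci]) * inv[ci]
                        gx[bi, ci, hi, wi] = gamma[ci] * inv[ci] * (gy - s1[ci] / n - xh * s2[ci] / n)
                    else:
                        gx[bi, ci, hi, wi] = gamma[ci] * inv[ci] * gy
    return gx, s2, s1


@njit(cache=True, fastmath=True)
def silu_fwd(x):
    flat = x.ravel()
    out = np.empty_like(flat)
    for i in range(flat.size):
        v = flat[i]
        out[i] = v / (np.float32(1.0) + np.exp(-v))
    return out.reshape(x.shape)


@njit(cache=True, fastmath=True)
def silu_bwd(x, g):
    flat = x.ravel()
    gf = g.ravel()
    out = np.empty_like(flat)
    for i in range(flat.size):
        v = flat[i]
        s = np.float32(1.0) / (np.float32(1.0) + np.exp(-v))
        out[i] = gf[i] * s * (np.float32(1.0) + v * (np.float32(1.0) - s))
    return out.reshape(x.shape)
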