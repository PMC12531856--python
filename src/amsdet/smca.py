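"""Spatial-multiscale context attention (SMCA).

The module fuses two complementary signals on a feature map ``X``:

1. **Spatial self-attention** — multi-head scaled-dot-product attention over
   the N = H*W spatial positions, ``X_s = MHSA(X)``, capturing long-range
   context that stacks of local convolutions miss.
2. **Local/global channel gating** — ``X_s`` is adaptively average-pooled to a
   ks x ks grid (local summary ``F_l``) and further to 1x1 (global summary
   ``F_g``); a shared 1-D convolution slides *across channels* of both
   summaries (kernel size chosen logarithmically in C, as in efficient channel
   attention), each is squashed by a sigmoid, and a learnable scalar
   ``omega`` in [0, 1] blends them into one gate per channel:

   ``A = omega * sigma(Conv1D_k(F_l)) + (1 - omega) * sigma(Conv1D_k(F_g))``

The output is the channel-wise recalibration ``Y = X_s * A``.

The 1-D convolution is applied independently at each of the ks^2 bins of
``F_l`` (channels as the sliding axis, zero padding k//2); the sigmoid gates
are then averaged over bins to a single weight per channel before blending.
The local and global branches share the same kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputError
from .nn import F, Module, Sequential, Tensor


@dataclass
class SMCAConfig:
    channels: int
    num_heads: int = 4
    local_pool_size: int = 5
    gamma: int = 2
    beta: int = 1
    omega_init: float = 0.5

    def __post_init__(self):
        if self.channels < 1 or self.num_heads < 1:
            raise ConfigurationError("channels and num_heads must be positive")
        if self.channels % self.num_heads:
            raise ConfigurationError(
                f"channels ({self.channels}) not divisible by heads ({self.num_heads})")
        if self.local_pool_size < 1:
            raise ConfigurationError("local_pool_size must be >= 1")
        if self.gamma < 1:
            raise ConfigurationError("gamma must be >= 1")

    @property
    def head_dim(self):
        return self.channels // self.num_heads


def adaptive_kernel_size(c, gamma=2, b=1):
    """Cross-channel 1-D kernel size: floor((log2 C + b)/gamma), odd, >= 1."""
    if c < 1:
        raise InputError("channel count must be >= 1")
    t = int(np.floor((np.log2(c) + b) / gamma))
    if t % 2 == 0:
        t += 1
    return max(t, 1)


def spatial_self_attention(x, qkv_w, qkv_b, proj_w, proj_b, num_heads):
    """Multi-head self-attention over spatial positions of an NCHW tensor.

    Q, K, V come from a single 1x1 convolution producing 3C channels; the
    result is linearly projected back to C channels.  Attention logits are
    scaled by 1/sqrt(d) and softmax-normalised over key positions with the
    usual max-subtraction for numerical stability.
    """
    data = x.data if isinstance(x, Tensor) else np.asarray(x)
    if not np.all(np.isfinite(data)):
        raise InputError("non-finite values in attention input")
    b, c, h, w = data.shape
    if c % num_heads:
        raise ConfigurationError(f"channels ({c}) not divisible by heads ({num_heads})")
    d = c // num_heads
    n = h * w
    qkv = F.conv2d(x, qkv_w, qkv_b)                      # (b, 3c, h, w)
    qkv = F.reshape(qkv, (b, 3, num_heads, d, n))
    q = F.narrow(qkv, 1, 0, 1)
    k = F.narrow(qkv, 1, 1, 1)
    v = F.narrow(qkv, 1, 2, 1)
    q = F.reshape(q, (b, num_heads, d, n))
    k = F.reshape(k, (b, num_heads, d, n))
    v = F.reshape(v, (b, num_heads, d, n))
    scores = F.matmul(F.transpose(q, (0, 1, 3, 2)), k)   # (b, h, n_query, n_key)
    attn = F.softmax(F.mul(scores, 1.0 / np.sqrt(d)), axis=-1)
    out = F.matmul(v, F.transpose(attn, (0, 1, 3, 2)))   # (b, h, d, n)
    out = F.reshape(out, (b, c, h, w))
    return F.conv2d(out, proj_w, proj_b)


def local_global_features(xs, ks):
    """Adaptive ks x ks average pooling of ``xs`` and its per-channel mean."""
    if ks < 1:
        raise ConfigurationError("local pool size must be >= 1")
    f_l = F.adaptive_avg_pool2d(xs, ks)
    f_g = F.mean_(f_l, axis=(2, 3), keepdims=True)
    return f_l, f_g


def fuse_attention(f_l, f_g, conv1d_w, omega, kernel_size):
    """Blend sigmoid-gated cross-channel convolutions of the two summaries."""
    if kernel_size % 2 == 0:
        raise ConfigurationError("cross-channel kernel size must be odd")
    b, c = f_l.data.shape[:2]
    # local branch: conv across channels at every spatial bin, then average
    loc = F.transpose(f_l, (0, 2, 3, 1))                 # (b, ks, ks, c)
    loc = F.sigmoid(F.conv1d_channels(loc, conv1d_w))
    loc = F.mean_(loc, axis=(1, 2))                      # (b, c)
    glo = F.reshape(f_g, (b, c))
    glo = F.sigmoid(F.conv1d_channels(glo, conv1d_w))
    w = F.clip(omega, 0.0, 1.0)
    a = F.add(F.mul(w, loc), F.mul(F.add(F.mul(w, -1.0), 1.0), glo))
    return F.reshape(a, (b, c, 1, 1))


class SMCA(Module):
    """Spatial-multiscale context attention over an NCHW feature map."""

    def __init__(self, rng, cfg: SMCAConfig):
        super().__init__()
        self.cfg = cfg
        c = cfg.channels
        std = np.sqrt(2.0 / c)
        self.qkv_w = Tensor.param(rng.standard_normal((3 * c, c, 1, 1)).astype(np.float32) * std)
        self.qkv_b = Tensor.param(np.zeros(3 * c, dtype=np.float32))
        self.proj_w = Tensor.param(rng.standard_normal((c, c, 1, 1)).astype(np.float32) * std)
        self.proj_b = Tensor.param(np.zeros(c, dtype=np.float32))
        self.k1d = adaptive_kernel_size(c, cfg.gamma, cfg.beta)
        self.conv1d_w = Tensor.param(
            rng.standard_normal(self.k1d).astype(np.float32) / np.sqrt(self.k1d))
        self.omega = Tensor.param(np.float32(cfg.omega_init))

    def attention(self, x):
        return spatial_self_attention(x, self.qkv_w, self.qkv_b,
                                      self.proj_w, self.proj_b, self.cfg.num_heads)

    def gate(self, xs):
        f_l, f_g = local_global_features(xs, self.cfg.local_pool_size)
        return fuse_attention(f_l, f_g, self.conv1d_w, self.omega, self.k1d)

    def forward(self, x):
        xs = self.attention(x)
        return F.mul(xs, self.gate(xs))


def smca_forward(x, module: SMCA):
    """Functional alias: Y = X_s * A_final for a given SMCA module."""
    return module(x)


def make_c2f_smca(rng, ci, co, n=1, shortcut=True, heads=4, ks=5, gamma=2, b=1):
    """C2f block whose inner units are Bottleneck -> SMCA chains.

    Each retained bottleneck is followed by an SMCA module on the hidden
    width, preserving the cross-stage split/skip/concat wiring.
    """
    from .blocks import Bottleneck, C2f
    c = co // 2
    units = []
    for _ in range(n):
        cfg = SMCAConfig(channels=c, num_heads=heads, local_pool_size=ks,
                         gamma=gamma, beta=b)
        units.append(Sequential(Bottleneck(rng, c, shortcut), SMCA(rng, cfg)))
    return C2f(rng, ci, co, n=n, units=units)
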