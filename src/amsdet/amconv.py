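"""Average-max pooling convolution (AMConv): a dual-path stride-2 downsampler.

Pipeline: (1) 2x2 average pooling with stride 1 (asymmetric 0/1 right/bottom
zero padding keeps H x W) smooths the map while initiating downsampling;
(2) channel split into two contiguous halves; (3) half A goes through a 3x3
stride-2 Conv producing out_channels/2; (4) half B goes through 3x3 stride-2
max pooling followed by a 1x1 pointwise Conv producing out_channels/2;
(5) the halves are concatenated.  The average path keeps smooth context, the
max path preserves local peaks (strong edges, small bright targets) that a
plain strided convolution blurs away.

Both convolutions follow the conv+norm+SiLU convention.  For equal channel
counts the block carries roughly (9+1)/4 / 9 ~ 28% of the weights of the plain
3x3 stride-2 convolution it replaces.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError, InputError
from .nn import F, Module


@dataclass
class AMConvConfig:
    in_channels: int
    out_channels: int

    def __post_init__(self):
        if self.in_channels < 2 or self.in_channels % 2:
            raise ConfigurationError("in_channels must be a positive even number")
        if self.out_channels < 2 or self.out_channels % 2:
            raise ConfigurationError("out_channels must be a positive even number")


class AMConv(Module):
    def __init__(self, rng, cfg: AMConvConfig):
        super().__init__()
        from .blocks import ConvBnAct
        self.cfg = cfg
        ci, co = cfg.in_channels, cfg.out_channels
        self.conv_a = ConvBnAct(rng, ci // 2, co // 2, 3, stride=2, padding=1)
        self.conv_b = ConvBnAct(rng, ci // 2, co // 2, 1)

    def forward(self, x):
        b, c, h, w = x.data.shape
        if c != self.cfg.in_channels:
            raise ConfigurationError(
                f"expected {self.cfg.in_channels} channels, got {c}")
        if h < 2 or w < 2:
            raise InputError("AMConv requires spatial dims >= 2")
        half = c // 2
        smoothed = F.avg_pool2d(x, 2, 1, padding=(0, 1, 0, 1))
        part_a = F.narrow(smoothed, 1, 0, half)
        part_b = F.narrow(smoothed, 1, half, half)
        out_a = self.conv_a(part_a)
        pooled_b = F.max_pool2d(part_b, 3, 2, padding=1)
        out_b = self.conv_b(pooled_b)
        return F.concat([out_a, out_b], axis=1)


def amconv_forward(x, module: AMConv):
    return module(x)


def amconv_param_count(cfg: AMConvConfig, norm_affine=True):
    """Learnable scalars: 9*(Ci/2)*(Co/2) weights on path A, (Ci/2)*(Co/2) on
    path B, plus 2*(Co/2) norm affine terms per convolution when enabled."""
    half_i, half_o = cfg.in_channels // 2, cfg.out_channels // 2
    total = 9 * half_i * half_o + half_i * half_o
    if norm_affine:
        total += 2 * half_o + 2 * half_o
    return total
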