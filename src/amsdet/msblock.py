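"""Multi-scale block (MSBlock): grouped cumulative inverted bottlenecks.

A 1x1 Conv expands C input channels to C_expanded = C * r_expand / r_down
(1.5C with the defaults r_expand=3, r_down=2), the expanded map is split into
N equal channel groups X_1..X_N, and each group is processed at its own kernel
size (default [1, 3, 5]):

    Y_1 = X_1                      (the k=1 group is an identity mapping)
    Y_i = IB_{k_i}(Y_{i-1} + X_i)  for i > 1

where IB_k is a stack of ``ib_layers`` inverted bottlenecks (1x1 expand by
``mid_expand``, k x k depthwise with padding k//2, 1x1 compress).  The
cumulative sum feeds each branch with everything the previous branches
learned, so the effective receptive field grows branch by branch.  All groups
are concatenated and fused by a final 1x1 Conv to out_channels.

Convolutions follow the conv+norm+SiLU convention except the depthwise stage,
which carries norm only (standard inverted-bottleneck practice).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigurationError
from .nn import F, Module, ModuleList, Sequential


@dataclass
class MSBlockConfig:
    in_channels: int
    out_channels: int
    kernel_sizes: tuple = (1, 3, 5)
    r_expand: float = 3.0
    r_down: float = 2.0
    mid_expand: int = 2
    ib_layers: int = 3

    def __post_init__(self):
        if self.r_expand <= 0 or self.r_down <= 0:
            raise ConfigurationError("expansion ratios must be positive")
        if any(k % 2 == 0 for k in self.kernel_sizes):
            raise ConfigurationError("all kernel sizes must be odd")
        if self.mid_expand < 1 or self.ib_layers < 1:
            raise ConfigurationError("mid_expand and ib_layers must be >= 1")


def expand_channels(c, r_expand=3.0, r_down=2.0, n_groups=1):
    """C_expanded = C * r_expand / r_down, rounded up to a multiple of the
    group count so the split is even (the final 1x1 fusion absorbs the
    adjustment)."""
    if c < 1:
        raise ConfigurationError("channel count must be >= 1")
    if r_expand <= 0 or r_down <= 0:
        raise ConfigurationError("expansion ratios must be positive")
    expanded = int(math.ceil(c * r_expand / r_down))
    if n_groups > 1 and expanded % n_groups:
        expanded += n_groups - expanded % n_groups
    return expanded


class InvertedBottleneck(Module):
    """1x1 expand -> k x k depthwise (norm only) -> 1x1 compress; k=1 is the
    identity mapping."""

    def __init__(self, rng, width, k, mid_expand=2):
        super().__init__()
        if k % 2 == 0:
            raise ConfigurationError("kernel size must be odd")
        from .blocks import BatchNorm2d, ConvBnAct, kaiming_conv
        self.k = k
        self.width = width
        if k == 1:
            return
        mid = width * mid_expand
        self.expand = ConvBnAct(rng, width, mid, 1)
        self.dw_weight = kaiming_conv(rng, mid, 1, k)
        self.dw_bn = BatchNorm2d(mid)
        self.compress = ConvBnAct(rng, mid, width, 1)

    def forward(self, x):
        if x.data.shape[1] != self.width:
            raise ConfigurationError(
                f"expected {self.width} channels, got {x.data.shape[1]}")
        if self.k == 1:
            return x
        y = self.expand(x)
        y = self.dw_bn(F.depthwise_conv2d(y, self.dw_weight, 1, self.k // 2))
        return self.compress(y)


class MSBlock(Module):
    def __init__(self, rng, cfg: MSBlockConfig):
        super().__init__()
        from .blocks import ConvBnAct
        self.cfg = cfg
        n = len(cfg.kernel_sizes)
        self.expanded = expand_channels(cfg.in_channels, cfg.r_expand, cfg.r_down, n)
        self.group = self.expanded // n
        self.inconv = ConvBnAct(rng, cfg.in_channels, self.expanded, 1)
        branches = []
        for k in cfg.kernel_sizes:
            if k == 1:
                branches.append(InvertedBottleneck(rng, self.group, 1))
            else:
                branches.append(Sequential(*[
                    InvertedBottleneck(rng, self.group, k, cfg.mid_expand)
                    for _ in range(cfg.ib_layers)]))
        self.branches = ModuleList(branches)
        self.outconv = ConvBnAct(rng, self.expanded, cfg.out_channels, 1)

    def forward(self, x):
        if x.data.shape[1] != self.cfg.in_channels:
            raise ConfigurationError(
                f"expected {self.cfg.in_channels} channels, got {x.data.shape[1]}")
        y = self.inconv(x)
        groups = [F.narrow(y, 1, i * self.group, self.group)
                  for i in range(len(self.branches))]
        outs = []
        for i, branch in enumerate(self.branches):
            if i == 0:
                outs.append(branch(groups[0]))
            else:
                outs.append(branch(F.add(outs[-1], groups[i])))
        return self.outconv(F.concat(outs, axis=1))


def msblock_forward(x, module: MSBlock):
    return module(x)


def make_c2f_msblock(rng, ci, co, n=1, kernel_sizes=(1, 3, 5), mid_expand=2,
                     ib_layers=3):
    """C2f block with MSBlock replacing each Bottleneck unit."""
    from .blocks import C2f
    c = co // 2
    units = [MSBlock(rng, MSBlockConfig(c, c, tuple(kernel_sizes),
                                        mid_expand=mid_expand, ib_layers=ib_layers))
             for _ in range(n)]
    return C2f(rng, ci, co, n=n, units=units)
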