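"""Standard YOLOv8-style building blocks on the numpy compute core.

Layer convention throughout the detector: a "Conv" is convolution (no bias)
followed by batch norm (affine) and SiLU, the same convention the YOLO family
uses.  Plain linear convolutions (with bias, no norm) appear only where the
reference head uses them (final logits) and inside attention projections.
"""

from __future__ import annotations

import numpy as np

from .nn import F, Module, ModuleList, Tensor


def kaiming_conv(rng, co, ci, k):
    """He-normal fan-in init for a (co, ci, k, k) conv weight."""
    fan_in = ci * k * k
    std = np.sqrt(2.0 / fan_in)
    return Tensor.param(rng.standard_normal((co, ci, k, k)).astype(np.float32) * std)


class Conv2dRaw(Module):
    """Plain convolution with bias; no norm, no activation."""

    def __init__(self, rng, ci, co, k=1, stride=1, padding=None, bias=True):
        super().__init__()
        self.ci, self.co, self.k, self.stride = ci, co, k, stride
        self.padding = k // 2 if padding is None else padding
        self.weight = kaiming_conv(rng, co, ci, k)
        self.bias = Tensor.param(np.zeros(co, dtype=np.float32)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-3, momentum=0.03):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.gamma = Tensor.param(np.ones(c, dtype=np.float32))
        self.beta = Tensor.param(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x):
        return F.batch_norm(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training, self.momentum, self.eps)


class ConvBnAct(Module):
    """conv (bias-free) + batch norm + SiLU; ``act=False`` drops the SiLU."""

    def __init__(self, rng, ci, co, k=1, stride=1, padding=None, act=True):
        super().__init__()
        self.ci, self.co, self.k, self.stride = ci, co, k, stride
        self.padding = k // 2 if padding is None else padding
        self.weight = kaiming_conv(rng, co, ci, k)
        self.bn = BatchNorm2d(co)
        self.act = act

    def forward(self, x):
        y = F.conv2d(x, self.weight, None, self.stride, self.padding)
        if self.act:
            return F.batch_norm_silu(y, self.bn.gamma, self.bn.beta,
                                     self.bn.running_mean, self.bn.running_var,
                                     self.training, self.bn.momentum, self.bn.eps)
        return self.bn(y)


class Bottleneck(Module):
    """Two 3x3 Convs with optional residual (YOLOv8 C2f inner unit)."""

    def __init__(self, rng, c, shortcut=True):
        super().__init__()
        self.cv1 = ConvBnAct(rng, c, c, 3)
        self.cv2 = ConvBnAct(rng, c, c, 3)
        self.shortcut = shortcut

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.shortcut else y


class C2f(Module):
    """Cross-stage-partial block: split, n inner units on one branch with each
    intermediate kept, concat everything, fuse with a 1x1 Conv."""

    def __init__(self, rng, ci, co, n=1, shortcut=False, units=None):
        super().__init__()
        self.c = co // 2
        self.cv1 = ConvBnAct(rng, ci, 2 * self.c, 1)
        self.cv2 = ConvBnAct(rng, (2 + n) * self.c, co, 1)
        if units is None:
            units = [Bottleneck(rng, self.c, shortcut) for _ in range(n)]
        self.m = ModuleList(units)

    def forward(self, x):
        y = self.cv1(x)
        parts = [F.narrow(y, 1, 0, self.c), F.narrow(y, 1, self.c, self.c)]
        for unit in self.m:
            parts.append(unit(parts[-1]))
        return self.cv2(F.concat(parts, axis=1))


class SPPF(Module):
    """Spatial pyramid pooling (fast): three chained 5x5 stride-1 max pools."""

    def __init__(self, rng, ci, co, k=5):
        super().__init__()
        c_ = ci // 2
        self.k = k
        self.cv1 = ConvBnAct(rng, ci, c_, 1)
        self.cv2 = ConvBnAct(rng, c_ * 4, co, 1)

    def forward(self, x):
        y = self.cv1(x)
        p1 = F.max_pool2d(y, self.k, 1, self.k // 2)
        p2 = F.max_pool2d(p1, self.k, 1, self.k // 2)
        p3 = F.max_pool2d(p2, self.k, 1, self.k // 2)
        return self.cv2(F.concat([y, p1, p2, p3], axis=1))


class Upsample(Module):
    def forward(self, x):
        return F.upsample_nearest2x(x)


class Concat(Module):
    def forward(self, xs):
        return F.concat(xs, axis=1)


class Detect(Module):
    """Decoupled anchor-free head over three feature levels.

    Each level carries a box branch (two 3x3 Convs then a 1x1 linear conv to
    4*reg_max distribution-focal logits) and a class branch (two 3x3 Convs then
    a 1x1 linear conv to nc class logits).  Branch widths follow the reference
    sizing: box width max(16, ch0/4, 4*reg_max); class width max(ch0, min(nc, 100)).
    """

    def __init__(self, rng, nc, ch, reg_max=16):
        super().__init__()
        self.nc = nc
        self.reg_max = reg_max
        self.nl = len(ch)
        self.strides = [8, 16, 32]
        c2 = max(16, ch[0] // 4, reg_max * 4)
        c3 = max(ch[0], min(nc, 100))
        self.box_branches = ModuleList([
            _Branch(rng, c, c2, 4 * reg_max) for c in ch])
        self.cls_branches = ModuleList([
            _Branch(rng, c, c3, nc) for c in ch])
        # prior-aware logit bias: ~5 objects per 640x640 image keeps the
        # initial classification loss small and training stable
        for branch, s in zip(self.box_branches, self.strides):
            branch.out.bias.data[:] = 1.0
        for branch, s in zip(self.cls_branches, self.strides):
            branch.out.bias.data[:] = np.log(5.0 / nc / (640.0 / s) ** 2)

    def forward(self, feats):
        """Returns per-level raw maps of shape (B, 4*reg_max + nc, H, W)."""
        outs = []
        for f, bb, cb in zip(feats, self.box_branches, self.cls_branches):
            outs.append(F.concat([bb(f), cb(f)], axis=1))
        return outs


class _Branch(Module):
    def __init__(self, rng, ci, mid, co):
        super().__init__()
        self.a = ConvBnAct(rng, ci, mid, 3)
        self.b = ConvBnAct(rng, mid, mid, 3)
        self.out = Conv2dRaw(rng, mid, co, 1)

    def forward(self, x):
        return self.out(self.b(self.a(x)))
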