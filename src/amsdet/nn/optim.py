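"""AdamW with decoupled weight decay (Loshchilov & Hutter)."""

from __future__ import annotations

import numpy as np


class AdamW:
    def __init__(self, params, lr=0.002, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0005, decay_mask=None):
        """``decay_mask``: optional list of bools, False exempts a parameter
        from weight decay (norm gains/biases, by YOLO convention)."""
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decay_mask = decay_mask if decay_mask is not None else [True] * len(self.params)
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v, decay in zip(self.params, self.m, self.v, self.decay_mask):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            if decay and self.weight_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def clip_grad_norm(params, max_norm):
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    norm = total ** 0.5
    if norm > max_norm > 0:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm
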