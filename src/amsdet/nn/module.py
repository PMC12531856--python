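"""Minimal module container: parameter registration, train/eval mode, state I/O."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class Module:
    """Base class; submodules and parameters are discovered via attributes."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- traversal ------------------------------------------------------------
    def children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix=""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield f"{prefix}{name}", value
        for name, child in self.children():
            yield from child.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_params(self):
        return int(sum(p.data.size for p in self.parameters()))

    def modules(self):
        yield self
        for _, child in self.children():
            yield from child.modules()

    def train(self, mode=True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    # -- buffers (running statistics) -----------------------------------------
    def named_buffers(self, prefix=""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield f"{prefix}{name}", value
        for name, child in self.children():
            yield from child.named_buffers(prefix=f"{prefix}{name}.")

    def state_dict(self):
        state = {name: p.data for name, p in self.named_parameters()}
        for name, b in self.named_buffers():
            state[f"__buf__{name}"] = b
        return state

    def load_state_dict(self, state):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=np.float32)
        for name, b in self.named_buffers():
            b[...] = state[f"__buf__{name}"]


class ModuleList(Module):
    def __init__(self, mods):
        super().__init__()
        self.items = list(mods)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.items = list(mods)

    def forward(self, x):
        for m in self.items:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]
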