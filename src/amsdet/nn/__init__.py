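def _tune_allocator():
    """Raise glibc's mmap/trim thresholds so large numpy buffers are reused
    from the heap instead of being mmapped and page-faulted on every
    allocation; a large, steady win for batched convolution workloads."""
    try:
        import ctypes
        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
        libc.mallopt(-1, 1 << 30)  # M_TRIM_THRESHOLD
    except Exception:
        pass


_tune_allocator()

from . import tensor as F
from .tensor import Tensor, no_grad
from .module import Module, ModuleList, Sequential
from .optim import AdamW, clip_grad_norm

__all__ = ["F", "Tensor", "no_grad", "Module", "ModuleList", "Sequential",
           "AdamW", "clip_grad_norm"]
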