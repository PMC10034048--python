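"""RMSprop with a per-epoch exponential learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .layers import F32, Param

__all__ = ["RMSprop", "exponential_lr"]


def exponential_lr(lr0: float, decay: float, epoch: int) -> float:
    """lr(e) = lr0 * decay**e, applied once per epoch."""
    return lr0 * decay**epoch


class RMSprop:
    """Root-mean-square propagation: cache = rho*cache + (1-rho)*g^2."""

    def __init__(self, params: list[Param], rho: float = 0.9, eps: float = 1e-7):
        self.params = params
        self.rho = rho
        self.eps = eps
        self.cache = [np.zeros_like(p.value) for p in params]

    def step(self, lr: float) -> None:
        for p, c in zip(self.params, self.cache):
            c *= self.rho
            c += (1.0 - self.rho) * p.grad**2
            p.value -= (lr * p.grad / (np.sqrt(c) + self.eps)).astype(F32)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
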