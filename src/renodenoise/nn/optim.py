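"""Optimisers: Adam and SGD with momentum."""

from __future__ import annotations

from typing import List

import numpy as np

from .autograd import _DTYPE
from .modules import Parameter

__all__ = ["Adam", "SGD"]


class Optimizer:
    def __init__(self, params: List[Parameter], lr: float):
        self.params = list(params)
        self.lr = float(lr)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:  # pragma: no cover - abstract
        raise NotImplementedError


class Adam(Optimizer):
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        super().__init__(params, lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data = (p.data - self.lr * (m / bc1) /
                      (np.sqrt(v / bc2) + self.eps)).astype(_DTYPE)


class SGD(Optimizer):
    def __init__(self, params, lr: float = 1e-3, momentum: float = 0.9):
        super().__init__(params, lr)
        self.momentum = momentum
        self.buf = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, b in zip(self.params, self.buf):
            if p.grad is None:
                continue
            b *= self.momentum
            b += p.grad
            p.data = (p.data - self.lr * b).astype(_DTYPE)
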