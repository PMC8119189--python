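"""Optimizers for the numpy network stack."""

from __future__ import annotations

import numpy as np

__all__ = ["RMSprop", "Adam"]


class Optimizer:
    def __init__(self, params, lr):
        self.params = list(params)
        self.lr = float(lr)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):  # pragma: no cover - abstract
        raise NotImplementedError


class RMSprop(Optimizer):
    """RMSprop with running mean-square gradient (no momentum)."""

    def __init__(self, params, lr=1e-5, alpha=0.9, eps=1e-8):
        super().__init__(params, lr)
        self.alpha, self.eps = alpha, eps
        self.sq = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, s in zip(self.params, self.sq):
            if p.grad is None:
                continue
            s *= self.alpha
            s += (1.0 - self.alpha) * p.grad**2
            p.data -= self.lr * p.grad / (np.sqrt(s) + self.eps)


class Adam(Optimizer):
    """Adam; beta1=0.5 is the usual GAN convention."""

    def __init__(self, params, lr=2e-4, betas=(0.5, 0.999), eps=1e-8):
        super().__init__(params, lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.data -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
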