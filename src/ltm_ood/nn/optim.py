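"""Adam optimiser (optionally AMSGrad) for the autodiff tensors."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Adam"]


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 amsgrad: bool = False):
        self.params = list(params)
        self.lr, self.eps, self.amsgrad = lr, eps, amsgrad
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.vhat = [np.zeros_like(p.data) for p in self.params] if amsgrad else None

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            v = self.v[i]
            if self.amsgrad:
                np.maximum(self.vhat[i], v, out=self.vhat[i])
                v = self.vhat[i]
            p.data -= self.lr * (self.m[i] / bc1) / (np.sqrt(v / bc2) + self.eps)
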