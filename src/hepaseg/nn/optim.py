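"""Adam optimizer with decoupled weight decay and an instrumented step counter."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["AdamW"]


class AdamW:
    """Adam with decoupled weight decay.

    ``step_count`` records the number of applied parameter updates — the
    trainer's gradient-accumulation accounting is asserted against it.
    """

    def __init__(self, params, lr: float = 1e-4, betas: tuple = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params: list[Tensor] = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.step_count = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.step_count += 1
        t = self.step_count
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** t)
            vhat = self.v[i] / (1 - b2 ** t)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
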