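"""Adam optimizer and the warmup + step-decay learning-rate schedule."""

from __future__ import annotations

from typing import List

import numpy as np

from .autograd import Tensor


class Adam:
    """Adam with bias correction; lr is mutable for scheduling."""

    def __init__(self, params: List[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def lr_at_epoch(epoch: int, lr_max: float, warmup_epochs: int,
                decay_every: int, decay_factor: float) -> float:
    """Linear warmup to lr_max, then step decay.

    During warmup the rate at epoch e (0-based) is lr_max*(e+1)/warmup_epochs,
    so it is monotone nondecreasing and reaches lr_max at the last warmup
    epoch.  Afterwards it is multiplied by decay_factor every decay_every
    epochs.
    """
    if warmup_epochs > 0 and epoch < warmup_epochs:
        return lr_max * (epoch + 1) / warmup_epochs
    past = epoch - warmup_epochs
    return lr_max * decay_factor ** (past // decay_every)
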