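"""SGD with momentum and weight decay, plus the piecewise-constant
learning-rate schedule used for training."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .tensor import Tensor


class SGD:
    """Momentum SGD: v <- mu*v + (g + wd*p); p <- p - lr*v."""

    def __init__(self, params: Iterable[Tensor], lr: float,
                 momentum: float = 0.0, weight_decay: float = 0.0):
        self.params = [p for p in params if p.requires_grad]
        if not self.params:
            raise ValueError("optimizer received no trainable parameters")
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v


def lr_at_epoch(epoch: int, base_lr: float, milestones: Sequence[int],
                gamma: float) -> float:
    """Closed form of the step schedule: lr * gamma^(#milestones <= epoch)."""
    drops = sum(1 for m in milestones if m <= epoch)
    return base_lr * gamma ** drops
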