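"""Stochastic gradient descent with momentum, weight decay and polynomial
learning-rate decay — the standard recipe for this segmentation family."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class SGD:
    def __init__(self, params: list[Tensor], lr: float = 0.01, momentum: float = 0.9,
                 weight_decay: float = 5e-4):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v


class PolyDecay:
    """lr(t) = lr0 * (1 - t/T)^power — gradual decay of the step size over the
    scheduled number of optimizer steps."""

    def __init__(self, optimizer: SGD, total_steps: int, power: float = 0.9):
        self.optimizer = optimizer
        self.lr0 = optimizer.lr
        self.total_steps = max(1, int(total_steps))
        self.power = power
        self._step = 0

    def step(self):
        self._step = min(self._step + 1, self.total_steps)
        frac = 1.0 - self._step / self.total_steps
        self.optimizer.lr = self.lr0 * max(frac, 1e-4) ** self.power
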