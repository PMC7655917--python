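"""Optimizers: SGD, Adam, and AdaBound with its dynamic learning-rate bounds,
plus a single-step learning-rate schedule.

AdaBound (Luo et al., ICLR 2019) behaves like Adam early in training and
converges to SGD: each element-wise step size is clipped into
``[final_lr * (1 - 1/(gamma*t + 1)), final_lr * (1 + 1/(gamma*t))]``,
a band that tightens onto ``final_lr`` as the step count t grows.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class Optimizer:
    def __init__(self, params: list[Tensor], lr: float, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.weight_decay = float(weight_decay)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def _grad(self, p: Tensor) -> np.ndarray:
        g = p.grad
        if self.weight_decay:
            g = g + self.weight_decay * p.data
        return g

    def step(self):
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, params, lr: float, momentum: float = 0.0, weight_decay: float = 0.0):
        super().__init__(params, lr, weight_decay)
        self.momentum = momentum
        self._buf = [None] * len(self.params)

    def step(self):
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = self._grad(p)
            if self.momentum:
                if self._buf[i] is None:
                    self._buf[i] = g.copy()
                else:
                    self._buf[i] = self.momentum * self._buf[i] + g
                g = self._buf[i]
            p.data -= self.lr * g


class Adam(Optimizer):
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        super().__init__(params, lr, weight_decay)
        self.betas = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = self._grad(p)
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            p.data -= self.lr * (self._m[i] / bc1) / (np.sqrt(self._v[i] / bc2) + self.eps)


class AdaBound(Optimizer):
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 final_lr: float = 0.1, gamma: float = 1e-3, weight_decay: float = 0.0):
        super().__init__(params, lr, weight_decay)
        self.betas = betas
        self.eps = eps
        self.final_lr = final_lr
        self.gamma = gamma
        self.base_lr = lr  # final_lr scales with any schedule applied to lr
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def bounds(self, t: int) -> tuple[float, float]:
        """Lower/upper clip on the per-element step size at step ``t >= 1``."""
        final_lr = self.final_lr * self.lr / self.base_lr
        lower = final_lr * (1 - 1 / (self.gamma * t + 1))
        upper = final_lr * (1 + 1 / (self.gamma * t))
        return lower, upper

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        lower, upper = self.bounds(self.t)
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = self._grad(p)
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            step_size = self.lr * np.sqrt(bc2) / bc1 / (np.sqrt(self._v[i]) + self.eps)
            p.data -= np.clip(step_size, lower, upper) * self._m[i]


class StepLR:
    """Multiply the learning rate by ``factor`` once, after ``drop_epoch``."""

    def __init__(self, optimizer: Optimizer, drop_epoch: int, factor: float = 0.1):
        self.optimizer = optimizer
        self.drop_epoch = drop_epoch
        self.factor = factor
        self.initial_lr = optimizer.lr

    def set_epoch(self, epoch: int) -> float:
        """epoch is 1-based; returns the lr in force for that epoch."""
        lr = self.initial_lr * (self.factor if epoch > self.drop_epoch else 1.0)
        self.optimizer.lr = lr
        return lr
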