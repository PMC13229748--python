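"""AdamW optimizer and a reduce-on-plateau learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .layers import Parameter

__all__ = ["AdamW", "ReduceLROnPlateau"]


class AdamW:
    """Adam with decoupled weight decay.

    Weight decay is applied directly to the parameters (not through the
    gradient moments), so decay strength is independent of the adaptive
    step size.
    """

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-4):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.value -= (self.lr * update + self.lr * self.weight_decay * p.value).astype(p.value.dtype)


class ReduceLROnPlateau:
    """Halve the learning rate when the monitored loss stops improving."""

    def __init__(self, optimizer: AdamW, factor: float = 0.5, patience: int = 5,
                 min_lr: float = 1e-6, threshold: float = 1e-4):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.threshold = threshold
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, metric: float) -> bool:
        """Update with a validation metric; returns True if the LR was reduced."""
        if metric < self.best - self.threshold:
            self.best = metric
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        if self.bad_epochs > self.patience:
            new_lr = max(self.opt.lr * self.factor, self.min_lr)
            reduced = new_lr < self.opt.lr
            self.opt.lr = new_lr
            self.bad_epochs = 0
            return reduced
        return False
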