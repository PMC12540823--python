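"""Optimizers and learning-rate schedules."""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-5):
        self.params: list[Tensor] = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def clip_grad_norm(self, max_norm: float) -> float:
        """Rescale all gradients so their global L2 norm is <= max_norm."""
        total = 0.0
        for p in self.params:
            if p.grad is not None:
                total += float(np.sum(p.grad.astype(np.float64) ** 2))
        norm = float(np.sqrt(total))
        if norm > max_norm > 0:
            scale = max_norm / (norm + 1e-12)
            for p in self.params:
                if p.grad is not None:
                    p.grad *= scale
        return norm

    def step(self):
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self._t
        bc2 = 1.0 - b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            # decoupled decay, then the Adam update
            p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def cosine_lr(epoch: float, lr0: float, lr_min: float, total_epochs: int) -> float:
    """Cosine annealing: lr0 at epoch 0 down to lr_min at `total_epochs`."""
    e = min(max(epoch, 0.0), float(total_epochs))
    return lr_min + (lr0 - lr_min) * (1.0 + math.cos(math.pi * e / total_epochs)) / 2.0
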