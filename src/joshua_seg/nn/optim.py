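"""Optimization utilities: Adam and gradient clipping."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class Adam:
    """Adam with optional decoupled-from-nothing L2 weight decay added to
    the gradient (the classic formulation)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.beta1, self.beta2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def clip_grad_value(params: list[Tensor], clip: float) -> None:
    """Clamp every gradient entry to [-clip, clip] in place."""
    for p in params:
        if p.grad is not None:
            np.clip(p.grad, -clip, clip, out=p.grad)


def clip_grad_norm(params: list[Tensor], max_norm: float) -> float:
    """Scale gradients so the global L2 norm is at most `max_norm`."""
    total = float(np.sqrt(sum(
        float((p.grad ** 2).sum()) for p in params if p.grad is not None)))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return total
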