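"""Optimizers. Only AdamW (decoupled weight decay) is provided."""

from __future__ import annotations

import numpy as np

from .tensor import Parameter

__all__ = ["AdamW"]


class AdamW:
    """Adam with decoupled weight decay.

    Update: p <- p - lr * (m_hat / (sqrt(v_hat) + eps) + weight_decay * p).
    """

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            mh = m / bc1
            vh = v / bc2
            p.data -= self.lr * (mh / (np.sqrt(vh) + self.eps)
                                 + self.weight_decay * p.data)
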