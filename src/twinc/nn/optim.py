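"""Adam optimizer for the NumPy layer stack."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam with the usual bias correction; no weight decay by default."""

    def __init__(self, params, lr: float = 1e-2,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        # params: list of (name, value, grad) triples sharing memory with layers
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(v) for _, v, _ in params]
        self.v = [np.zeros_like(v) for _, v, _ in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for (_, value, grad), m, v in zip(self.params, self.m, self.v):
            g = grad
            if self.weight_decay:
                g = g + self.weight_decay * value
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            value -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)

    def zero_grad(self) -> None:
        for _, _, grad in self.params:
            grad[...] = 0
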