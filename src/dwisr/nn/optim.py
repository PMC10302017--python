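"""Adam optimizer operating on autograd parameter tensors."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class Adam:
    def __init__(self, params, lr=1e-5, betas=(0.9, 0.999), eps=1e-8):
        self.params: list[Tensor] = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads) -> None:
        """Apply one update; ``grads`` aligned with the parameter list."""
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, (p, g) in enumerate(zip(self.params, grads)):
            gd = g.data if isinstance(g, Tensor) else np.asarray(g)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * gd
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * gd * gd
            p.data = p.data - self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
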