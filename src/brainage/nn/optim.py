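"""Optimizers for the autodiff engine."""

from __future__ import annotations

import numpy as np


class AdamW:
    """Adam with decoupled weight decay.

    Decay is applied to every parameter by default; pass ``no_decay`` (a set
    of parameter names) to exempt norms/biases/gates.
    """

    def __init__(self, named_params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0, no_decay=()):
        self.items = [(n, p) for n, p in named_params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.no_decay = set(no_decay)
        self.t = 0
        self.m = {n: np.zeros_like(p.data) for n, p in self.items}
        self.v = {n: np.zeros_like(p.data) for n, p in self.items}

    def zero_grad(self):
        for _, p in self.items:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for n, p in self.items:
            if p.grad is None:
                continue
            g = p.grad
            m = self.m[n]
            v = self.v[n]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            if self.weight_decay and n not in self.no_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
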