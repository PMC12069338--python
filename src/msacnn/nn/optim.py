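"""Adam optimizer operating in place on layer parameter dicts."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, leaves, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.leaves = [l for l in leaves if l.P]
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.P.items()} for l in self.leaves]
        self.v = [{k: np.zeros_like(v) for k, v in l.P.items()} for l in self.leaves]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for leaf, m, v in zip(self.leaves, self.m, self.v):
            for k, p in leaf.P.items():
                g = leaf.G[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                p -= self.lr * (m[k] / bias1) / (np.sqrt(v[k] / bias2) + self.eps)
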