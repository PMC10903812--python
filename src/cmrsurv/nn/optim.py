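"""Adam optimizer over named parameter slots."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam with bias correction; operates on (key, layer, param-name) slots."""

    def __init__(self, slots, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.slots = list(slots)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {key: np.zeros_like(layer.params[name]) for key, layer, name in self.slots}
        self.v = {key: np.zeros_like(layer.params[name]) for key, layer, name in self.slots}

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for key, layer, name in self.slots:
            g = layer.grads.get(name)
            if g is None:
                continue
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
            mhat = self.m[key] / b1t
            vhat = self.v[key] / b2t
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
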