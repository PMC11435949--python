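"""AdamW: Adam with decoupled weight decay.

Weight decay is applied directly to the parameters (not through the
gradient), and only to matrices/tensors (ndim >= 2) — biases and
normalization scales are excluded, the common practice.
"""

from __future__ import annotations

import numpy as np


class AdamW:
    def __init__(self, parameters, lr: float = 0.005, weight_decay: float = 0.001,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        if lr <= 0:
            raise ValueError("lr must be positive")
        self.handles = list(parameters)  # (module, name) pairs
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(mod.params[name]) for mod, name in self.handles]
        self.v = [np.zeros_like(mod.params[name]) for mod, name in self.handles]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, (mod, name) in enumerate(self.handles):
            p = mod.params[name]
            g = mod.grads[name]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            if self.weight_decay and p.ndim >= 2:
                p -= self.lr * self.weight_decay * p
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
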