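"""AdamW: Adam with decoupled weight decay.

The weight-decay step is applied directly to the parameters (scaled by
the learning rate), outside the adaptive-moment update — the decoupled
formulation, not L2-in-the-gradient.  Biases are exempt from decay.
"""

from __future__ import annotations

import numpy as np


class AdamW:
    def __init__(self, param_layers, lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        #: flat list of (params-dict, grads-dict) pairs
        self.layers = [(l.params, l.grads) for l in param_layers
                       if l.params]
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in p.items()}
                  for p, _ in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in p.items()}
                  for p, _ in self.layers]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for (params, grads), m, v in zip(self.layers, self.m, self.v):
            for k, p in params.items():
                g = grads[k]
                m[k] = self.b1 * m[k] + (1.0 - self.b1) * g
                v[k] = self.b2 * v[k] + (1.0 - self.b2) * g * g
                mhat = m[k] / bc1
                vhat = v[k] / bc2
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
                if self.weight_decay and k != "b":
                    p -= self.lr * self.weight_decay * p

    def zero_grad(self) -> None:
        for _, grads in self.layers:
            for k in grads:
                grads[k][...] = 0.0
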