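"""Adaptive Moment Estimation (Adam) over a SequentialClassifier's layers."""

from __future__ import annotations

import numpy as np

from .layers import Layer

__all__ = ["Adam"]


class Adam:
    def __init__(self, layers: list[Layer], lr: float = 1e-5,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = layers
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads.get(k)
                if g is None:
                    continue
                self.m[i][k] = b1 * self.m[i][k] + (1 - b1) * g
                self.v[i][k] = b2 * self.v[i][k] + (1 - b2) * g * g
                mhat = self.m[i][k] / (1 - b1**self.t)
                vhat = self.v[i][k] / (1 - b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
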