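"""Optimizers updating layer parameters in place from accumulated grads."""

from __future__ import annotations

import numpy as np


class SGD:
    """Plain gradient descent: W <- W - lr * dL/dW."""

    def __init__(self, parameters, lr: float = 0.001) -> None:
        self.parameters = list(parameters)
        self.lr = lr

    def step(self) -> None:
        for layer, name in self.parameters:
            layer.params[name] -= (self.lr * layer.grads[name]).astype(
                layer.params[name].dtype)


class Adam:
    """Adam with the customary defaults (beta1=0.9, beta2=0.999)."""

    def __init__(self, parameters, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.parameters = list(parameters)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(l.params[n], dtype=np.float64)
                  for l, n in self.parameters]
        self.v = [np.zeros_like(l.params[n], dtype=np.float64)
                  for l, n in self.parameters]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for i, (layer, name) in enumerate(self.parameters):
            g = layer.grads[name].astype(np.float64)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bias1
            vhat = self.v[i] / bias2
            layer.params[name] -= (self.lr * mhat /
                                   (np.sqrt(vhat) + self.eps)).astype(
                layer.params[name].dtype)


def make_optimizer(name: str, parameters, lr: float):
    if name == "adam":
        return Adam(parameters, lr=lr)
    if name == "sgd":
        return SGD(parameters, lr=lr)
    raise ValueError(f"unknown optimizer {name!r}; use 'adam' or 'sgd'")
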