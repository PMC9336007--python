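"""Stochastic-gradient optimizers for the autodiff tensors.

Adadelta is the training default throughout the package, following the
model's published hyper-parameter choice.  Adadelta maintains running RMS
estimates of gradients and updates, so the step size adapts per-parameter;
``lr`` is an overall multiplier on the adaptive step (the original
formulation corresponds to ``lr=1.0``).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class Optimizer:
    def __init__(self, params: list[Tensor]):
        self.params = params

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:  # pragma: no cover - interface
        raise NotImplementedError


class Adadelta(Optimizer):
    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1.0,
        rho: float = 0.95,
        eps: float = 1e-6,
    ):
        super().__init__(params)
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self._eg2 = [np.zeros_like(p.data) for p in params]
        self._ed2 = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, eg2, ed2 in zip(self.params, self._eg2, self._ed2):
            if p.grad is None:
                continue
            g = p.grad
            eg2 *= self.rho
            eg2 += (1.0 - self.rho) * g * g
            delta = -np.sqrt((ed2 + self.eps) / (eg2 + self.eps)) * g
            ed2 *= self.rho
            ed2 += (1.0 - self.rho) * delta * delta
            p.data += self.lr * delta


class SGD(Optimizer):
    def __init__(self, params: list[Tensor], lr: float = 0.1):
        super().__init__(params)
        self.lr = lr

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad


def make_optimizer(name: str, params: list[Tensor], lr: float) -> Optimizer:
    name = name.lower()
    if name == "adadelta":
        return Adadelta(params, lr=lr)
    if name == "sgd":
        return SGD(params, lr=lr)
    raise ValueError(f"unknown optimizer {name!r}")
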