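"""Stochastic gradient descent with momentum, plus the cosine learning-rate
decay used for training (initial rate decaying to a floor)."""

from __future__ import annotations

import numpy as np

from .tensor import Parameter


class SGD:
    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.9):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data = p.data - self.lr * v

    def state_dict(self) -> dict:
        return {"lr": self.lr, "momentum": self.momentum,
                "velocity": [v.copy() for v in self.velocity]}

    def load_state_dict(self, state: dict) -> None:
        self.lr = state["lr"]
        self.momentum = state["momentum"]
        self.velocity = [np.asarray(v).copy() for v in state["velocity"]]


def cosine_lr(epoch: int, total_epochs: int, initial_lr: float, min_lr: float) -> float:
    """Cosine decay from ``initial_lr`` at epoch 0 to ``min_lr`` at the final
    epoch; constant ``min_lr`` beyond."""
    if total_epochs <= 1 or epoch >= total_epochs:
        return min_lr if epoch > 0 else initial_lr
    t = epoch / (total_epochs - 1)
    return min_lr + 0.5 * (initial_lr - min_lr) * (1.0 + np.cos(np.pi * t))
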