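"""Optimizers operating on autograd parameter tensors."""
from __future__ import annotations

import numpy as np

from .autograd import Tensor


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros(p.shape) for p in self.params]
        self.v = [np.zeros(p.shape) for p in self.params]

    def step(self, grads: list):
        """Apply one update; `grads` aligns with `params` (Tensors or arrays)."""
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data if isinstance(g, Tensor) else np.asarray(g)
            m *= self.b1
            m += (1 - self.b1) * gd
            v *= self.b2
            v += (1 - self.b2) * gd * gd
            upd = p.data - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.data = upd.astype(p.data.dtype, copy=False)

    def state(self) -> dict:
        return {"t": self.t,
                "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v]}

    def load_state(self, state: dict):
        self.t = int(state["t"])
        self.m = [np.asarray(m, dtype=np.float64) for m in state["m"]]
        self.v = [np.asarray(v, dtype=np.float64) for v in state["v"]]


class ReduceLROnPlateau:
    """Halve the learning rate when the monitored value stops improving."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 5,
                 min_lr: float = 1e-7, mode: str = "min"):
        self.opt = optimizer
        self.factor, self.patience, self.min_lr = factor, patience, min_lr
        self.sign = 1.0 if mode == "min" else -1.0
        self.best = np.inf
        self.bad = 0

    def step(self, value: float):
        v = self.sign * value
        if v < self.best - 1e-12:
            self.best = v
            self.bad = 0
        else:
            self.bad += 1
            if self.bad > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad = 0
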