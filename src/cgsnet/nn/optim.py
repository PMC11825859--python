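"""Optimizers and learning-rate scheduling."""
from __future__ import annotations

import numpy as np

from .tensor import Tensor


class Adam:
    """Adam with parameter groups; frozen parameters are skipped."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        if params and isinstance(params[0], dict):
            self.groups = [dict(g) for g in params]
            for g in self.groups:
                g.setdefault("lr", lr)
        else:
            self.groups = [{"params": list(params), "lr": lr}]
        self.betas, self.eps = betas, eps
        self.state: dict[int, dict] = {}

    def zero_grad(self):
        for g in self.groups:
            for p in g["params"]:
                p.grad = None

    def step(self):
        b1, b2 = self.betas
        for g in self.groups:
            lr = g["lr"]
            for p in g["params"]:
                if not p.requires_grad or p.grad is None:
                    continue
                st = self.state.setdefault(id(p), {
                    "m": np.zeros_like(p.data), "v": np.zeros_like(p.data), "t": 0})
                st["t"] += 1
                st["m"] = b1 * st["m"] + (1 - b1) * p.grad
                st["v"] = b2 * st["v"] + (1 - b2) * p.grad ** 2
                mhat = st["m"] / (1 - b1 ** st["t"])
                vhat = st["v"] / (1 - b2 ** st["t"])
                p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)


class ReduceLROnPlateau:
    """Halve the learning rate of the attached groups when a metric stalls."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 10,
                 min_lr: float = 1e-7, group_indices=None):
        self.opt = optimizer
        self.factor, self.patience, self.min_lr = factor, patience, min_lr
        self.group_indices = (list(range(len(optimizer.groups)))
                              if group_indices is None else list(group_indices))
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, metric: float):
        if metric < self.best - 1e-12:
            self.best = metric
            self.bad_epochs = 0
            return
        self.bad_epochs += 1
        if self.bad_epochs > self.patience:
            for i in self.group_indices:
                g = self.opt.groups[i]
                g["lr"] = max(g["lr"] * self.factor, self.min_lr)
            self.bad_epochs = 0
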