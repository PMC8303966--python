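"""Optimisers operating on :class:`~numgen._nn.layers.Param` collections."""

from __future__ import annotations

from typing import Iterable, List

import numpy as np

from .layers import Param


class Adam:
    """Adam with bias correction (no weight decay)."""

    def __init__(self, params: Iterable[Param], lr: float = 3e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params: List[Param] = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class SGD:
    def __init__(self, params: Iterable[Param], lr: float = 1e-2):
        self.params = list(params)
        self.lr = float(lr)

    def step(self) -> None:
        for p in self.params:
            p.value -= self.lr * p.grad

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
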