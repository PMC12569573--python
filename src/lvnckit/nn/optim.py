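"""Rectified Adam (RAdam) optimiser.

RAdam rectifies the variance of the adaptive learning rate during the first
steps, removing the need for a warm-up schedule.  Hyperparameters beyond the
learning rate follow the reference defaults (beta1=0.9, beta2=0.999,
eps=1e-8).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .layers import Parameter

__all__ = ["RAdam"]


class RAdam:
    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 0.005,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self.rho_inf = 2.0 / (1.0 - beta2) - 1.0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        t = self.t
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**t
        bias2 = 1.0 - b2**t
        rho_t = self.rho_inf - 2.0 * t * b2**t / bias2
        if rho_t > 4.0:
            r_num = (rho_t - 4.0) * (rho_t - 2.0) * self.rho_inf
            r_den = (self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho_t
            rect = math.sqrt(r_num / r_den)
        else:
            rect = None
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            m_hat = m / bias1
            if rect is not None:
                v_hat = np.sqrt(v / bias2) + self.eps
                p.data -= self.lr * rect * m_hat / v_hat
            else:
                p.data -= self.lr * m_hat
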