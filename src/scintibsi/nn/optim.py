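"""Adam optimizer (Kingma & Ba) for the autodiff parameter tensors."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Adam"]


class Adam:
    """Adaptive moment estimation with bias correction.

    Parameters follow the conventional names: ``alpha`` is the step size,
    ``beta1``/``beta2`` the moment decay rates, ``eps`` the denominator
    stabilizer. ``alpha`` may be reassigned between steps (step decay).
    """

    def __init__(self, params: list[Tensor], alpha: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.alpha = float(alpha)
        self.beta1 = float(beta1)
        self.beta2 = float(beta2)
        self.eps = float(eps)
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data -= self.alpha * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
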