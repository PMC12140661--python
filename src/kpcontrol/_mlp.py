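"""Minimal fully-connected network with manual backprop and Adam.

Sized for the gain-tuning problem (inputs of a few dozen features, two
hidden tanh layers); not a general autodiff framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam"]


class MLP:
    """Tanh MLP.  forward() caches activations; backward() returns the
    gradient with respect to the input and accumulates parameter grads."""

    def __init__(self, sizes: list[int], rng: np.random.Generator,
                 out_scale: float = 1.0):
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.W.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self.W[-1] *= out_scale
        self._cache: list[np.ndarray] = []

    @property
    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def forward(self, x: np.ndarray) -> np.ndarray:
        a = np.atleast_2d(x)
        self._cache = [a]
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            a = a @ W + b
            if i < last:
                a = np.tanh(a)
            self._cache.append(a)
        return a

    def backward(self, grad_out: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        """Backprop ``grad_out`` (d loss / d output).  Returns
        (parameter gradients ordered like ``params``, d loss / d input)."""
        gW = [np.zeros_like(W) for W in self.W]
        gb = [np.zeros_like(b) for b in self.b]
        g = np.atleast_2d(grad_out)
        last = len(self.W) - 1
        for i in range(last, -1, -1):
            a_out = self._cache[i + 1]
            if i < last:
                g = g * (1.0 - a_out**2)
            a_in = self._cache[i]
            gW[i] = a_in.T @ g
            gb[i] = g.sum(axis=0)
            g = g @ self.W[i].T
        return gW + gb, g


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 3e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
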