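"""Minimal feed-forward neural network machinery (numpy, CPU).

A small ReLU multilayer perceptron with manual backpropagation and an Adam
optimizer — everything the variational mutual-information critic needs.
Weights use He-scaled Gaussian initialization; evaluation is deterministic
given the weights.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np

__all__ = ["MLP", "Adam"]


class MLP:
    """Fully connected ReLU network; the final layer is linear."""

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator):
        if len(sizes) < 2:
            raise ValueError("need at least input and output sizes")
        self.sizes = tuple(int(s) for s in sizes)
        self.W: List[np.ndarray] = []
        self.b: List[np.ndarray] = []
        for fan_in, fan_out in zip(self.sizes[:-1], self.sizes[1:]):
            self.W.append(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                     (fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self._h: List[np.ndarray] = []
        self._z: List[np.ndarray] = []

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        h = np.asarray(x, dtype=float)
        hs, zs = [h], []
        n_layers = len(self.W)
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            zs.append(z)
            h = np.maximum(z, 0.0) if i < n_layers - 1 else z
            hs.append(h)
        if cache:
            self._h, self._z = hs, zs
        return h

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        """Backpropagate through the cached forward pass.

        Stores parameter gradients in ``gW``/``gb`` and returns the gradient
        with respect to the input.
        """
        if not self._h:
            raise RuntimeError("forward(cache=True) must run before backward")
        d = np.asarray(grad_out, dtype=float)
        self.gW = [np.empty_like(W) for W in self.W]
        self.gb = [np.empty_like(b) for b in self.b]
        for i in range(len(self.W) - 1, -1, -1):
            self.gW[i] = self._h[i].T @ d
            self.gb[i] = d.sum(axis=0)
            d = d @ self.W[i].T
            if i > 0:
                d = d * (self._z[i - 1] > 0.0)
        return d

    @property
    def params(self) -> List[np.ndarray]:
        return self.W + self.b

    @property
    def grads(self) -> List[np.ndarray]:
        return self.gW + self.gb


class Adam:
    """Adam optimizer updating a fixed list of parameter arrays in place."""

    def __init__(self, params: List[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params: List[np.ndarray], grads: List[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
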