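"""Minimal feedforward networks with manual backprop, sized for 2x64 MLPs.

The actor and critics used here are small (hundreds of parameters), so plain
numpy matmuls with hand-written reverse-mode gradients are fast and keep the
package dependency-light.  The only nonstandard requirement is that the
critic's backward pass must also return the gradient with respect to its
*inputs*, which the deterministic policy gradient chains into the actor.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam", "soft_update"]


class MLP:
    """Fully connected network: ReLU hidden layers, linear or tanh output.

    Parameters are stored as a flat list ``[W0, b0, W1, b1, ...]``.
    ``forward`` returns the output and a cache for ``backward``; ``backward``
    returns (parameter gradients, input gradient).
    """

    def __init__(self, sizes, rng: np.random.Generator, out_activation: str | None = None):
        self.sizes = list(sizes)
        self.out_activation = out_activation
        self.params: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            bound = 1.0 / np.sqrt(fan_in)  # fan-in uniform init
            self.params.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.params.append(rng.uniform(-bound, bound, size=fan_out))

    @property
    def n_layers(self) -> int:
        return len(self.sizes) - 1

    def forward(self, x: np.ndarray):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        acts = [x]
        h = x
        for i in range(self.n_layers):
            W, b = self.params[2 * i], self.params[2 * i + 1]
            z = h @ W + b
            if i < self.n_layers - 1:
                h = np.maximum(z, 0.0)
            elif self.out_activation == "tanh":
                h = np.tanh(z)
            else:
                h = z
            acts.append(h)
        return h, acts

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def backward(self, cache, dout: np.ndarray):
        """Reverse pass. ``cache`` is the activation list from ``forward``."""
        acts = cache
        grads = [None] * len(self.params)
        delta = np.atleast_2d(np.asarray(dout, dtype=float))
        for i in reversed(range(self.n_layers)):
            h_out, h_in = acts[i + 1], acts[i]
            if i == self.n_layers - 1:
                if self.out_activation == "tanh":
                    delta = delta * (1.0 - h_out**2)
            else:
                delta = delta * (h_out > 0.0)
            W = self.params[2 * i]
            grads[2 * i] = h_in.T @ delta
            grads[2 * i + 1] = delta.sum(axis=0)
            delta = delta @ W.T
        return grads, delta

    def copy(self) -> "MLP":
        clone = MLP.__new__(MLP)
        clone.sizes = list(self.sizes)
        clone.out_activation = self.out_activation
        clone.params = [p.copy() for p in self.params]
        return clone

    def get_params(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_params(self, params) -> None:
        for own, new in zip(self.params, params):
            own[...] = new


class Adam:
    """Adam optimizer over a network's parameter list (in-place updates)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g**2
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def soft_update(target: MLP, online: MLP, tau: float) -> None:
    """Polyak averaging: target <- (1-tau)*target + tau*online."""
    for pt, po in zip(target.params, online.params):
        pt *= 1.0 - tau
        pt += tau * po
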