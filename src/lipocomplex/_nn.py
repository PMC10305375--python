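"""Shared NumPy neural-network primitives: He-normal initialization,
activations, and an Adam optimizer operating on flat parameter dicts.

The networks in this package are small (a few thousand parameters) and
trained full-batch, so explicit forward/backward passes in NumPy are both
fast and bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np


def he_normal(rng: np.random.Generator, fan_in: int, fan_out: int,
              ) -> np.ndarray:
    """Weight matrix (fan_in, fan_out) ~ N(0, 2 / fan_in)."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_grad(pre: np.ndarray) -> np.ndarray:
    return (pre > 0).astype(pre.dtype)


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable two-branch form
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_sum(x: np.ndarray, x_hat: np.ndarray, eps: float = 1e-12) -> float:
    """Element-summed binary cross-entropy; targets in [0,1], predictions
    in (0,1)."""
    x_hat = np.clip(x_hat, eps, 1.0 - eps)
    return float(-np.sum(x * np.log(x_hat) + (1.0 - x) * np.log(1.0 - x_hat)))


class Adam:
    """Adam over a dict of named parameter arrays (updates in place)."""

    def __init__(self, params: dict[str, np.ndarray], learning_rate: float,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1 ** self.t)
            v_hat = self.v[k] / (1 - b2 ** self.t)
            self.params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
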