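"""Shared neural-network primitives: activations, init, SGD with momentum."""

from __future__ import annotations

import numpy as np
from scipy.special import expit

ACTIVATIONS = ("relu", "tanh", "linear", "sigmoid")


def activate(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(x, 0.0)
    if kind == "tanh":
        return np.tanh(x)
    if kind == "linear":
        return x
    if kind == "sigmoid":
        return expit(x)
    raise ValueError(f"unknown activation {kind!r}")


def activate_grad(pre: np.ndarray, post: np.ndarray, kind: str) -> np.ndarray:
    """Derivative of the activation w.r.t. its pre-activation input."""
    if kind == "relu":
        return (pre > 0.0).astype(pre.dtype)
    if kind == "tanh":
        return 1.0 - post**2
    if kind == "linear":
        return np.ones_like(pre)
    if kind == "sigmoid":
        return post * (1.0 - post)
    raise ValueError(f"unknown activation {kind!r}")


def glorot_uniform(
    fan_in: int, fan_out: int, rng: np.random.Generator
) -> np.ndarray:
    """Symmetric uniform fan-based initialization, U(-limit, limit)."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class MomentumSGD:
    """Classical momentum SGD over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, v, g in zip(self.params, self.velocity, grads):
            v *= self.momentum
            v -= self.lr * g
            p += v
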