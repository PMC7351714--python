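"""Shared numerical pieces: activations, loss, optimizer, schedules, dropout."""

from __future__ import annotations

import math

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def binary_cross_entropy(probs: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(probs, eps, 1.0 - eps)
    y = np.asarray(y, dtype=float)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    fan_in, fan_out = shape
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def dropout_mask(
    rng: np.random.Generator, shape: tuple[int, ...], rate: float
) -> np.ndarray:
    """Inverted-dropout mask: zero with probability ``rate``, else 1/(1-rate)."""
    if rate <= 0.0:
        return np.ones(shape)
    keep = rng.random(shape) >= rate
    return keep / (1.0 - rate)


def cosine_warm_restarts(
    base_lr: float, period: int = 10, eta_min: float = 0.0
):
    """Cosine-annealed learning rate restarting every ``period`` epochs."""

    def schedule(epoch: int) -> float:
        t = epoch % period
        return eta_min + 0.5 * (base_lr - eta_min) * (
            1.0 + math.cos(math.pi * t / period)
        )

    return schedule


def constant_schedule(lr: float):
    def schedule(epoch: int) -> float:  # noqa: ARG001 - uniform interface
        return lr

    return schedule


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(
        self,
        params: dict[str, np.ndarray],
        grads: dict[str, np.ndarray],
        lr: float,
    ) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, g in grads.items():
            self.m[key] = b1 * self.m[key] + (1.0 - b1) * g
            self.v[key] = b2 * self.v[key] + (1.0 - b2) * g * g
            m_hat = self.m[key] / (1.0 - b1**self.t)
            v_hat = self.v[key] / (1.0 - b2**self.t)
            params[key] -= lr * m_hat / (np.sqrt(v_hat) + self.eps)
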