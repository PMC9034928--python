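"""Minimal NumPy neural-network plumbing.

Parameters are plain arrays paired with gradient accumulators; each layer
implements an explicit ``forward`` returning a cache and a ``backward``
consuming it.  Reverse-mode differentiation is hand-written per layer and
validated against numerical gradients in the test suite.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray) -> None:
        self.name = name
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    def zero_grad(self) -> None:
        self.grad.fill(0.0)

    def __repr__(self) -> str:
        return f"Parameter({self.name!r}, shape={self.value.shape})"


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    shifted = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    shifted = x - np.max(x, axis=axis, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=axis, keepdims=True))


def logsumexp(x: np.ndarray, axis: int = -1) -> np.ndarray:
    m = np.max(x, axis=axis, keepdims=True)
    out = m.squeeze(axis) + np.log(np.exp(x - m).sum(axis=axis))
    return out


def uniform_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int | None = None) -> np.ndarray:
    """Glorot-style uniform initialization sqrt(6/(fan_in+fan_out))."""
    if len(shape) == 1:
        return np.zeros(shape)
    fan_in = fan_in or shape[0]
    bound = np.sqrt(6.0 / (fan_in + shape[-1]))
    return rng.uniform(-bound, bound, size=shape)


def dropout_mask(rng: np.random.Generator, shape: tuple[int, ...], rate: float) -> np.ndarray:
    """Inverted-dropout mask (scales kept units by 1/(1-rate))."""
    if rate <= 0.0:
        return np.ones(shape)
    keep = 1.0 - rate
    return (rng.random(shape) < keep).astype(float) / keep
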