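"""Character-level CNN word representations.

Each word's characters are embedded, optionally dropped out (training
only), convolved with ``F`` filters of window width ``w`` (default 3 and 30
per the experimental configuration), and max-pooled over time into a fixed
``F``-dimensional character feature vector for the word.  Character
sequences are padded symmetrically with the padding symbol so that every
word — including single-character ones — yields one window per character;
trailing padding beyond that requirement is stripped first, making the
output invariant to it.
"""

from __future__ import annotations

import numpy as np

from ..alphabet import Alphabet
from .core import Parameter, dropout_mask, uniform_init


class CharCNN:
    def __init__(
        self,
        char_vocab_size: int,
        rng: np.random.Generator,
        char_dim: int = 30,
        window: int = 3,
        n_filters: int = 30,
        dropout_rate: float = 0.5,
        init_bound: float | None = None,
    ) -> None:
        bound = init_bound if init_bound is not None else float(np.sqrt(3.0 / char_dim))
        table = rng.uniform(-bound, bound, size=(char_vocab_size, char_dim))
        table[Alphabet.PAD_INDEX] = 0.0
        self.embedding = Parameter("charcnn.embedding", table)
        self.filters = Parameter(
            "charcnn.filters", uniform_init(rng, (window, char_dim, n_filters), fan_in=window * char_dim)
        )
        self.bias = Parameter("charcnn.bias", np.zeros(n_filters))
        self.window = window
        self.n_filters = n_filters
        self.char_dim = char_dim
        self.dropout_rate = dropout_rate

    def parameters(self) -> list[Parameter]:
        return [self.embedding, self.filters, self.bias]

    def _prep_ids(self, char_ids: np.ndarray) -> np.ndarray:
        ids = np.asarray(char_ids, dtype=int)
        # strip trailing padding, then pad symmetrically for "same" windows
        while ids.size > 1 and ids[-1] == Alphabet.PAD_INDEX:
            ids = ids[:-1]
        if ids.size == 0:
            raise ValueError("word must have at least one character")
        pad = self.window // 2
        return np.concatenate(
            [np.full(pad, Alphabet.PAD_INDEX), ids, np.full(pad, Alphabet.PAD_INDEX)]
        )

    def forward(
        self,
        char_ids: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Encode one word's character ids into an F-vector (plus cache)."""
        padded = self._prep_ids(char_ids)
        T = padded.size - 2 * (self.window // 2)
        X = self.embedding.value[padded]
        if training and self.dropout_rate > 0:
            if rng is None:
                raise ValueError("training-mode forward needs an rng for dropout")
            mask = dropout_mask(rng, X.shape, self.dropout_rate)
            X = X * mask
        else:
            mask = None
        scores = np.broadcast_to(self.bias.value, (T, self.n_filters)).copy()
        W = self.filters.value
        for j in range(self.window):
            scores += X[j : j + T] @ W[j]
        argmax = np.argmax(scores, axis=0)
        out = scores[argmax, np.arange(self.n_filters)]
        cache = {"padded": padded, "X": X, "mask": mask, "argmax": argmax, "T": T}
        return out, cache

    def backward(self, cache: dict, dout: np.ndarray) -> None:
        """Accumulate gradients for one word (max routes to winning window)."""
        T = cache["T"]
        ds = np.zeros((T, self.n_filters))
        ds[cache["argmax"], np.arange(self.n_filters)] = dout
        X = cache["X"]
        dX = np.zeros_like(X)
        W = self.filters.value
        for j in range(self.window):
            self.filters.grad[j] += X[j : j + T].T @ ds
            dX[j : j + T] += ds @ W[j].T
        self.bias.grad += dout
        if cache["mask"] is not None:
            dX *= cache["mask"]
        np.add.at(self.embedding.grad, cache["padded"], dX)
        self.embedding.grad[Alphabet.PAD_INDEX] = 0.0
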