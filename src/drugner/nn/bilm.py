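"""Small bidirectional language model and ELMo-style layer mixing.

A biLM with L recurrent layers yields 2L+1 representations per token: the
context-independent input vector x_k plus, for each layer j, a forward
state (conditioned on tokens <= k) and a backward state (conditioned on
tokens >= k).  For mixing these regroup into L+1 layers of a common width
2s — layer 0 is x_k duplicated, layer j the forward/backward concatenation
— and the contextual embedding is the softmax-weighted sum

    elmo_k = gain * sum_j softmax(logits)_j * h_{k,j}

The softmax weights always sum to one; the scalar gain defaults to 1 (the
mixing formula as printed carries no task scale).

The biLM is trained, at toy scale, by next-token prediction in the forward
direction and previous-token prediction in the backward direction over the
training corpus; during downstream training its parameters stay frozen and
only the mixing logits (and gain) receive gradient.  Precomputed per-token
vectors from file can stand in for the whole channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..alphabet import Alphabet
from .core import Parameter, log_softmax, softmax, uniform_init
from .lstm import LSTM


@dataclass
class BiLMStates:
    """The 2L+1 per-token representations of a biLM pass."""

    x: np.ndarray  # (n, s) context-independent input vectors
    forward: list[np.ndarray]  # L arrays (n, s); state at k sees tokens <= k
    backward: list[np.ndarray]  # L arrays (n, s); state at k sees tokens >= k

    @property
    def n_layers(self) -> int:
        return len(self.forward)

    @property
    def n_representations(self) -> int:
        return 2 * self.n_layers + 1

    def mixing_layers(self) -> list[np.ndarray]:
        """L+1 arrays of width 2s: duplicated x, then fwd||bwd per layer."""
        layers = [np.concatenate([self.x, self.x], axis=1)]
        for hf, hb in zip(self.forward, self.backward):
            layers.append(np.concatenate([hf, hb], axis=1))
        return layers


class BiLM:
    def __init__(
        self,
        vocab_size: int,
        rng: np.random.Generator,
        state_size: int = 32,
        n_layers: int = 1,
    ) -> None:
        self.vocab_size = vocab_size
        self.state_size = state_size
        self.n_layers = n_layers
        bound = float(np.sqrt(3.0 / state_size))
        table = rng.uniform(-bound, bound, size=(vocab_size, state_size))
        table[Alphabet.PAD_INDEX] = 0.0
        self.embedding = Parameter("bilm.embedding", table)
        self.fwd = [
            LSTM(f"bilm.fwd{j}", state_size, state_size, rng) for j in range(n_layers)
        ]
        self.bwd = [
            LSTM(f"bilm.bwd{j}", state_size, state_size, rng) for j in range(n_layers)
        ]
        self.proj_fwd = Parameter("bilm.proj_fwd", uniform_init(rng, (state_size, vocab_size)))
        self.proj_bwd = Parameter("bilm.proj_bwd", uniform_init(rng, (state_size, vocab_size)))

    @property
    def output_dim(self) -> int:
        return 2 * self.state_size

    def parameters(self) -> list[Parameter]:
        params = [self.embedding, self.proj_fwd, self.proj_bwd]
        for cell in self.fwd + self.bwd:
            params += cell.parameters()
        return params

    def states(self, word_ids: np.ndarray) -> BiLMStates:
        """Run both directions; no caches (feature-extraction mode)."""
        ids = np.asarray(word_ids, dtype=int)
        X = self.embedding.value[ids]
        forward: list[np.ndarray] = []
        backward: list[np.ndarray] = []
        inp = X
        for cell in self.fwd:
            inp, _ = cell.forward(inp)
            forward.append(inp)
        inp = X[::-1]
        for cell in self.bwd:
            inp, _ = cell.forward(inp)
            backward.append(inp[::-1])
        return BiLMStates(x=X, forward=forward, backward=backward)

    def lm_loss(self, word_ids: np.ndarray, backprop: bool = False) -> float:
        """Mean token NLL of next-token (fwd) and previous-token (bwd)
        prediction; accumulates gradients when ``backprop``."""
        ids = np.asarray(word_ids, dtype=int)
        n = ids.size
        if n < 2:
            return 0.0
        X = self.embedding.value[ids]
        total = 0.0
        count = 0
        dX = np.zeros_like(X) if backprop else None

        for direction, cells, proj in (
            ("f", self.fwd, self.proj_fwd),
            ("b", self.bwd, self.proj_bwd),
        ):
            inp = X if direction == "f" else X[::-1]
            targets = ids[1:] if direction == "f" else ids[::-1][1:]
            caches = []
            h = inp
            for cell in cells:
                h, cache = cell.forward(h)
                caches.append(cache)
            logits = h[:-1] @ proj.value  # state at k predicts token k+1
            logp = log_softmax(logits, axis=1)
            rows = np.arange(n - 1)
            total += float(-logp[rows, targets].sum())
            count += n - 1
            if backprop:
                dlogits = softmax(logits, axis=1)
                dlogits[rows, targets] -= 1.0
                dlogits /= 2 * (n - 1)
                proj.grad += h[:-1].T @ dlogits
                dh = np.zeros_like(h)
                dh[:-1] = dlogits @ proj.value.T
                for cell, cache in zip(reversed(cells), reversed(caches)):
                    dh = cell.backward(cache, dh)
                if direction == "f":
                    dX += dh
                else:
                    dX += dh[::-1]

        if backprop:
            np.add.at(self.embedding.grad, ids, dX)
            self.embedding.grad[Alphabet.PAD_INDEX] = 0.0
        return total / count


def train_bilm(
    bilm: BiLM,
    sentences: list[np.ndarray],
    epochs: int = 3,
    lr: float = 0.1,
    seed: int = 0,
) -> list[float]:
    """Plain-SGD language-model pretraining; returns per-epoch mean loss."""
    rng = np.random.default_rng(seed)
    params = bilm.parameters()
    history = []
    for _ in range(epochs):
        order = rng.permutation(len(sentences))
        losses = []
        for idx in order:
            for p in params:
                p.zero_grad()
            loss = bilm.lm_loss(sentences[idx], backprop=True)
            for p in params:
                p.value -= lr * p.grad
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history


def bilm_states(word_ids: np.ndarray, bilm: BiLM) -> BiLMStates:
    return bilm.states(word_ids)


class ElmoMixer:
    """Trainable softmax mixing of biLM layers (logits + scalar gain)."""

    def __init__(self, n_layers: int, gain: float = 1.0) -> None:
        self.logits = Parameter("elmo.logits", np.zeros(n_layers + 1))
        self.gain = Parameter("elmo.gain", np.array([gain]))

    def parameters(self) -> list[Parameter]:
        return [self.logits, self.gain]

    def forward(self, layers: list[np.ndarray]) -> tuple[np.ndarray, dict]:
        out, weights = elmo_mix(layers, self.logits.value, float(self.gain.value[0]))
        return out, {"layers": layers, "weights": weights}

    def backward(self, cache: dict, dout: np.ndarray) -> None:
        layers, weights = cache["layers"], cache["weights"]
        gain = float(self.gain.value[0])
        inner = np.array([float(np.sum(dout * layer)) for layer in layers])
        mixed_inner = float(weights @ inner)
        self.logits.grad += gain * weights * (inner - mixed_inner)
        self.gain.grad += mixed_inner


def elmo_mix(
    layers: list[np.ndarray], logits: np.ndarray, gain: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Softmax-weighted sum of equally shaped layers.

    Returns the mixed representation and the normalized weights (which sum
    to one).
    """
    logits = np.asarray(logits, dtype=float)
    if len(layers) != logits.size:
        raise ValueError(f"{len(layers)} layers but {logits.size} mixing logits")
    shapes = {layer.shape for layer in layers}
    if len(shapes) != 1:
        raise ValueError(f"mixing layers disagree in shape: {sorted(shapes)}")
    weights = softmax(logits)
    mixed = gain * sum(w * layer for w, layer in zip(weights, layers))
    return mixed, weights
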