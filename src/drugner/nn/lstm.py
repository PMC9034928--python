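"""LSTM sequence encoders with explicit reverse-mode gradients.

Two gate arrangements are provided behind the ``variant`` switch:

* ``"standard"`` — the conventional LSTM with an independent forget gate
  and no peephole connections (the hyperparameter-table configuration; the
  training default).
* ``"paper"`` — a coupled input-forget (CIFG) cell with peephole weights:
  ``i_t = sigma(W_xi x_t + W_hi h_{t-1} + w_ci * c_{t-1} + b_i)``,
  ``c_t = (1 - i_t) * c_{t-1} + i_t * tanh(W_xc x_t + W_hc h_{t-1} + b_c)``,
  ``o_t = sigma(W_xo x_t + W_ho h_{t-1} + w_co * c_t + b_o)``,
  ``h_t = o_t * tanh(c_t)``.

Initial hidden and cell states are zero.  The bidirectional encoder runs
one cell left-to-right and an independent cell right-to-left and
concatenates their states per token, so the forward state at position t
depends only on tokens <= t and the backward state only on tokens >= t.
"""

from __future__ import annotations

import numpy as np

from .core import Parameter, sigmoid, uniform_init

VARIANTS = ("standard", "paper")


class LSTM:
    """A single-direction LSTM over (n, input_dim) float sequences."""

    def __init__(
        self,
        name: str,
        input_dim: int,
        state_size: int,
        rng: np.random.Generator,
        variant: str = "standard",
    ) -> None:
        if variant not in VARIANTS:
            raise ValueError(f"unknown LSTM variant {variant!r}; valid: {VARIANTS}")
        self.name = name
        self.input_dim = input_dim
        self.state_size = state_size
        self.variant = variant
        s = state_size
        n_gates = 4 if variant == "standard" else 3  # standard: i,f,g,o ; paper: i,g,o
        self.Wx = Parameter(f"{name}.Wx", uniform_init(rng, (input_dim, n_gates * s)))
        self.Wh = Parameter(f"{name}.Wh", uniform_init(rng, (s, n_gates * s)))
        self.b = Parameter(f"{name}.b", np.zeros(n_gates * s))
        if variant == "paper":
            self.peep_i = Parameter(f"{name}.peep_i", np.zeros(s))
            self.peep_o = Parameter(f"{name}.peep_o", np.zeros(s))

    def parameters(self) -> list[Parameter]:
        base = [self.Wx, self.Wh, self.b]
        if self.variant == "paper":
            base += [self.peep_i, self.peep_o]
        return base

    # -- single step ---------------------------------------------------

    def step(
        self, x: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """One recurrence step; returns (h_t, c_t)."""
        s = self.state_size
        pre = x @ self.Wx.value + h_prev @ self.Wh.value + self.b.value
        if self.variant == "standard":
            i = sigmoid(pre[..., :s])
            f = sigmoid(pre[..., s : 2 * s])
            g = np.tanh(pre[..., 2 * s : 3 * s])
            o = sigmoid(pre[..., 3 * s :])
            c = f * c_prev + i * g
            h = o * np.tanh(c)
        else:
            i = sigmoid(pre[..., :s] + self.peep_i.value * c_prev)
            g = np.tanh(pre[..., s : 2 * s])
            c = (1.0 - i) * c_prev + i * g
            o = sigmoid(pre[..., 2 * s :] + self.peep_o.value * c)
            h = o * np.tanh(c)
        return h, c

    # -- full sequence with cache for backprop -------------------------

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, dict]:
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        s = self.state_size
        H = np.zeros((n, s))
        cache: dict = {"X": X, "i": [], "f": [], "g": [], "o": [], "c": [], "h_prev": [], "c_prev": []}
        h = np.zeros(s)
        c = np.zeros(s)
        pre_x = X @ self.Wx.value + self.b.value
        for t in range(n):
            pre = pre_x[t] + h @ self.Wh.value
            cache["h_prev"].append(h)
            cache["c_prev"].append(c)
            if self.variant == "standard":
                i = sigmoid(pre[:s])
                f = sigmoid(pre[s : 2 * s])
                g = np.tanh(pre[2 * s : 3 * s])
                o = sigmoid(pre[3 * s :])
                c = f * c + i * g
            else:
                i = sigmoid(pre[:s] + self.peep_i.value * c)
                f = 1.0 - i
                g = np.tanh(pre[s : 2 * s])
                c = f * c + i * g
                o = sigmoid(pre[2 * s :] + self.peep_o.value * c)
            h = o * np.tanh(c)
            for key, val in (("i", i), ("f", f), ("g", g), ("o", o), ("c", c)):
                cache[key].append(val)
            H[t] = h
        return H, cache

    def backward(self, cache: dict, dH: np.ndarray) -> np.ndarray:
        """Accumulate parameter gradients; return gradient w.r.t. inputs."""
        X = cache["X"]
        n = X.shape[0]
        s = self.state_size
        dX = np.zeros_like(X)
        dh_next = np.zeros(s)
        dc_next = np.zeros(s)
        Wh = self.Wh.value
        Wx = self.Wx.value
        for t in range(n - 1, -1, -1):
            i, f, g, o, c = (cache[k][t] for k in ("i", "f", "g", "o", "c"))
            h_prev, c_prev = cache["h_prev"][t], cache["c_prev"][t]
            tanh_c = np.tanh(c)
            dh = dH[t] + dh_next
            do = dh * tanh_c
            dzo = do * o * (1.0 - o)
            dc = dc_next + dh * o * (1.0 - tanh_c**2)
            if self.variant == "paper":
                dc = dc + dzo * self.peep_o.value
                dg = dc * i
                dzg = dg * (1.0 - g**2)
                di = dc * (g - c_prev)
                dzi = di * i * (1.0 - i)
                dc_next = dc * (1.0 - i) + dzi * self.peep_i.value
                self.peep_i.grad += dzi * c_prev
                self.peep_o.grad += dzo * c
                dgates = np.concatenate([dzi, dzg, dzo])
            else:
                dg = dc * i
                di = dc * g
                df = dc * c_prev
                dzi = di * i * (1.0 - i)
                dzf = df * f * (1.0 - f)
                dzg = dg * (1.0 - g**2)
                dc_next = dc * f
                dgates = np.concatenate([dzi, dzf, dzg, dzo])
            self.Wx.grad += np.outer(X[t], dgates)
            self.Wh.grad += np.outer(h_prev, dgates)
            self.b.grad += dgates
            dX[t] = dgates @ Wx.T
            dh_next = dgates @ Wh.T
        return dX


def lstm_step(
    x: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    cell: LSTM,
) -> tuple[np.ndarray, np.ndarray]:
    """Functional single-step interface over a cell's parameters."""
    return cell.step(np.asarray(x, float), np.asarray(h_prev, float), np.asarray(c_prev, float))


class BiLSTM:
    """Bidirectional encoder: per-token concat of forward/backward states."""

    def __init__(
        self,
        name: str,
        input_dim: int,
        state_size: int,
        rng: np.random.Generator,
        variant: str = "standard",
    ) -> None:
        self.fwd = LSTM(f"{name}.fwd", input_dim, state_size, rng, variant)
        self.bwd = LSTM(f"{name}.bwd", input_dim, state_size, rng, variant)
        self.state_size = state_size

    @property
    def output_dim(self) -> int:
        return 2 * self.state_size

    def parameters(self) -> list[Parameter]:
        return self.fwd.parameters() + self.bwd.parameters()

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, dict]:
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            raise ValueError("cannot encode an empty sequence")
        Hf, cache_f = self.fwd.forward(X)
        Hb_rev, cache_b = self.bwd.forward(X[::-1])
        H = np.concatenate([Hf, Hb_rev[::-1]], axis=1)
        return H, {"f": cache_f, "b": cache_b}

    def backward(self, cache: dict, dH: np.ndarray) -> np.ndarray:
        s = self.state_size
        dXf = self.fwd.backward(cache["f"], dH[:, :s])
        dXb = self.bwd.backward(cache["b"], dH[::-1, s:])
        return dXf + dXb[::-1]
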