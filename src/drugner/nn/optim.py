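"""First-order optimizers over :class:`~drugner.nn.core.Parameter` lists.

The default training regime is minibatch SGD with a per-epoch decaying
learning rate ``lr_e = lr_0 / (1 + decay * e)`` (decay 0.05) and global
gradient-norm clipping at 5.0.  AdaGrad, Adadelta, RMSProp and Adam are
provided for optimizer-comparison experiments.
"""

from __future__ import annotations

import numpy as np

from .core import Parameter

OPTIMIZERS = ("SGD", "AdaGrad", "Adadelta", "RMSProp", "Adam")


def clip_gradients(params: list[Parameter], max_norm: float) -> float:
    """Scale gradients so their global L2 norm is at most ``max_norm``.

    Returns the pre-clipping norm.
    """
    total = float(np.sqrt(sum(float(np.sum(p.grad**2)) for p in params)))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / total
        for p in params:
            p.grad *= scale
    return total


class Optimizer:
    def __init__(self, params: list[Parameter]) -> None:
        self.params = params
        self.epoch = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def set_epoch(self, epoch: int) -> None:
        self.epoch = epoch

    def step(self) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    """SGD with learning-rate decay lr_e = lr0 / (1 + decay * epoch)."""

    def __init__(self, params, lr: float = 0.015, decay: float = 0.05) -> None:
        super().__init__(params)
        self.lr0 = lr
        self.decay = decay

    @property
    def lr(self) -> float:
        return self.lr0 / (1.0 + self.decay * self.epoch)

    def step(self) -> None:
        lr = self.lr
        for p in self.params:
            p.value -= lr * p.grad


class AdaGrad(Optimizer):
    def __init__(self, params, lr: float = 0.015, eps: float = 1e-8) -> None:
        super().__init__(params)
        self.lr = lr
        self.eps = eps
        self._accum = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, acc in zip(self.params, self._accum):
            acc += p.grad**2
            p.value -= self.lr * p.grad / (np.sqrt(acc) + self.eps)


class Adadelta(Optimizer):
    def __init__(self, params, rho: float = 0.95, eps: float = 1e-6) -> None:
        super().__init__(params)
        self.rho = rho
        self.eps = eps
        self._eg = [np.zeros_like(p.value) for p in params]
        self._ex = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, eg, ex in zip(self.params, self._eg, self._ex):
            eg *= self.rho
            eg += (1 - self.rho) * p.grad**2
            update = np.sqrt(ex + self.eps) / np.sqrt(eg + self.eps) * p.grad
            ex *= self.rho
            ex += (1 - self.rho) * update**2
            p.value -= update


class RMSProp(Optimizer):
    def __init__(self, params, lr: float = 0.001, rho: float = 0.9, eps: float = 1e-8) -> None:
        super().__init__(params)
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self._eg = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, eg in zip(self.params, self._eg):
            eg *= self.rho
            eg += (1 - self.rho) * p.grad**2
            p.value -= self.lr * p.grad / (np.sqrt(eg) + self.eps)


class Adam(Optimizer):
    def __init__(self, params, lr: float = 0.001, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        super().__init__(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        bc1 = 1 - self.beta1**self._t
        bc2 = 1 - self.beta2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def make_optimizer(name: str, params: list[Parameter], **config) -> Optimizer:
    """Construct an optimizer by name (SGD default regime per config)."""
    table = {
        "sgd": SGD,
        "adagrad": AdaGrad,
        "adadelta": Adadelta,
        "rmsprop": RMSProp,
        "adam": Adam,
    }
    cls = table.get(name.lower())
    if cls is None:
        raise ValueError(f"unknown optimizer {name!r}; valid names: {', '.join(OPTIMIZERS)}")
    return cls(params, **config)
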