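"""Asynchronous multitask training.

The training pool is the union of task-labeled instance sets D_dner and
D_dnen over the (fully shared) encoder.  Each step samples a task —
proportionally to dataset sizes by default — draws the next minibatch from
that task's shuffled pool, computes that task's loss (CRF NLL for
recognition, per-token cross-entropy for normalization), and updates the
shared parameters together with that task's head; the other task's head is
untouched.  One epoch is one expected pass over the union of instances.

Optimization follows the experimental regime: minibatch SGD (batch 10)
with per-epoch learning-rate decay lr_e = lr0/(1 + 0.05 e) and global
gradient-norm clipping at 5.0; batch loss is the mean per-sentence loss.
Single-task training is literally this loop with a degenerate schedule and
feedback off, so the "zeroed feedback reduces to single-task" regression
holds by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .encoding import EncodedSentence
from .model import MultitaskModel
from .nn.optim import clip_gradients, make_optimizer


@dataclass
class TrainHistory:
    """Per-epoch mean minibatch loss per task plus optional dev metrics."""

    losses: dict[str, list[float]] = field(default_factory=dict)
    dev_metrics: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"losses": self.losses, "dev_metrics": self.dev_metrics}


class _Pool:
    """Shuffled instance pool that reshuffles deterministically on wrap."""

    def __init__(self, data: Sequence[EncodedSentence], rng: np.random.Generator) -> None:
        self.data = list(data)
        self.rng = rng
        self.order: list[int] = []

    def next_batch(self, size: int) -> list[EncodedSentence]:
        batch = []
        while len(batch) < size:
            if not self.order:
                self.order = list(self.rng.permutation(len(self.data)))
            batch.append(self.data[self.order.pop()])
        return batch


def resolve_schedule(
    schedule: dict[str, float] | str | None,
    datasets: dict[str, Sequence[EncodedSentence]],
) -> dict[str, float]:
    """Task-sampling probabilities: proportional to sizes by default."""
    active = {t: d for t, d in datasets.items() if d is not None}
    if schedule is None or schedule == "proportional":
        total = sum(len(d) for d in active.values())
        return {t: len(d) / total for t, d in active.items()}
    if schedule == "uniform":
        return {t: 1.0 / len(active) for t in active}
    total = sum(schedule.values())
    if total <= 0:
        raise ValueError("schedule probabilities must sum to a positive value")
    return {t: p / total for t, p in schedule.items()}


def multitask_train(
    model: MultitaskModel,
    d_dner: Sequence[EncodedSentence] | None,
    d_dnen: Sequence[EncodedSentence] | None,
    epochs: int | None = None,
    schedule: dict[str, float] | str | None = None,
    seed: int | None = None,
    epoch_callback: Callable[[int, MultitaskModel], dict | None] | None = None,
) -> TrainHistory:
    """Train the model; returns the loss history.

    ``epoch_callback(epoch, model)`` may compute dev metrics (recorded in
    the history) and may request early stop by returning
    ``{"stop": True, ...}``.
    """
    cfg = model.config
    datasets = {"dner": d_dner, "dnen": d_dnen}
    for t, d in datasets.items():
        if d is not None and len(d) == 0:
            raise ValueError(f"task {t!r} was given an empty dataset")
    probs = resolve_schedule(schedule, datasets)
    for task, p in probs.items():
        if p > 0 and not datasets.get(task):
            raise ValueError(f"task {task!r} is scheduled (p={p}) but its dataset is empty")
    tasks = sorted(t for t, p in probs.items() if p > 0)
    weights = np.asarray([probs[t] for t in tasks])

    seed = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng_sample, rng_dropout, *rng_pools = [np.random.default_rng(s) for s in ss.spawn(2 + len(tasks))]
    pools = {t: _Pool(datasets[t], r) for t, r in zip(tasks, rng_pools)}

    params = model.shared_parameters() + [
        p for t in tasks for p in model.head_parameters(t)
    ]
    opt_kwargs = {}
    if cfg.optimizer.lower() == "sgd":
        opt_kwargs = {"lr": cfg.initial_lr, "decay": cfg.decay_rate}
    optimizer = make_optimizer(cfg.optimizer, params, **opt_kwargs)

    n_total = sum(len(datasets[t]) for t in tasks)
    steps_per_epoch = max(1, math.ceil(n_total / cfg.batch_size))
    epochs = cfg.epochs if epochs is None else epochs

    history = TrainHistory(losses={t: [] for t in tasks})
    for epoch in range(epochs):
        optimizer.set_epoch(epoch)
        sums = {t: 0.0 for t in tasks}
        counts = {t: 0 for t in tasks}
        for _ in range(steps_per_epoch):
            task = tasks[int(rng_sample.choice(len(tasks), p=weights))] if len(tasks) > 1 else tasks[0]
            batch = pools[task].next_batch(cfg.batch_size)
            optimizer.zero_grad()
            batch_loss = 0.0
            for sentence in batch:
                batch_loss += model.task_loss(task, sentence, rng_dropout)
            batch_loss /= len(batch)
            for p in params:
                p.grad /= len(batch)
            clip_gradients(params, cfg.gradient_clip)
            optimizer.step()
            sums[task] += batch_loss
            counts[task] += 1
        for t in tasks:
            history.losses[t].append(sums[t] / counts[t] if counts[t] else float("nan"))
        if epoch_callback is not None:
            result = epoch_callback(epoch, model) or {}
            if result:
                history.dev_metrics.append({"epoch": epoch, **result})
            if result.get("stop"):
                break
    return history


def train_single_task(
    model: MultitaskModel,
    task: str,
    dataset: Sequence[EncodedSentence],
    epochs: int | None = None,
    seed: int | None = None,
    epoch_callback: Callable[[int, MultitaskModel], dict | None] | None = None,
) -> TrainHistory:
    """Single-task training: the multitask loop with a degenerate schedule."""
    datasets = {"dner": None, "dnen": None}
    datasets[task] = dataset
    return multitask_train(
        model,
        datasets["dner"],
        datasets["dnen"],
        epochs=epochs,
        schedule={task: 1.0},
        seed=seed,
        epoch_callback=epoch_callback,
    )
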