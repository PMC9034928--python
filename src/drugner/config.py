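"""Run configuration.

Defaults reproduce the experimental hyperparameter table: char-CNN window
3 with 30 filters, LSTM state size 200 with zero initial state and no
peepholes, dropout 0.5, batch size 10, initial learning rate 0.015 with
decay rate 0.05, gradient clipping 5.0, BIO labeling, contextual-embedding
width 1024.  Word/char/contextual embedding dimensions default to
100/30/1024 (the char dimension is tied to 30 by the character-embedding
initialization; the alternative 30/100 reading is a plain override).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

TASKS = ("dner", "dnen", "multitask")
CHANNELS = ("word", "char", "elmo")


@dataclass
class RunConfig:
    # char-CNN
    window_size: int = 3
    num_filters: int = 30
    char_dim: int = 30
    # encoder
    state_size: int = 200
    lstm_variant: str = "standard"  # "paper" = coupled-gate peephole cell
    # embeddings
    word_dim: int = 100
    elmo_dim: int = 1024  # width of the mixed contextual vector (= 2 x biLM state)
    elmo_layers: int = 1
    channels: tuple[str, ...] = ("word", "char", "elmo")
    init_bound: str = "sqrt"  # "sqrt": +-sqrt(3/dim); "linear": +-3/dim
    # training
    dropout_rate: float = 0.5
    batch_size: int = 10
    initial_lr: float = 0.015
    gradient_clip: float = 5.0
    decay_rate: float = 0.05
    labeling_schema: str = "BIO"
    optimizer: str = "SGD"
    epochs: int = 10
    # tasks
    task: str = "multitask"
    feedback: bool = True
    feedback_mode: str = "onehot"  # inference coupling; "distribution" optional
    feedback_concat: bool = True  # concat(v, v + yM); False: v + yM alone
    bio_constraint: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; valid: {TASKS}")
        unknown = set(self.channels) - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels {sorted(unknown)}; valid: {CHANNELS}")
        if not self.channels:
            raise ValueError("at least one embedding channel must be active")
        if self.feedback and self.task != "multitask":
            raise ValueError("feedback requires task='multitask'")
        if self.elmo_dim % 2:
            raise ValueError("elmo_dim must be even (forward + backward halves)")

    def to_dict(self) -> dict:
        payload = dataclasses.asdict(self)
        payload["channels"] = list(self.channels)
        return payload

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(payload) - known
        if bad:
            raise ValueError(f"invalid config keys: {sorted(bad)}")
        if "channels" in payload:
            payload = {**payload, "channels": tuple(payload["channels"])}
        return cls(**payload)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        payload = yaml.safe_load(text) or {}
        if not isinstance(payload, dict):
            raise ValueError("config file must hold a mapping of keys to values")
        return cls.from_dict(payload)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)
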