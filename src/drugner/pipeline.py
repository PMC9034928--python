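"""End-to-end wiring: corpus -> alphabets -> model -> training -> prediction.

These helpers are the programmatic interface the command-line tool wraps:
build a model over a training corpus, train it on one or both tasks, and
map predictions back to annotated sentences for evaluation or writing.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .config import RunConfig
from .corpus import AnnotatedSentence
from .encoding import EncodedCorpus, build_alphabets, encode_corpus
from .evaluation import evaluate_corpus
from .model import MultitaskModel
from .training import TrainHistory, multitask_train, train_single_task


def build_model(
    corpus: Sequence[AnnotatedSentence], config: RunConfig
) -> tuple[MultitaskModel, EncodedCorpus]:
    """Build alphabets over ``corpus``, freeze them, and initialize a model."""
    alphabets = build_alphabets(corpus)
    encoded = encode_corpus(corpus, alphabets)
    alphabets.freeze()
    model = MultitaskModel(config, alphabets, rng=np.random.default_rng(config.seed))
    return model, encoded


def predict_corpus(
    model: MultitaskModel, corpus: Sequence[AnnotatedSentence]
) -> list[AnnotatedSentence]:
    """Predict both label rows for each sentence (tokens kept from input)."""
    encoded = encode_corpus(corpus, model.alphabets)
    out = []
    for sentence, enc in zip(corpus, encoded):
        pred = model.predict(enc)
        out.append(
            AnnotatedSentence(
                list(sentence.tokens),
                pred.ner_labels,
                pred.norm_labels,
                sentence_id=sentence.sentence_id,
            )
        )
    return out


def strict_f1(model: MultitaskModel, corpus: Sequence[AnnotatedSentence]) -> float:
    return evaluate_corpus(corpus, predict_corpus(model, corpus), mode="strict").micro.f1


def fit(
    config: RunConfig,
    corpus: Sequence[AnnotatedSentence],
    epochs: int | None = None,
    dev: Sequence[AnnotatedSentence] | None = None,
    stop_at_f1: float | None = None,
) -> tuple[MultitaskModel, TrainHistory]:
    """Train per ``config.task`` on ``corpus``; optionally evaluate a dev
    set each epoch and stop early once its strict F1 reaches ``stop_at_f1``."""
    model, encoded = build_model(corpus, config)
    sentences = list(encoded)

    callback: Callable[[int, MultitaskModel], dict | None] | None = None
    if dev is not None or stop_at_f1 is not None:
        probe = dev if dev is not None else corpus

        def callback(epoch: int, m: MultitaskModel) -> dict:
            f1 = strict_f1(m, probe)
            result = {"strict_f1": f1}
            if stop_at_f1 is not None and f1 >= stop_at_f1:
                result["stop"] = True
            return result

    if config.task == "multitask":
        history = multitask_train(
            model, sentences, sentences, epochs=epochs, epoch_callback=callback
        )
    else:
        history = train_single_task(
            model, config.task, sentences, epochs=epochs, epoch_callback=callback
        )
    return model, history
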