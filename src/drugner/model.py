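"""The multitask tagging model.

Architecture: per-token representations (pretrained/trainable word vectors,
char-CNN features, optionally a contextual channel mixed from a small
frozen biLM) are concatenated in fixed (word, char, contextual) order and
encoded by a shared BiLSTM.  Two task heads sit on the shared states
``v_i``: an entity-recognition (NER) head scoring BIO labels through a
linear-chain CRF, and a normalization (NEN) head with a per-token softmax
over the controlled vocabulary (NIL included).

Cross-task feedback: the head input for one task is

    concat(v_i, v_i + y_other @ M)

where ``y_other`` is the other task's predicted label (one-hot at
inference, optionally the softmax distribution during training, gradient
never propagated through it), and ``M`` is the trainable mapping matrix —
``U`` maps NEN labels into the NER feedback space, ``V`` maps NER labels
into the NEN feedback space.  With feedback disabled the head sees
``concat(v_i, v_i)`` so the width contract is unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
import numpy as np

from .alphabet import Alphabet
from .config import RunConfig
from .corpus import repair_bio
from .encoding import CorpusAlphabets, EncodedSentence
from .nn.bilm import BiLM, ElmoMixer
from .nn.charcnn import CharCNN
from .nn.core import Parameter, log_softmax, softmax, uniform_init
from .nn.crf import (
    bio_transition_penalties,
    crf_nll_grad,
    init_transitions,
    viterbi_decode,
)
from .nn.lstm import BiLSTM
from .vectors import random_embedding

CHECKPOINT_FORMAT = "drugner-checkpoint-1"


@dataclass
class Prediction:
    ner_labels: list[str]
    norm_labels: list[str]


class MultitaskModel:
    def __init__(
        self,
        config: RunConfig,
        alphabets: CorpusAlphabets,
        rng: np.random.Generator | None = None,
    ) -> None:
        self.config = config
        self.alphabets = alphabets
        rng = rng if rng is not None else np.random.default_rng(config.seed)

        self.ner_labels: list[str] = alphabets.label.instances()
        self.norm_labels: list[str] = alphabets.norm.instances()
        self.k_ner = len(self.ner_labels)
        self.k_nen = len(self.norm_labels)
        if self.k_ner == 0:
            raise ValueError("label alphabet holds no learned labels")

        bound = config.init_bound if config.init_bound in ("sqrt", "linear") else "sqrt"
        input_dim = 0
        self.word_embedding: Parameter | None = None
        if "word" in config.channels:
            self.word_embedding = Parameter(
                "word_embedding",
                random_embedding(alphabets.word.size, config.word_dim, rng, bound),
            )
            input_dim += config.word_dim
        self.charcnn: CharCNN | None = None
        if "char" in config.channels:
            self.charcnn = CharCNN(
                alphabets.char.size,
                rng,
                char_dim=config.char_dim,
                window=config.window_size,
                n_filters=config.num_filters,
                dropout_rate=config.dropout_rate,
            )
            input_dim += config.num_filters
        self.bilm: BiLM | None = None
        self.elmo_mixer: ElmoMixer | None = None
        if "elmo" in config.channels:
            self.bilm = BiLM(
                alphabets.word.size,
                rng,
                state_size=config.elmo_dim // 2,
                n_layers=config.elmo_layers,
            )
            self.elmo_mixer = ElmoMixer(config.elmo_layers)
            input_dim += config.elmo_dim

        self.encoder = BiLSTM(
            "encoder", input_dim, config.state_size, rng, variant=config.lstm_variant
        )
        width = self.encoder.output_dim  # 2 x state size
        head_width = 2 * width if config.feedback_concat else width

        self.W_ner = Parameter("W_ner", uniform_init(rng, (head_width, self.k_ner)))
        self.b_ner = Parameter("b_ner", np.zeros(self.k_ner))
        self.transitions = Parameter("transitions", init_transitions(self.k_ner, rng))
        self.W_nen = Parameter("W_nen", uniform_init(rng, (head_width, self.k_nen)))
        self.b_nen = Parameter("b_nen", np.zeros(self.k_nen))
        self.U = Parameter("U", np.zeros((self.k_nen, width)))  # NEN -> NER feedback
        self.V = Parameter("V", np.zeros((self.k_ner, width)))  # NER -> NEN feedback

        self._bio_penalty = (
            bio_transition_penalties(self.ner_labels) if config.bio_constraint else None
        )

    # -- parameter registry --------------------------------------------

    def shared_parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        if self.word_embedding is not None:
            params.append(self.word_embedding)
        if self.charcnn is not None:
            params += self.charcnn.parameters()
        if self.elmo_mixer is not None:
            params += self.elmo_mixer.parameters()  # biLM itself stays frozen
        params += self.encoder.parameters()
        return params

    def head_parameters(self, task: str) -> list[Parameter]:
        if task == "dner":
            return [self.W_ner, self.b_ner, self.transitions, self.U]
        if task == "dnen":
            return [self.W_nen, self.b_nen, self.V]
        raise ValueError(f"unknown task {task!r}")

    def parameters(self) -> list[Parameter]:
        params = self.shared_parameters() + self.head_parameters("dner") + self.head_parameters("dnen")
        if self.bilm is not None:
            params += self.bilm.parameters()
        return params

    def named_parameters(self) -> dict[str, Parameter]:
        return {p.name: p for p in self.parameters()}

    # -- encoding -------------------------------------------------------

    def encode(
        self,
        sentence: EncodedSentence,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Shared per-token representation v (n, 2*state) plus backprop cache."""
        n = len(sentence)
        parts: list[np.ndarray] = []
        cache: dict = {"n": n, "word_ids": np.asarray(sentence.word_ids, dtype=int)}
        if self.word_embedding is not None:
            parts.append(self.word_embedding.value[cache["word_ids"]])
        if self.charcnn is not None:
            char_caches = []
            char_out = np.empty((n, self.charcnn.n_filters))
            for i, ids in enumerate(sentence.char_ids):
                char_out[i], cc = self.charcnn.forward(ids, training=training, rng=rng)
                char_caches.append(cc)
            parts.append(char_out)
            cache["char"] = char_caches
        if self.bilm is not None:
            states = self.bilm.states(cache["word_ids"])
            mixed, mix_cache = self.elmo_mixer.forward(states.mixing_layers())
            parts.append(mixed)
            cache["elmo"] = mix_cache
        X = np.concatenate(parts, axis=1)
        v, enc_cache = self.encoder.forward(X)
        cache["encoder"] = enc_cache
        return v, cache

    def backward_encode(self, cache: dict, dv: np.ndarray) -> None:
        dX = self.encoder.backward(cache["encoder"], dv)
        offset = 0
        if self.word_embedding is not None:
            d = self.config.word_dim
            np.add.at(self.word_embedding.grad, cache["word_ids"], dX[:, offset : offset + d])
            self.word_embedding.grad[Alphabet.PAD_INDEX] = 0.0
            offset += d
        if self.charcnn is not None:
            d = self.charcnn.n_filters
            for i, cc in enumerate(cache["char"]):
                self.charcnn.backward(cc, dX[i, offset : offset + d])
            offset += d
        if self.bilm is not None:
            d = self.bilm.output_dim
            self.elmo_mixer.backward(cache["elmo"], dX[:, offset : offset + d])

    # -- feedback -------------------------------------------------------

    def feedback_input(
        self, v: np.ndarray, y_other: np.ndarray | None, M: Parameter
    ) -> tuple[np.ndarray, np.ndarray | None]:
        """Head input concat(v, v + y@M); returns (input, y_other-as-used)."""
        if y_other is None:
            corrected = v
        else:
            if y_other.shape[1] != M.value.shape[0]:
                raise ValueError(
                    f"feedback label width {y_other.shape[1]} != mapping rows {M.value.shape[0]}"
                )
            corrected = v + y_other @ M.value
        if self.config.feedback_concat:
            return np.concatenate([v, corrected], axis=1), y_other
        return corrected, y_other

    def _backward_feedback(
        self, dF: np.ndarray, y_other: np.ndarray | None, M: Parameter
    ) -> np.ndarray:
        """Route head-input gradient back to v; accumulate M's gradient."""
        if self.config.feedback_concat:
            width = dF.shape[1] // 2
            dv = dF[:, :width].copy()
            dcorr = dF[:, width:]
        else:
            dv = np.zeros_like(dF)
            dcorr = dF
        dv += dcorr
        if y_other is not None:
            M.grad += y_other.T @ dcorr
        return dv

    # -- task heads -----------------------------------------------------

    def _nen_distribution(self, v: np.ndarray, y_ner: np.ndarray | None) -> np.ndarray:
        F, _ = self.feedback_input(v, y_ner, self.V)
        return softmax(F @ self.W_nen.value + self.b_nen.value, axis=1)

    def _ner_emissions(self, v: np.ndarray, y_nen: np.ndarray | None) -> np.ndarray:
        F, _ = self.feedback_input(v, y_nen, self.U)
        return F @ self.W_ner.value + self.b_ner.value

    def _feedback_labels(self, probs: np.ndarray) -> np.ndarray:
        """One-hot (default) or distribution view of the other task's output."""
        if self.config.feedback_mode == "distribution":
            return probs
        onehot = np.zeros_like(probs)
        onehot[np.arange(probs.shape[0]), np.argmax(probs, axis=1)] = 1.0
        return onehot

    # -- losses (accumulate gradients) ----------------------------------

    def dner_loss(
        self,
        sentence: EncodedSentence,
        training: bool = True,
        rng: np.random.Generator | None = None,
    ) -> float:
        v, cache = self.encode(sentence, training=training, rng=rng)
        y_nen = None
        if self.config.feedback:
            # other task's current prediction, gradient stopped
            y_nen = self._feedback_labels(self._nen_distribution(v, None))
        F, y_used = self.feedback_input(v, y_nen, self.U)
        P = F @ self.W_ner.value + self.b_ner.value
        gold = np.asarray(sentence.label_ids, dtype=int) - Alphabet.NUM_RESERVED
        loss, dP, dA = crf_nll_grad(P, self.transitions.value, gold)
        self.transitions.grad += dA
        self.W_ner.grad += F.T @ dP
        self.b_ner.grad += dP.sum(axis=0)
        dF = dP @ self.W_ner.value.T
        dv = self._backward_feedback(dF, y_used, self.U)
        self.backward_encode(cache, dv)
        return loss

    def dnen_loss(
        self,
        sentence: EncodedSentence,
        training: bool = True,
        rng: np.random.Generator | None = None,
    ) -> float:
        v, cache = self.encode(sentence, training=training, rng=rng)
        y_ner = None
        if self.config.feedback:
            P = self._ner_emissions(v, None)
            path, _ = viterbi_decode(P, self.transitions.value)
            y_ner = np.zeros((len(sentence), self.k_ner))
            y_ner[np.arange(len(sentence)), path] = 1.0
        F, y_used = self.feedback_input(v, y_ner, self.V)
        logits = F @ self.W_nen.value + self.b_nen.value
        gold = np.asarray(sentence.norm_ids, dtype=int) - Alphabet.NUM_RESERVED
        logp = log_softmax(logits, axis=1)
        rows = np.arange(len(sentence))
        loss = float(-logp[rows, gold].sum())
        dlogits = softmax(logits, axis=1)
        dlogits[rows, gold] -= 1.0
        self.W_nen.grad += F.T @ dlogits
        self.b_nen.grad += dlogits.sum(axis=0)
        dF = dlogits @ self.W_nen.value.T
        dv = self._backward_feedback(dF, y_used, self.V)
        self.backward_encode(cache, dv)
        return loss

    def task_loss(self, task: str, sentence: EncodedSentence, rng: np.random.Generator) -> float:
        if task == "dner":
            return self.dner_loss(sentence, training=True, rng=rng)
        if task == "dnen":
            return self.dnen_loss(sentence, training=True, rng=rng)
        raise ValueError(f"unknown task {task!r}")

    # -- prediction ------------------------------------------------------

    def predict(self, sentence: EncodedSentence) -> Prediction:
        """Decode both tasks (evaluation mode, deterministic).

        With feedback on, the NEN head is first read without feedback, its
        labels feed the NER head, and the decoded NER labels feed the final
        NEN pass — one alternation round.
        """
        v, _ = self.encode(sentence, training=False)
        y_nen = None
        if self.config.feedback:
            y_nen = self._feedback_labels(self._nen_distribution(v, None))
        P = self._ner_emissions(v, y_nen)
        A = self.transitions.value
        if self._bio_penalty is not None:
            A = A + self._bio_penalty
        path, _ = viterbi_decode(P, A)
        ner = repair_bio([self.ner_labels[j] for j in path])

        y_ner = None
        if self.config.feedback:
            y_ner = np.zeros((len(sentence), self.k_ner))
            y_ner[np.arange(len(sentence)), path] = 1.0
        probs = self._nen_distribution(v, y_ner)
        norm = [self.norm_labels[j] for j in np.argmax(probs, axis=1)]
        return Prediction(ner_labels=ner, norm_labels=norm)

    def predict_dner(self, sentence: EncodedSentence) -> list[str]:
        return self.predict(sentence).ner_labels

    def predict_dnen(self, sentence: EncodedSentence) -> list[str]:
        return self.predict(sentence).norm_labels

    # -- persistence -----------------------------------------------------

    def save(self, path: str) -> None:
        payload = {
            "format": CHECKPOINT_FORMAT,
            "config": self.config.to_dict(),
            "alphabets": self.alphabets.to_dict(),
            "parameters": {p.name: p.value.tolist() for p in self.parameters()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "MultitaskModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(f"unrecognized checkpoint format {payload.get('format')!r}")
        config = RunConfig.from_dict(payload["config"])
        alphabets = CorpusAlphabets.from_dict(payload["alphabets"])
        model = cls(config, alphabets)
        named = model.named_parameters()
        for name, value in payload["parameters"].items():
            if name not in named:
                raise ValueError(f"checkpoint parameter {name!r} not in model")
            arr = np.asarray(value, dtype=float)
            if arr.shape != named[name].value.shape:
                raise ValueError(
                    f"checkpoint/alphabet mismatch for {name!r}: "
                    f"{arr.shape} vs {named[name].value.shape}"
                )
            named[name].value = arr
        return model
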