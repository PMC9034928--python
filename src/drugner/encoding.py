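"""Alphabet construction and the two-list corpus encoding.

Four alphabets are built over a corpus — word, character, (NER) label and
feature — and every sentence becomes four parallel surface columns
``[words, chars, labels, features]`` mirrored by four index columns
``[word_ids, char_ids, label_ids, feature_ids]``.  The feature column is an
optional discrete per-token channel; by default it is a single constant
symbol, and a user-supplied extractor ``f(sentence, i) -> str`` can replace
it.  The multitask model additionally uses a normalization-label alphabet,
built here alongside the four.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

from .alphabet import Alphabet
from .corpus import AnnotatedSentence

FeatureExtractor = Callable[[AnnotatedSentence, int], str]

CONSTANT_FEATURE = "<F>"


def constant_feature(sentence: AnnotatedSentence, i: int) -> str:
    return CONSTANT_FEATURE


@dataclass
class CorpusAlphabets:
    word: Alphabet
    char: Alphabet
    label: Alphabet
    feature: Alphabet
    norm: Alphabet

    def freeze(self) -> "CorpusAlphabets":
        for a in (self.word, self.char, self.label, self.feature, self.norm):
            a.freeze()
        return self

    def to_dict(self) -> dict:
        return {k: getattr(self, k).to_dict() for k in ("word", "char", "label", "feature", "norm")}

    @classmethod
    def from_dict(cls, payload: dict) -> "CorpusAlphabets":
        return cls(**{k: Alphabet.from_dict(payload[k]) for k in payload})


@dataclass
class EncodedSentence:
    words: list[str]
    chars: list[list[str]]
    labels: list[str]
    features: list[str]
    word_ids: list[int]
    char_ids: list[list[int]]
    label_ids: list[int]
    feature_ids: list[int]
    norm_labels: list[str] = field(default_factory=list)
    norm_ids: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.words)


@dataclass
class EncodedCorpus:
    sentences: list[EncodedSentence]
    alphabets: CorpusAlphabets

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self):
        return iter(self.sentences)

    @property
    def surface_list(self) -> list[list[list]]:
        """Per-sentence ``[words, chars, labels, features]`` columns."""
        return [[s.words, s.chars, s.labels, s.features] for s in self.sentences]

    @property
    def id_list(self) -> list[list[list]]:
        """Per-sentence ``[word_ids, char_ids, label_ids, feature_ids]``."""
        return [[s.word_ids, s.char_ids, s.label_ids, s.feature_ids] for s in self.sentences]


def build_alphabets(
    corpus: Sequence[AnnotatedSentence],
    feature_extractor: FeatureExtractor = constant_feature,
) -> CorpusAlphabets:
    """Build the word/char/label/feature (and normalization) alphabets.

    Indices are dense and assigned in first-occurrence order, so identical
    corpora yield identical alphabets.
    """
    if not corpus:
        raise ValueError("cannot build alphabets from an empty corpus")
    alphabets = CorpusAlphabets(
        word=Alphabet("word"),
        char=Alphabet("char"),
        label=Alphabet("label"),
        feature=Alphabet("feature"),
        norm=Alphabet("norm"),
    )
    for sentence in corpus:
        for i, token in enumerate(sentence.tokens):
            alphabets.word.add(token.surface)
            for ch in token.surface:
                alphabets.char.add(ch)
            alphabets.label.add(sentence.ner_labels[i])
            alphabets.feature.add(feature_extractor(sentence, i))
            alphabets.norm.add(sentence.norm_labels[i])
    return alphabets


def encode_sentence(
    sentence: AnnotatedSentence,
    alphabets: CorpusAlphabets,
    feature_extractor: FeatureExtractor = constant_feature,
) -> EncodedSentence:
    words = sentence.surfaces
    chars = [list(w) for w in words]
    labels = list(sentence.ner_labels)
    features = [feature_extractor(sentence, i) for i in range(len(words))]
    return EncodedSentence(
        words=words,
        chars=chars,
        labels=labels,
        features=features,
        word_ids=[alphabets.word.index(w) for w in words],
        char_ids=[[alphabets.char.index(c) for c in cs] for cs in chars],
        label_ids=[alphabets.label.index(l) for l in labels],
        feature_ids=[alphabets.feature.index(f) for f in features],
        norm_labels=list(sentence.norm_labels),
        norm_ids=[alphabets.norm.index(n) for n in sentence.norm_labels],
    )


def encode_corpus(
    corpus: Sequence[AnnotatedSentence],
    alphabets: CorpusAlphabets,
    feature_extractor: FeatureExtractor = constant_feature,
) -> EncodedCorpus:
    """Encode a corpus against (growable or frozen) alphabets.

    Under frozen alphabets, unseen instances map to the unknown index.
    """
    return EncodedCorpus(
        [encode_sentence(s, alphabets, feature_extractor) for s in corpus], alphabets
    )


def decode_labels(label_ids: Sequence[int], alphabet: Alphabet) -> list[str]:
    return [alphabet.instance(i) for i in label_ids]
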