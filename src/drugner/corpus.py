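"""Core corpus data structures: tokens, entity annotations, BIO sequences.

The unit of training and evaluation is the :class:`AnnotatedSentence`: a
token sequence with two aligned label rows, a BIO row for entity
recognition (NER) and a normalization-ID row for entity normalization
(NEN).  Non-entity tokens carry the reserved ``NIL`` normalization label.

Span convention: a span is ``(start_token, end_token_inclusive, type)``.
Character offsets in annotations are 0-based and inclusive on both ends,
the convention of the DDI-challenge corpora.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

NIL = "NIL"
OUTSIDE = "O"

_PUNCT = set(string.punctuation)


@dataclass(frozen=True)
class Token:
    """A surface token; ``chars`` is the character sequence of ``surface``."""

    surface: str

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("token surface must be non-empty")

    @property
    def chars(self) -> tuple[str, ...]:
        return tuple(self.surface)


@dataclass(frozen=True)
class EntityAnnotation:
    """A character-offset entity annotation (offsets inclusive)."""

    char_start: int
    char_end: int
    type: str
    norm_id: str | None = None

    def __post_init__(self) -> None:
        if self.char_start > self.char_end:
            raise ValueError(
                f"entity char_start {self.char_start} > char_end {self.char_end}"
            )


@dataclass
class AnnotatedSentence:
    """Tokens plus aligned BIO (NER) and normalization-ID (NEN) labels."""

    tokens: list[Token]
    ner_labels: list[str]
    norm_labels: list[str] = field(default_factory=list)
    sentence_id: str = ""

    def __post_init__(self) -> None:
        if not self.norm_labels:
            self.norm_labels = [NIL] * len(self.tokens)
        if not (len(self.tokens) == len(self.ner_labels) == len(self.norm_labels)):
            raise ValueError(
                "tokens, ner_labels and norm_labels must have equal length: "
                f"{len(self.tokens)}/{len(self.ner_labels)}/{len(self.norm_labels)}"
            )
        problems = bio_violations(self.ner_labels)
        if problems:
            raise ValueError(f"illegal BIO sequence at positions {problems}: {self.ner_labels}")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]

    @property
    def text(self) -> str:
        return " ".join(self.surfaces)

    def entity_spans(self) -> list[tuple[int, int, str]]:
        return bio_to_spans(self.ner_labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotatedSentence):
            return NotImplemented
        return (
            self.surfaces == other.surfaces
            and self.ner_labels == other.ner_labels
            and self.norm_labels == other.norm_labels
        )


def bio_violations(labels: list[str]) -> list[int]:
    """Positions at which an I- tag does not continue a same-type entity."""
    bad = []
    prev = OUTSIDE
    for i, label in enumerate(labels):
        if label.startswith("I-"):
            entity_type = label[2:]
            if not (prev == f"B-{entity_type}" or prev == f"I-{entity_type}"):
                bad.append(i)
        prev = label
    return bad


def repair_bio(labels: list[str]) -> list[str]:
    """Promote stray ``I-X`` tags (those not continuing an ``X`` entity) to
    ``B-X``.  Conservative repair: entity content is kept, only the boundary
    marker is fixed, so recall stays measurable on ill-formed model output."""
    repaired = list(labels)
    prev = OUTSIDE
    for i, label in enumerate(repaired):
        if label.startswith("I-"):
            entity_type = label[2:]
            if not (prev == f"B-{entity_type}" or prev == f"I-{entity_type}"):
                repaired[i] = f"B-{entity_type}"
        prev = repaired[i]
    return repaired


def spans_to_bio(spans: list[tuple[int, int, str]], n_tokens: int) -> list[str]:
    """Convert token spans ``(start, end_inclusive, type)`` to BIO tags.

    Raises on overlapping spans (naming the colliding pair) and on spans
    outside ``[0, n_tokens)``.
    """
    labels = [OUTSIDE] * n_tokens
    ordered = sorted(spans)
    for a, b in zip(ordered, ordered[1:]):
        if a[1] >= b[0]:
            raise ValueError(f"overlapping entity spans {a} and {b}")
    for start, end, entity_type in ordered:
        if not (0 <= start <= end < n_tokens):
            raise ValueError(f"span ({start}, {end}) outside [0, {n_tokens})")
        labels[start] = f"B-{entity_type}"
        for i in range(start + 1, end + 1):
            labels[i] = f"I-{entity_type}"
    return labels


def bio_to_spans(labels: list[str]) -> list[tuple[int, int, str]]:
    """Extract ``(start, end_inclusive, type)`` spans from BIO tags.

    Ill-formed sequences are repaired first (stray I-X becomes B-X), so this
    never fails on model output.
    """
    labels = repair_bio(labels)
    spans: list[tuple[int, int, str]] = []
    start = None
    current_type = None
    for i, label in enumerate(labels):
        if label.startswith("B-"):
            if start is not None:
                spans.append((start, i - 1, current_type))
            start, current_type = i, label[2:]
        elif label.startswith("I-"):
            pass  # guaranteed continuation after repair
        else:
            if start is not None:
                spans.append((start, i - 1, current_type))
                start, current_type = None, None
    if start is not None:
        spans.append((start, len(labels) - 1, current_type))
    return spans


def tokenize(text: str, forced_boundaries: set[int] | None = None) -> list[tuple[str, int, int]]:
    """Tokenize ``text`` into ``(surface, char_start, char_end_inclusive)``.

    Whitespace split, then leading/trailing punctuation of each chunk is
    split off into separate tokens.  ``forced_boundaries`` is a set of
    character offsets at which a token must start — used to make entity
    boundaries coincide with token boundaries, which guarantees lossless
    BIO conversion.
    """
    forced = forced_boundaries or set()
    chunks: list[tuple[int, int]] = []  # [start, end) of whitespace-free chunks
    start = None
    for i, ch in enumerate(text):
        if ch.isspace():
            if start is not None:
                chunks.append((start, i))
                start = None
        elif start is None:
            start = i
    if start is not None:
        chunks.append((start, len(text)))

    spans: list[tuple[int, int]] = []
    for cs, ce in chunks:
        # peel leading punctuation
        while cs < ce and text[cs] in _PUNCT and ce - cs > 1:
            spans.append((cs, cs + 1))
            cs += 1
        # peel trailing punctuation
        trailing: list[tuple[int, int]] = []
        while ce - cs > 1 and text[ce - 1] in _PUNCT:
            trailing.append((ce - 1, ce))
            ce -= 1
        spans.append((cs, ce))
        spans.extend(reversed(trailing))

    # apply forced boundary splits
    final: list[tuple[str, int, int]] = []
    for cs, ce in spans:
        cuts = sorted({b for b in forced if cs < b < ce})
        lo = cs
        for cut in cuts:
            final.append((text[lo:cut], lo, cut - 1))
            lo = cut
        final.append((text[lo:ce], lo, ce - 1))
    return final


def annotate_sentence(
    text: str,
    entities: list[EntityAnnotation],
    sentence_id: str = "",
) -> AnnotatedSentence:
    """Tokenize ``text`` and project character-offset entities onto tokens.

    Entity boundaries that fall inside a token force a split there, so
    every entity maps to a maximal run of whole tokens; the first token of
    the run gets ``B-TYPE``, the rest ``I-TYPE``; the entity's norm_id (when
    present) is copied to every token of the run, ``NIL`` elsewhere.
    """
    boundaries: set[int] = set()
    for ent in entities:
        boundaries.add(ent.char_start)
        boundaries.add(ent.char_end + 1)
    triples = tokenize(text, boundaries)
    tokens = [Token(s) for s, _, _ in triples]

    token_spans: list[tuple[int, int, str]] = []
    norm_labels = [NIL] * len(tokens)
    span_keys = []
    for ent in entities:
        covered = [
            i
            for i, (_, ts, te) in enumerate(triples)
            if ts >= ent.char_start and te <= ent.char_end
        ]
        if not covered:
            raise ValueError(
                f"entity {ent} covers no token in {text!r}"
            )
        start, end = covered[0], covered[-1]
        span_keys.append((start, end, ent.type))
        token_spans.append((start, end, ent.type))
        if ent.norm_id is not None:
            for i in range(start, end + 1):
                norm_labels[i] = ent.norm_id
    ner_labels = spans_to_bio(token_spans, len(tokens))
    return AnnotatedSentence(tokens, ner_labels, norm_labels, sentence_id=sentence_id)
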