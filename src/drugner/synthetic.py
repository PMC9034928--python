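"""Synthetic DDI-like corpora with known ground truth.

Real drug-interaction corpora are licensed and large; every other module in
this package is exercised instead on generated corpora that mimic their
annotation structure: sentences over a closed context vocabulary containing
multi-token drug entities of types Drug/Brand/Group/Drug_n, each entity
surface form mapped to a normalization ID from a finite controlled
vocabulary, with controllable synonymy (several surface forms per ID) and
ambiguity (context words homographic with entity words).

Two regimes matter for testing:

* **separable** (``ambiguity_rate = 0``): entity surface forms are disjoint
  from the context vocabulary, so a correct tagger can approach perfect F1
  — the training-convergence fixture.
* **correlated tasks** (``ambiguity_rate > 0``): entity words also occur as
  plain context, so token identity alone no longer decides entity-hood;
  every true entity is preceded by a trigger token, making the task
  context-sensitive.  The normalization ID remains a deterministic function
  of (surface form, type), which is what lets the recognition and
  normalization tasks inform each other.

All randomness flows from a single generator derived from ``spec.seed``;
no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import NIL, AnnotatedSentence, Token, spans_to_bio

# Entity-type proportions of the DDI2013 training data.
DDI2013_TYPES: dict[str, float] = {"DRUG": 0.63, "BRAND": 0.10, "GROUP": 0.23, "DRUG_N": 0.04}
DDI2011_TYPES: dict[str, float] = {"DRUG": 1.0}

TRIGGER = "given"  # reserved token emitted immediately before every entity


@dataclass(frozen=True)
class LexiconEntry:
    surface: tuple[str, ...]  # token sequence of the mention
    type: str
    norm_id: str


@dataclass
class SyntheticSpec:
    """Generation parameters for a synthetic annotated corpus."""

    n_sentences: int = 200
    min_len: int = 6
    max_len: int = 14
    context_vocab_size: int = 120
    lexicon: list[LexiconEntry] = field(default_factory=list)
    entity_rate: float = 0.30  # ~2+ entities per sentence, like the real corpora
    ambiguity_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p, name in ((self.entity_rate, "entity_rate"), (self.ambiguity_rate, "ambiguity_rate")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("need 1 <= min_len <= max_len")
        for entry in self.lexicon:
            if not entry.surface:
                raise ValueError(f"lexicon surface form empty for {entry.norm_id}")


def build_lexicon(
    n_norm_ids: int = 40,
    synonymy: int = 2,
    type_proportions: dict[str, float] | None = None,
    multi_token_rate: float = 0.35,
    max_tokens: int = 3,
    seed: int = 0,
) -> list[LexiconEntry]:
    """Deterministically build a lexicon of entity surface forms.

    ``synonymy`` surface forms are created per normalization ID; types are
    assigned in the given proportions (DDI2013 training proportions by
    default).  Surface-form tokens are drawn from a dedicated entity
    vocabulary disjoint from the context vocabulary by naming convention.
    """
    props = type_proportions or DDI2013_TYPES
    rng = np.random.default_rng(seed)
    types = list(props)
    weights = np.asarray([props[t] for t in types], dtype=float)
    weights /= weights.sum()
    # largest-remainder quota: lexicon type counts track the proportions
    # exactly up to rounding, so corpus type frequencies do too
    quota = weights * n_norm_ids
    counts = np.floor(quota).astype(int)
    for j in np.argsort(quota - counts)[::-1][: n_norm_ids - counts.sum()]:
        counts[j] += 1
    type_of_id = [t for t, c in zip(types, counts) for _ in range(c)]
    lexicon: list[LexiconEntry] = []
    next_word = 0
    for i in range(n_norm_ids):
        etype = type_of_id[i]
        norm_id = f"{etype[0]}{i:04d}"
        for _ in range(max(1, synonymy)):
            n_tok = 1
            if rng.random() < multi_token_rate:
                n_tok = int(rng.integers(2, max_tokens + 1))
            surface = tuple(f"ent{next_word + j}" for j in range(n_tok))
            next_word += n_tok
            lexicon.append(LexiconEntry(surface, etype, norm_id))
    return lexicon


def entity_vocabulary(lexicon: list[LexiconEntry]) -> list[str]:
    seen: dict[str, None] = {}
    for entry in lexicon:
        for word in entry.surface:
            seen.setdefault(word)
    return list(seen)


def generate_corpus(spec: SyntheticSpec) -> list[AnnotatedSentence]:
    """Generate a corpus of annotated sentences from a spec.

    Deterministic given ``spec.seed``; entities never overlap; every entity
    token carries the entity's normalization ID so the recognition and
    normalization labelings are mutually consistent by construction.
    """
    if spec.entity_rate > 0 and not spec.lexicon:
        raise ValueError("entity_rate > 0 requires a non-empty lexicon")
    rng = np.random.default_rng(spec.seed)
    context_words = [f"ctx{i}" for i in range(spec.context_vocab_size)]
    homographs = entity_vocabulary(spec.lexicon)
    corpus: list[AnnotatedSentence] = []
    for si in range(spec.n_sentences):
        length = int(rng.integers(spec.min_len, spec.max_len + 1))
        surfaces: list[str] = []
        spans: list[tuple[int, int, str]] = []
        norm: list[str] = []
        while len(surfaces) < length:
            room = length - len(surfaces)
            if (
                spec.lexicon
                and room >= 2
                and rng.random() < spec.entity_rate
            ):
                entry = spec.lexicon[int(rng.integers(len(spec.lexicon)))]
                if len(entry.surface) + 1 <= room:
                    surfaces.append(TRIGGER)
                    norm.append(NIL)
                    start = len(surfaces)
                    surfaces.extend(entry.surface)
                    norm.extend([entry.norm_id] * len(entry.surface))
                    spans.append((start, start + len(entry.surface) - 1, entry.type))
                    continue
            if homographs and rng.random() < spec.ambiguity_rate:
                surfaces.append(homographs[int(rng.integers(len(homographs)))])
            else:
                surfaces.append(context_words[int(rng.integers(len(context_words)))])
            norm.append(NIL)
        labels = spans_to_bio(spans, len(surfaces))
        corpus.append(
            AnnotatedSentence([Token(s) for s in surfaces], labels, norm, sentence_id=f"syn.s{si}")
        )
    return corpus


def separable_spec(n_sentences: int = 2000, seed: int = 0, **kwargs) -> SyntheticSpec:
    """Spec whose entity vocabulary never occurs as context (learnable to
    near-perfect F1 by a correct tagger)."""
    lexicon = kwargs.pop("lexicon", None) or build_lexicon(seed=seed)
    return SyntheticSpec(
        n_sentences=n_sentences, lexicon=lexicon, ambiguity_rate=0.0, seed=seed, **kwargs
    )


def correlated_spec(n_sentences: int = 400, seed: int = 0, **kwargs) -> SyntheticSpec:
    """Spec with homographic context words; normalization IDs remain a
    deterministic function of (surface form, type), so the two tasks carry
    mutually relevant signal."""
    lexicon = kwargs.pop("lexicon", None) or build_lexicon(seed=seed)
    ambiguity = kwargs.pop("ambiguity_rate", 0.3)
    return SyntheticSpec(
        n_sentences=n_sentences, lexicon=lexicon, ambiguity_rate=ambiguity, seed=seed, **kwargs
    )
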