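"""Span-level evaluation: precision / recall / F1 under strict and type
matching.

A predicted span is a true positive under **strict** matching iff a gold
span has identical boundaries and identical type, and under **type**
matching iff it overlaps (shares at least one token with) a gold span of
the same type.  Credit is one-to-one: spans are paired greedily left to
right, so one long prediction cannot match several gold entities.  P, R
and F1 follow the usual counts with the conventions P = 0 when no
predictions, R = 0 when no gold, F1 = 0 when P + R = 0; the micro-average
is computed from TP/FP/FN summed across entity types.

Normalization output is scored by token-level accuracy and mention-level
accuracy (a gold mention counts iff every one of its tokens carries the
gold ID).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .corpus import AnnotatedSentence

Span = tuple[int, int, str]  # (start, end_inclusive, type)

MODES = ("strict", "type")


@dataclass
class MatchCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass
class PRF:
    precision: float
    recall: float
    f1: float
    counts: MatchCounts


@dataclass
class MetricReport:
    mode: str
    per_type: dict[str, PRF]
    micro: PRF

    def as_dict(self) -> dict:
        def row(p: PRF) -> dict:
            return {
                "precision": p.precision,
                "recall": p.recall,
                "f1": p.f1,
                "tp": p.counts.tp,
                "fp": p.counts.fp,
                "fn": p.counts.fn,
            }

        return {
            "mode": self.mode,
            "per_type": {t: row(p) for t, p in self.per_type.items()},
            "micro": row(self.micro),
        }

    def format_table(self) -> str:
        """Aligned plain-text table, one row per type plus the micro row."""
        rows = [("Type", "Precision", "Recall", "F1", "TP", "FP", "FN")]
        for name in sorted(self.per_type):
            p = self.per_type[name]
            rows.append(
                (name, f"{100 * p.precision:.2f}", f"{100 * p.recall:.2f}",
                 f"{100 * p.f1:.2f}", str(p.counts.tp), str(p.counts.fp), str(p.counts.fn))
            )
        m = self.micro
        rows.append(
            ("Micro-average", f"{100 * m.precision:.2f}", f"{100 * m.recall:.2f}",
             f"{100 * m.f1:.2f}", str(m.counts.tp), str(m.counts.fp), str(m.counts.fn))
        )
        widths = [max(len(r[i]) for r in rows) for i in range(len(rows[0]))]
        return "\n".join("  ".join(c.ljust(w) for c, w in zip(r, widths)) for r in rows)


def _overlaps(a: Span, b: Span) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def match_entities(gold: Sequence[Span], predicted: Sequence[Span], mode: str) -> MatchCounts:
    """TP/FP/FN between one sentence's gold and predicted spans."""
    if mode not in MODES:
        raise ValueError(f"unknown matching mode {mode!r}; valid: {MODES}")
    gold_sorted = sorted(gold)
    pred_sorted = sorted(predicted)
    used = [False] * len(gold_sorted)
    tp = 0
    for pspan in pred_sorted:
        for gi, gspan in enumerate(gold_sorted):
            if used[gi] or gspan[2] != pspan[2]:
                continue
            hit = (gspan[:2] == pspan[:2]) if mode == "strict" else _overlaps(gspan, pspan)
            if hit:
                used[gi] = True
                tp += 1
                break
    return MatchCounts(tp=tp, fp=len(pred_sorted) - tp, fn=len(gold_sorted) - tp)


def prf(counts: MatchCounts) -> PRF:
    """Precision, recall and F1 from counts (zero-denominator -> 0)."""
    if min(counts.tp, counts.fp, counts.fn) < 0:
        raise ValueError(f"negative counts: {counts}")
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return PRF(precision=p, recall=r, f1=f1, counts=counts)


def evaluate_spans(
    gold_spans: Sequence[Sequence[Span]],
    pred_spans: Sequence[Sequence[Span]],
    mode: str = "strict",
) -> MetricReport:
    if len(gold_spans) != len(pred_spans):
        raise ValueError(
            f"gold has {len(gold_spans)} sentences but prediction has {len(pred_spans)}"
        )
    types = sorted(
        {s[2] for sent in gold_spans for s in sent} | {s[2] for sent in pred_spans for s in sent}
    )
    per_type: dict[str, PRF] = {}
    total = MatchCounts()
    for etype in types:
        counts = MatchCounts()
        for g_sent, p_sent in zip(gold_spans, pred_spans):
            g = [s for s in g_sent if s[2] == etype]
            p = [s for s in p_sent if s[2] == etype]
            counts = counts + match_entities(g, p, mode)
        per_type[etype] = prf(counts)
        total = total + counts
    return MetricReport(mode=mode, per_type=per_type, micro=prf(total))


def evaluate_corpus(
    gold: Sequence[AnnotatedSentence],
    predicted: Sequence[AnnotatedSentence],
    mode: str = "strict",
) -> MetricReport:
    """Span metrics between aligned gold and predicted corpora."""
    if len(gold) != len(predicted):
        raise ValueError(f"corpus size mismatch: {len(gold)} gold vs {len(predicted)} predicted")
    for i, (g, p) in enumerate(zip(gold, predicted)):
        if len(g) != len(p):
            raise ValueError(f"sentence {i}: {len(g)} gold tokens vs {len(p)} predicted")
    return evaluate_spans(
        [s.entity_spans() for s in gold], [s.entity_spans() for s in predicted], mode
    )


@dataclass
class NormalizationReport:
    token_accuracy: float
    mention_accuracy: float
    n_tokens: int = 0
    n_mentions: int = 0

    def as_dict(self) -> dict:
        return {
            "token_accuracy": self.token_accuracy,
            "mention_accuracy": self.mention_accuracy,
            "n_tokens": self.n_tokens,
            "n_mentions": self.n_mentions,
        }


def evaluate_normalization(
    gold: Sequence[AnnotatedSentence], predicted: Sequence[AnnotatedSentence]
) -> NormalizationReport:
    """Token- and mention-level accuracy of normalization-ID labels."""
    if len(gold) != len(predicted):
        raise ValueError(f"corpus size mismatch: {len(gold)} vs {len(predicted)}")
    token_hits = tokens = mention_hits = mentions = 0
    for g, p in zip(gold, predicted):
        if len(g) != len(p):
            raise ValueError("token-count mismatch between gold and prediction")
        for gl, pl in zip(g.norm_labels, p.norm_labels):
            tokens += 1
            token_hits += gl == pl
        for start, end, _ in g.entity_spans():
            mentions += 1
            mention_hits += all(
                g.norm_labels[i] == p.norm_labels[i] for i in range(start, end + 1)
            )
    return NormalizationReport(
        token_accuracy=token_hits / tokens if tokens else 0.0,
        mention_accuracy=mention_hits / mentions if mentions else 0.0,
        n_tokens=tokens,
        n_mentions=mentions,
    )
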