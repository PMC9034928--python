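"""Strict/type span matching, P/R/F1 arithmetic, corpus-level reports."""

import networkx as nx
import numpy as np
import pytest

from drugner.corpus import AnnotatedSentence, Token, spans_to_bio
from drugner.evaluation import (
    MatchCounts,
    evaluate_corpus,
    evaluate_normalization,
    evaluate_spans,
    match_entities,
    prf,
)

from conftest import random_spans


def maximum_matching_counts(gold, pred, mode):
    """Independent oracle: maximum bipartite matching on the hit graph."""
    g = nx.Graph()
    g.add_nodes_from([("g", i) for i in range(len(gold))])
    g.add_nodes_from([("p", i) for i in range(len(pred))])
    for gi, gs in enumerate(gold):
        for pi, ps in enumerate(pred):
            if gs[2] != ps[2]:
                continue
            hit = gs[:2] == ps[:2] if mode == "strict" else (gs[0] <= ps[1] and ps[0] <= gs[1])
            if hit:
                g.add_edge(("g", gi), ("p", pi))
    tp = len(nx.algorithms.matching.max_weight_matching(g, maxcardinality=True))
    return MatchCounts(tp=tp, fp=len(pred) - tp, fn=len(gold) - tp)


class TestMatchEntities:
    def test_identical_sets_all_true_positive(self):
        spans = [(0, 1, "DRUG"), (3, 3, "BRAND"), (5, 7, "GROUP")]
        for mode in ("strict", "type"):
            counts = match_entities(spans, spans, mode)
            assert (counts.tp, counts.fp, counts.fn) == (3, 0, 0)

    def test_boundary_error_counts_differ_by_mode(self):
        gold = [(2, 4, "DRUG")]
        pred = [(2, 3, "DRUG")]
        strict = match_entities(gold, pred, "strict")
        assert (strict.tp, strict.fp, strict.fn) == (0, 1, 1)
        typed = match_entities(gold, pred, "type")
        assert (typed.tp, typed.fp, typed.fn) == (1, 0, 0)

    def test_type_mismatch_never_matches(self):
        assert match_entities([(0, 2, "DRUG")], [(0, 2, "BRAND")], "type").tp == 0

    def test_one_to_one_credit(self):
        # one long prediction overlaps two golds: only one may be credited
        counts = match_entities([(0, 1, "DRUG"), (3, 4, "DRUG")], [(0, 4, "DRUG")], "type")
        assert (counts.tp, counts.fp, counts.fn) == (1, 0, 1)

    @pytest.mark.parametrize("mode", ["strict", "type"])
    def test_matches_maximum_bipartite_oracle(self, mode):
        rng = np.random.default_rng(77)
        for _ in range(200):
            n = int(rng.integers(3, 15))
            gold = random_spans(rng, n)
            pred = random_spans(rng, n)
            got = match_entities(gold, pred, mode)
            want = maximum_matching_counts(gold, pred, mode)
            assert (got.tp, got.fp, got.fn) == (want.tp, want.fp, want.fn)

    def test_strict_tp_never_exceeds_type_tp(self):
        rng = np.random.default_rng(78)
        for _ in range(200):
            n = int(rng.integers(3, 12))
            gold = random_spans(rng, n)
            pred = random_spans(rng, n)
            assert match_entities(gold, pred, "strict").tp <= match_entities(gold, pred, "type").tp

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            match_entities([], [], "partial")


class TestPRF:
    def test_hand_arithmetic(self):
        r = prf(MatchCounts(tp=1, fp=1, fn=0))
        assert (r.precision, r.recall) == (0.5, 1.0)
        assert r.f1 == pytest.approx(2 / 3)

    def test_degenerate_all_zero(self):
        r = prf(MatchCounts(0, 0, 0))
        assert (r.precision, r.recall, r.f1) == (0.0, 0.0, 0.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            prf(MatchCounts(-1, 0, 0))

    def test_f1_between_min_and_max(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            counts = MatchCounts(*[int(x) for x in rng.integers(0, 20, 3)])
            r = prf(counts)
            assert min(r.precision, r.recall) - 1e-12 <= r.f1 <= max(r.precision, r.recall) + 1e-12


def _sentence_from_spans(spans, n):
    return AnnotatedSentence([Token(f"w{i}") for i in range(n)], spans_to_bio(spans, n))


class TestEvaluateCorpus:
    # hand-audited 10-sentence fixture: per-type TP/FP/FN tallied on paper
    GOLD = [
        [(0, 0, "DRUG")], [(1, 2, "DRUG")], [(0, 1, "BRAND")], [], [(2, 2, "GROUP")],
        [(0, 0, "DRUG"), (3, 4, "GROUP")], [(1, 1, "BRAND")], [], [(0, 2, "DRUG")], [(4, 4, "DRUG")],
    ]
    PRED = [
        [(0, 0, "DRUG")],            # exact hit             DRUG TP
        [(1, 1, "DRUG")],            # boundary short        DRUG strict FP+FN, type TP
        [(0, 1, "DRUG")],            # wrong type            DRUG FP, BRAND FN
        [(2, 2, "GROUP")],           # spurious              GROUP FP
        [(2, 2, "GROUP")],           # exact hit             GROUP TP
        [(0, 0, "DRUG")],            # one hit, GROUP missed
        [], [], [(0, 2, "DRUG")], [(4, 4, "DRUG")],
    ]
    def report(self, mode):
        return evaluate_spans(self.GOLD, self.PRED, mode)

    def test_hand_counts_strict(self):
        r = self.report("strict")
        d = r.per_type["DRUG"].counts
        assert (d.tp, d.fp, d.fn) == (4, 2, 1)
        b = r.per_type["BRAND"].counts
        assert (b.tp, b.fp, b.fn) == (0, 0, 2)
        g = r.per_type["GROUP"].counts
        assert (g.tp, g.fp, g.fn) == (1, 1, 1)
        assert (r.micro.counts.tp, r.micro.counts.fp, r.micro.counts.fn) == (5, 3, 4)

    def test_hand_counts_type_mode(self):
        r = self.report("type")
        d = r.per_type["DRUG"].counts
        assert (d.tp, d.fp, d.fn) == (5, 1, 0)
        assert (r.micro.counts.tp, r.micro.counts.fp, r.micro.counts.fn) == (6, 2, 3)

    def test_micro_average_equals_prf_of_summed_counts(self):
        for mode in ("strict", "type"):
            r = self.report(mode)
            summed = MatchCounts()
            for entry in r.per_type.values():
                summed = summed + entry.counts
            expected = prf(summed)
            assert r.micro.precision == pytest.approx(expected.precision)
            assert r.micro.f1 == pytest.approx(expected.f1)

    def test_perfect_prediction_scores_100(self):
        r = evaluate_spans(self.GOLD, self.GOLD, "strict")
        assert r.micro.precision == r.micro.recall == r.micro.f1 == 1.0

    def test_all_outside_prediction_scores_zero(self):
        empty = [[] for _ in self.GOLD]
        r = evaluate_spans(self.GOLD, empty, "strict")
        assert r.micro.precision == r.micro.recall == r.micro.f1 == 0.0

    def test_invariant_under_sentence_permutation(self):
        rng = np.random.default_rng(3)
        order = rng.permutation(len(self.GOLD))
        shuffled = evaluate_spans(
            [self.GOLD[i] for i in order], [self.PRED[i] for i in order], "strict"
        )
        assert shuffled.micro.f1 == pytest.approx(self.report("strict").micro.f1)

    def test_sentence_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="10 sentences"):
            evaluate_spans(self.GOLD, self.PRED[:-1], "strict")

    def test_corpus_interface_agrees_with_span_interface(self):
        gold = [_sentence_from_spans(s, 6) for s in self.GOLD]
        pred = [_sentence_from_spans(s, 6) for s in self.PRED]
        assert evaluate_corpus(gold, pred, "strict").micro.f1 == pytest.approx(
            self.report("strict").micro.f1
        )

    def test_report_table_has_micro_row(self):
        table = self.report("strict").format_table()
        assert "Micro-average" in table and "DRUG" in table


class TestNormalization:
    def test_token_and_mention_accuracy(self):
        gold = AnnotatedSentence(
            [Token(w) for w in "a b c d".split()],
            ["B-DRUG", "I-DRUG", "O", "B-DRUG"],
            ["D1", "D1", "NIL", "D2"],
        )
        pred = AnnotatedSentence(
            [Token(w) for w in "a b c d".split()],
            ["B-DRUG", "I-DRUG", "O", "B-DRUG"],
            ["D1", "D9", "NIL", "D2"],
        )
        r = evaluate_normalization([gold], [pred])
        assert r.token_accuracy == pytest.approx(3 / 4)
        # first mention broken by its second token, second mention correct
        assert r.mention_accuracy == pytest.approx(1 / 2)
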