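"""CRF: enumeration oracles, gradient checks, decoding contracts."""

import numpy as np
import pytest

from drugner.nn.crf import (
    NEG_INF,
    bio_transition_penalties,
    crf_nll,
    crf_nll_grad,
    init_transitions,
    log_partition,
    score_sequence,
    start_index,
    stop_index,
    viterbi_decode,
)


def enumerate_scores(P, A):
    """Vectorized brute force: path scores for all k^n label sequences."""
    n, k = P.shape
    paths = np.indices((k,) * n).reshape(n, -1).T  # (k^n, n)
    start, stop = start_index(k), stop_index(k)
    scores = A[start, paths[:, 0]] + A[paths[:, -1], stop]
    scores = scores + P[np.arange(n), paths].sum(axis=1)
    for t in range(n - 1):
        scores = scores + A[paths[:, t], paths[:, t + 1]]
    return paths, scores


def random_instance(rng, n=None, k=None):
    n = n or int(rng.integers(1, 7))
    k = k or int(rng.integers(1, 6))
    P = rng.normal(size=(n, k))
    A = init_transitions(k, rng, scale=1.0)
    z = rng.integers(0, k, size=n)
    return P, A, z


class TestScoreSequence:
    def test_all_zero_scores(self):
        k = 3
        A = np.zeros((k + 2, k + 2))
        P = np.zeros((4, k))
        for z in ([0, 1, 2, 0], [2, 2, 2, 2]):
            assert score_sequence(P, A, np.array(z)) == 0.0

    def test_hand_sum_n1(self):
        # START->0 = 0.5, 0->STOP = 0.25, emission 1.0 => 1.75
        k = 2
        A = np.zeros((k + 2, k + 2))
        A[start_index(k), 0] = 0.5
        A[0, stop_index(k)] = 0.25
        P = np.array([[1.0, 2.0]])
        assert score_sequence(P, A, np.array([0])) == pytest.approx(1.75)

    def test_matches_explicit_loop(self, rng):
        P, A, z = random_instance(rng, n=4, k=3)
        expected = A[start_index(3), z[0]] + A[z[-1], stop_index(3)]
        for i in range(4):
            expected += P[i, z[i]]
        for i in range(3):
            expected += A[z[i], z[i + 1]]
        assert score_sequence(P, A, z) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_label_rejected(self, rng):
        P, A, _ = random_instance(rng, n=3, k=2)
        with pytest.raises(ValueError, match="out of range"):
            score_sequence(P, A, np.array([0, 2, 0]))


class TestLogPartition:
    def test_closed_form_n1_zero_scores(self):
        for k in (1, 2, 5):
            P = np.zeros((1, k))
            A = np.zeros((k + 2, k + 2))
            assert log_partition(P, A) == pytest.approx(np.log(k), abs=1e-12)

    def test_matches_enumeration(self, rng):
        for _ in range(30):
            P, A, _ = random_instance(rng)
            _, scores = enumerate_scores(P, A)
            m = scores.max()
            expected = m + np.log(np.exp(scores - m).sum())
            assert log_partition(P, A) == pytest.approx(expected, abs=1e-8)

    def test_row_shift_invariance(self, rng):
        P, A, _ = random_instance(rng, n=4, k=3)
        base = log_partition(P, A)
        P2 = P.copy()
        P2[2] += 1.7
        assert log_partition(P2, A) == pytest.approx(base + 1.7, abs=1e-10)

    def test_upper_bounds_any_path_score(self, rng):
        P, A, z = random_instance(rng)
        assert log_partition(P, A) >= score_sequence(P, A, z)


class TestNLL:
    def test_single_label_loss_zero(self, rng):
        P, A, z = random_instance(rng, k=1)
        assert crf_nll(P, A, z) == pytest.approx(0.0, abs=1e-12)

    def test_matches_enumeration(self, rng):
        P, A, z = random_instance(rng, n=4, k=3)
        paths, scores = enumerate_scores(P, A)
        gold = score_sequence(P, A, z)
        m = scores.max()
        logZ = m + np.log(np.exp(scores - m).sum())
        assert crf_nll(P, A, z) == pytest.approx(logZ - gold, abs=1e-8)

    def test_nonnegative_and_monotone_in_gold_emission(self, rng):
        for _ in range(20):
            P, A, z = random_instance(rng)
            loss = crf_nll(P, A, z)
            assert loss >= -1e-12
            P2 = P.copy()
            P2[0, z[0]] += 0.5
            assert crf_nll(P2, A, z) < loss + 1e-12

    def test_analytic_gradient_matches_numerics(self, rng):
        P, A, z = random_instance(rng, n=5, k=4)
        _, dP, dA = crf_nll_grad(P, A, z)
        eps = 1e-6
        for idx in [(0, 0), (2, 3), (4, 1)]:
            P2 = P.copy()
            P2[idx] += eps
            P3 = P.copy()
            P3[idx] -= eps
            num = (crf_nll(P2, A, z) - crf_nll(P3, A, z)) / (2 * eps)
            assert num == pytest.approx(dP[idx], rel=1e-4, abs=1e-8)
        for idx in [(0, 1), (start_index(4), 2), (3, stop_index(4))]:
            A2 = A.copy()
            A2[idx] += eps
            A3 = A.copy()
            A3[idx] -= eps
            num = (crf_nll(P, A2, z) - crf_nll(P, A3, z)) / (2 * eps)
            assert num == pytest.approx(dA[idx], rel=1e-4, abs=1e-8)


class TestViterbi:
    def test_diagonal_dominant_reduces_to_argmax(self):
        P = np.array([[9.0, 0, 0], [0, 9.0, 0], [0, 0, 9.0]])
        A = np.zeros((5, 5))
        path, score = viterbi_decode(P, A)
        np.testing.assert_array_equal(path, [0, 1, 2])
        assert score == pytest.approx(27.0)

    def test_matches_enumeration(self, rng):
        for _ in range(30):
            P, A, _ = random_instance(rng)
            paths, scores = enumerate_scores(P, A)
            path, score = viterbi_decode(P, A)
            assert score == pytest.approx(scores.max(), abs=1e-8)
            assert score == pytest.approx(score_sequence(P, A, path), abs=1e-10)
            # path equality when the max is unique
            order = np.sort(scores)
            if order.size == 1 or order[-1] - order[-2] > 1e-9:
                np.testing.assert_array_equal(path, paths[int(np.argmax(scores))])

    def test_tie_break_all_lowest_index(self):
        P = np.zeros((4, 3))
        A = np.zeros((5, 5))
        path, score = viterbi_decode(P, A)
        np.testing.assert_array_equal(path, [0, 0, 0, 0])
        assert score == 0.0

    def test_path_probabilities_normalize(self, rng):
        P, A, _ = random_instance(rng, n=4, k=3)
        _, scores = enumerate_scores(P, A)
        total = np.exp(scores - log_partition(P, A)).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_viterbi_score_never_exceeds_log_partition(self, rng):
        P, A, _ = random_instance(rng)
        _, score = viterbi_decode(P, A)
        assert score <= log_partition(P, A) + 1e-10


class TestBioMask:
    def test_forbidden_transitions_never_decoded(self, rng):
        labels = ["O", "B-DRUG", "I-DRUG", "B-BRAND", "I-BRAND"]
        k = len(labels)
        mask = bio_transition_penalties(labels)
        for _ in range(20):
            P = rng.normal(scale=5.0, size=(6, k))
            A = init_transitions(k, rng, scale=1.0)
            path, _ = viterbi_decode(P, A + mask)
            decoded = [labels[j] for j in path]
            prev = "O"
            for label in decoded:
                if label.startswith("I-"):
                    assert prev in (f"B-{label[2:]}", f"I-{label[2:]}")
                prev = label

    def test_mask_structure(self):
        labels = ["O", "B-DRUG", "I-DRUG"]
        mask = bio_transition_penalties(labels)
        assert mask[0, 2] == NEG_INF  # O -> I-DRUG forbidden
        assert mask[1, 2] == 0.0  # B-DRUG -> I-DRUG allowed
        assert mask[start_index(3), 2] == NEG_INF  # cannot start inside
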