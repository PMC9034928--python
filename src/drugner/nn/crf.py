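"""Linear-chain conditional random field in log space.

The CRF scores a label sequence ``z`` for an ``n``-token sentence as

    s(z) = A[START, z_1] + sum_i A[z_i, z_{i+1}] + A[z_n, STOP] + sum_i P[i, z_i]

where ``P`` (n x k) holds per-token emission scores produced by the encoder
and ``A`` ((k+2) x (k+2)) holds label-transition scores with distinguished
START = k and STOP = k+1 rows.  Training minimizes the negative
log-likelihood ``logZ - s(gold)`` where the partition ``logZ`` is computed
by the forward recursion; decoding is exact Viterbi.  All arithmetic is in
log space; impossible transitions carry a large negative sentinel rather
than -inf so gradients stay finite.
"""

from __future__ import annotations

import numpy as np

from .core import logsumexp, softmax

NEG_INF = -1.0e4


def start_index(k: int) -> int:
    return k


def stop_index(k: int) -> int:
    return k + 1


def init_transitions(k: int, rng: np.random.Generator, scale: float = 0.1) -> np.ndarray:
    """Random (k+2)x(k+2) transition matrix with forbidden entries masked.

    Transitions into START and out of STOP never lie on a path; they are
    pinned at the sentinel.
    """
    A = rng.uniform(-scale, scale, size=(k + 2, k + 2))
    A[:, start_index(k)] = NEG_INF
    A[stop_index(k), :] = NEG_INF
    return A


def _check(P: np.ndarray, A: np.ndarray) -> int:
    n, k = P.shape
    if n < 1:
        raise ValueError("emission matrix must cover at least one token")
    if A.shape != (k + 2, k + 2):
        raise ValueError(f"transition matrix shape {A.shape} != ({k + 2}, {k + 2})")
    return k


def score_sequence(P: np.ndarray, A: np.ndarray, z: np.ndarray) -> float:
    """Path score of label sequence ``z`` (START/STOP transitions implicit)."""
    P = np.asarray(P, dtype=float)
    A = np.asarray(A, dtype=float)
    z = np.asarray(z, dtype=int)
    k = _check(P, A)
    n = P.shape[0]
    if z.shape != (n,):
        raise ValueError(f"label sequence length {z.shape} != {n}")
    if np.any(z < 0) or np.any(z >= k):
        raise ValueError(f"label index out of range [0, {k})")
    total = A[start_index(k), z[0]] + A[z[-1], stop_index(k)]
    total += float(P[np.arange(n), z].sum())
    if n > 1:
        total += float(A[z[:-1], z[1:]].sum())
    return float(total)


def forward_scores(P: np.ndarray, A: np.ndarray) -> tuple[np.ndarray, float]:
    """Forward (alpha) lattice and the log-partition logZ."""
    k = _check(P, A)
    n = P.shape[0]
    alpha = np.empty((n, k))
    alpha[0] = A[start_index(k), :k] + P[0]
    inner = A[:k, :k]
    for t in range(1, n):
        alpha[t] = logsumexp(alpha[t - 1][:, None] + inner, axis=0) + P[t]
    logZ = float(logsumexp(alpha[-1] + A[:k, stop_index(k)], axis=0))
    return alpha, logZ


def backward_scores(P: np.ndarray, A: np.ndarray) -> np.ndarray:
    k = _check(P, A)
    n = P.shape[0]
    beta = np.empty((n, k))
    beta[-1] = A[:k, stop_index(k)]
    inner = A[:k, :k]
    for t in range(n - 2, -1, -1):
        beta[t] = logsumexp(inner + (P[t + 1] + beta[t + 1])[None, :], axis=1)
    return beta


def log_partition(P: np.ndarray, A: np.ndarray) -> float:
    """log of the sum over all k^n label sequences of exp(path score)."""
    return forward_scores(np.asarray(P, float), np.asarray(A, float))[1]


def crf_nll(P: np.ndarray, A: np.ndarray, z: np.ndarray) -> float:
    """Negative log-likelihood of the gold path: logZ - s(gold); >= 0."""
    return log_partition(P, A) - score_sequence(P, A, z)


def crf_nll_grad(
    P: np.ndarray, A: np.ndarray, z: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """NLL plus analytic gradients d(NLL)/dP and d(NLL)/dA.

    The gradient is (expected - observed) feature counts: unary marginals
    minus the gold one-hots for ``P``; pairwise marginals minus gold
    transitions for the inner block of ``A``, with the START row and STOP
    column handled via the first/last unary marginals.
    """
    P = np.asarray(P, dtype=float)
    A = np.asarray(A, dtype=float)
    z = np.asarray(z, dtype=int)
    k = _check(P, A)
    n = P.shape[0]
    start, stop = start_index(k), stop_index(k)

    alpha, logZ = forward_scores(P, A)
    beta = backward_scores(P, A)
    marginals = softmax(alpha + beta, axis=1)  # rows normalize to 1 at optimum of lse

    dP = marginals.copy()
    dP[np.arange(n), z] -= 1.0

    dA = np.zeros_like(A)
    inner = A[:k, :k]
    for t in range(n - 1):
        pair = alpha[t][:, None] + inner + (P[t + 1] + beta[t + 1])[None, :] - logZ
        dA[:k, :k] += np.exp(pair)
        dA[z[t], z[t + 1]] -= 1.0
    dA[start, :k] += marginals[0]
    dA[start, z[0]] -= 1.0
    dA[:k, stop] += marginals[-1]
    dA[z[-1], stop] -= 1.0

    loss = logZ - score_sequence(P, A, z)
    return float(loss), dP, dA


def viterbi_decode(P: np.ndarray, A: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact best-path decode.

    Returns the argmax label sequence and its path score; ties break toward
    the lowest label index at the latest decision point (argmax convention).
    """
    P = np.asarray(P, dtype=float)
    A = np.asarray(A, dtype=float)
    k = _check(P, A)
    n = P.shape[0]
    start, stop = start_index(k), stop_index(k)

    delta = A[start, :k] + P[0]
    back = np.empty((n, k), dtype=int)
    inner = A[:k, :k]
    for t in range(1, n):
        cand = delta[:, None] + inner  # cand[i, j]: best-so-far ending i, then j
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(k)] + P[t]
    final = delta + A[:k, stop]
    last = int(np.argmax(final))
    path = np.empty(n, dtype=int)
    path[-1] = last
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, float(final[last])


def bio_transition_penalties(labels: list[str]) -> np.ndarray:
    """Optional hard BIO constraint mask for decoding.

    Returns a (k+2) x (k+2) matrix that is 0 for legal transitions and the
    sentinel for illegal ones (I-X may only follow B-X or I-X; START may not
    enter I-X).  Add it to ``A`` before decoding to forbid ill-formed output
    structurally instead of repairing it afterwards.
    """
    k = len(labels)
    mask = np.zeros((k + 2, k + 2))
    start, stop = start_index(k), stop_index(k)
    for j, to_label in enumerate(labels):
        if not to_label.startswith("I-"):
            continue
        etype = to_label[2:]
        legal_from = {f"B-{etype}", f"I-{etype}"}
        for i, from_label in enumerate(labels):
            if from_label not in legal_from:
                mask[i, j] = NEG_INF
        mask[start, j] = NEG_INF
    mask[:, start] = NEG_INF
    mask[stop, :] = NEG_INF
    return mask
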