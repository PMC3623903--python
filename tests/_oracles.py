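"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own algorithmic code paths: the CRF
oracle enumerates all label paths, the alignment oracle is a plain Gotoh
dynamic program, and the AUC oracle averages over all positive-negative
pairs.
"""

from __future__ import annotations

import itertools

import numpy as np


def crf_enumerate(S: np.ndarray, T: np.ndarray):
    """Exhaustive enumeration over all 3^L label paths.

    Returns (log_Z, node marginals (L,3), best_path) with ties in the best
    path broken toward the lexicographically smallest label sequence.
    """
    L = S.shape[0]
    log_z_terms = []
    marg = np.zeros((L, 3))
    best_score, best_path = -np.inf, None
    for path in itertools.product(range(3), repeat=L):
        sc = sum(S[i, p] for i, p in enumerate(path))
        sc += sum(T[a, b] for a, b in zip(path, path[1:]))
        log_z_terms.append(sc)
        if sc > best_score + 1e-12:
            best_score, best_path = sc, path
    log_z_terms = np.array(log_z_terms)
    m = log_z_terms.max()
    log_z = m + np.log(np.exp(log_z_terms - m).sum())
    for weight, path in zip(
        np.exp(log_z_terms - log_z), itertools.product(range(3), repeat=L)
    ):
        for i, p in enumerate(path):
            marg[i, p] += weight
    return float(log_z), marg, best_path


def smith_waterman_score(
    a: str, b: str, matrix, gap_open: int = 11, gap_extend: int = 1
) -> float:
    """Gotoh local alignment score with BLAST-convention affine gaps
    (a gap of length k costs open + k*extend)."""
    n, m = len(a), len(b)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in b (deletion from a)
    F = np.full((n + 1, m + 1), NEG)  # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(E[i, j - 1] - gap_extend, H[i, j - 1] - gap_open - gap_extend)
            F[i, j] = max(F[i - 1, j] - gap_extend, H[i - 1, j] - gap_open - gap_extend)
            sub = matrix[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, H[i - 1, j - 1] + sub, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


def pairwise_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean over all positive-negative pairs; ties count 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
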