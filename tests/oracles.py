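"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's own code paths: set partitions are
enumerated via restricted-growth strings, minimax path distances via a
Floyd-Warshall-style recursion on the full matrix, and partition quality
by direct summation.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np


def set_partitions(n: int) -> Iterator[tuple[int, ...]]:
    """All partitions of n items as canonical label tuples (Bell(n) many)."""
    labels = [0] * n

    def rec(i: int, maxlab: int):
        if i == n:
            yield tuple(labels)
            return
        for lab in range(maxlab + 2):
            labels[i] = lab
            yield from rec(i + 1, max(maxlab, lab))

    yield from rec(1, 0)


def minimax_distances(D: np.ndarray) -> np.ndarray:
    """Minimax path distance between all pairs: min over paths of the
    maximum edge, computed by the Floyd-Warshall recursion."""
    mm = D.astype(float).copy()
    n = len(mm)
    np.fill_diagonal(mm, 0.0)
    for k in range(n):
        np.minimum(mm, np.maximum(mm[:, k][:, None], mm[k, :][None, :]), out=mm)
    return mm


def rmst_keep_rule(D: np.ndarray, gamma: float) -> set[tuple[int, int]]:
    """Direct application of the relaxed-MST keep rule to every pair."""
    n = len(D)
    mm = minimax_distances(D)
    masked = D.astype(float).copy()
    np.fill_diagonal(masked, np.inf)
    dnn = masked.min(axis=1)
    kept = set()
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] <= mm[i, j] + (dnn[i] + dnn[j]) / gamma:
                kept.add((i, j))
    return kept


def partition_quality(R: np.ndarray, labels) -> float:
    """Direct block-sum of R over the communities of `labels`."""
    labels = np.asarray(labels)
    total = 0.0
    for c in set(labels.tolist()):
        idx = np.flatnonzero(labels == c)
        for a in idx:
            for b in idx:
                total += R[a, b]
    return float(total)


def best_partition_bruteforce(R: np.ndarray) -> tuple[float, tuple[int, ...]]:
    """Exhaustive maximisation of the block sum over all partitions."""
    n = len(R)
    best_q, best_p = -np.inf, None
    for part in set_partitions(n):
        q = partition_quality(R, part)
        if q > best_q + 1e-15:
            best_q, best_p = q, part
    return best_q, best_p
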