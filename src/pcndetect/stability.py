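"""Markov-stability community detection with Louvain optimisation.

A continuous-time random walk on the weighted practice network has
transition operator M = D^-1 A (D the diagonal degree matrix) and
stationary distribution pi = k / 2m. The stability of a partition H at
Markov time t is

    r(t, H) = sum over communities c of sum_{i,j in c} R(t)_ij,
    R(t) = Pi exp(t (M - I)) - pi pi^T,   Pi = diag(pi),

the probability that a random walk at stationarity stays within its
starting community after time t, minus the chance level. Small t rewards
fine partitions (at t = 0 the off-diagonal entries are all negative), large
t coarser ones, which is what makes the method multiscale. The full matrix
exponential is used by default; a linearised variant
Pi (I + t (M - I)) - pi pi^T is available for speed and reduces to
Newman-Girvan modularity at t = 1.

r(t, H) is maximised by a Louvain scheme run on the fixed t-dependent
matrix R(t): repeated sweeps of greedy single-node moves followed by
aggregation (summing matrix blocks), which leaves the objective on the
original matrix exact. Node sweep order is randomised from a seed;
repeated runs are combined by taking the most common partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .rmst import SparseGraph

logger = logging.getLogger(__name__)

_MAX_SWEEPS = 200
_MAX_LEVELS = 50
_GAIN_TOL = 1e-12


@dataclass
class StabilityModel:
    """Random-walk operators of a weighted graph."""

    adjacency: np.ndarray
    degrees: np.ndarray
    transition: np.ndarray      # M = D^-1 A, rows sum to 1
    pi: np.ndarray              # stationary distribution k / 2m

    @property
    def n(self) -> int:
        return len(self.pi)


def random_walk_operators(graph: SparseGraph | np.ndarray) -> StabilityModel:
    """Build M and pi from a sparse graph or a dense adjacency matrix.

    A node with zero weighted degree (possible when every incident edge
    has zero similarity) is given a self-loop in M and zero stationary
    mass, so it forms its own community at every time.
    """
    A = graph.adjacency() if isinstance(graph, SparseGraph) else np.asarray(graph, float)
    if np.any(A < 0):
        raise ValueError("negative edge weight")
    k = A.sum(axis=1)
    total = k.sum()
    if total <= 0:
        raise ValueError("graph has no positive-weight edges")
    if np.any(k == 0):
        logger.warning("%d zero-degree nodes held as singletons", int((k == 0).sum()))
    M = np.where(k[:, None] > 0, A / np.where(k[:, None] > 0, k[:, None], 1.0), 0.0)
    M[k == 0, :] = 0.0
    M[np.flatnonzero(k == 0), np.flatnonzero(k == 0)] = 1.0
    pi = k / total
    return StabilityModel(adjacency=A, degrees=k, transition=M, pi=pi)


def stability_matrix(model: StabilityModel, t: float, method: str = "exponential") -> np.ndarray:
    """The matrix R(t) whose block sums give partition stability.

    R(t) is symmetric in exact arithmetic (Pi M^k is symmetric for the
    reversible walk); symmetry is enforced against rounding.
    """
    n = model.n
    if method == "exponential":
        T = expm(t * (model.transition - np.eye(n)))
    elif method == "linearised":
        T = np.eye(n) + t * (model.transition - np.eye(n))
    else:
        raise ValueError(f"unknown stability method {method!r}")
    R = model.pi[:, None] * T - np.outer(model.pi, model.pi)
    return (R + R.T) / 2.0


def canonical_labels(labels) -> tuple[int, ...]:
    """Relabel communities by order of first appearance (0, 1, 2, ...)."""
    mapping: dict[int, int] = {}
    out = []
    for lab in labels:
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out.append(mapping[lab])
    return tuple(out)


@dataclass
class Partition:
    """Canonical node labelling with its stability value and multiplicity."""

    labels: tuple[int, ...]
    stability: float
    markov_time: float = float("nan")
    multiplicity: int = 1

    @property
    def n_communities(self) -> int:
        return len(set(self.labels))

    def members(self) -> list[list[int]]:
        comms: dict[int, list[int]] = {}
        for i, lab in enumerate(self.labels):
            comms.setdefault(lab, []).append(i)
        return [comms[c] for c in sorted(comms)]


def stability_score(R: np.ndarray, labels) -> float:
    """Block sum of R over communities: r(t, H)."""
    labels = np.asarray(labels)
    total = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        total += R[np.ix_(idx, idx)].sum()
    return float(total)


def _local_moves(B: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Greedy single-node moves maximising the block sum of B.

    The gain of moving node i from community a to community b is
    2 (l_ib - l_ia) with l_ic the summed weight from i to c \\ {i}; B_ii
    travels with the node and cancels. Empty community slots have l = 0,
    so detaching a node into a singleton is considered automatically.
    """
    n = len(B)
    comm = np.arange(n)
    improved_any = False
    for sweep in range(_MAX_SWEEPS):
        moved = False
        for i in rng.permutation(n):
            links = np.bincount(comm, weights=B[i], minlength=n)
            links[comm[i]] -= B[i, i]
            best = int(np.argmax(links))
            if best != comm[i] and links[best] - links[comm[i]] > _GAIN_TOL:
                comm[i] = best
                moved = improved_any = True
        if not moved:
            return comm, improved_any
    raise RuntimeError(
        f"Louvain local phase failed to converge within {_MAX_SWEEPS} sweeps "
        f"(n={n}, {len(np.unique(comm))} communities)"
    )


def louvain_optimise(
    R: np.ndarray, seed: int, markov_time: float = float("nan")
) -> Partition:
    """One seeded Louvain run on the stability matrix R(t).

    Local moves alternate with aggregation (summing blocks of R), so the
    score of the coarse matrix equals r on the original matrix exactly.
    Returns the partition in canonical form with its stability value.
    """
    rng = np.random.default_rng(seed)
    n = len(R)
    node_comm = np.arange(n)
    B = np.array(R, dtype=float)
    for _level in range(_MAX_LEVELS):
        labels, improved = _local_moves(B, rng)
        uniq, compact = np.unique(labels, return_inverse=True)
        node_comm = compact[node_comm]
        if not improved or len(uniq) == len(B):
            break
        H = np.zeros((len(B), len(uniq)))
        H[np.arange(len(B)), compact] = 1.0
        B = H.T @ B @ H
    else:
        raise RuntimeError(f"Louvain aggregation failed to converge within {_MAX_LEVELS} levels")
    labels = canonical_labels(node_comm)
    return Partition(
        labels=labels,
        stability=stability_score(R, labels),
        markov_time=markov_time,
    )


def consensus_partition(runs: list[Partition]) -> Partition:
    """Most common canonical partition among repeated runs.

    Multiplicity ties are broken by higher mean stability, then by the
    lexicographically smallest canonical labelling.
    """
    if not runs:
        raise ValueError("no runs to take a consensus over")
    groups: dict[tuple[int, ...], list[Partition]] = {}
    for p in runs:
        groups.setdefault(p.labels, []).append(p)
    best_key = min(
        groups,
        key=lambda lab: (-len(groups[lab]), -float(np.mean([p.stability for p in groups[lab]])), lab),
    )
    members = groups[best_key]
    return Partition(
        labels=best_key,
        stability=float(np.mean([p.stability for p in members])),
        markov_time=members[0].markov_time,
        multiplicity=len(members),
    )
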