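"""Relaxed minimum spanning tree sparsification of the similarity network.

The dense similarity matrix is turned into distances d = 1 - s and
sparsened: an edge (A, B) survives when

    d_AB <= mlink_AB + (dNN_A + dNN_B) / gamma

where mlink_AB is the largest edge on the path between A and B in a
minimum spanning tree (the minimax path weight, identical for every MST),
and dNN_X is the distance from X to its nearest neighbour. The relaxation
term measures local scale: nodes in dense neighbourhoods tolerate longer
direct edges. Dividing by the pruning parameter gamma makes larger gamma
prune harder; a multiplicative variant (relaxation times gamma, with the
opposite direction) is available as ``variant="multiplicative"``. All MST
edges are kept regardless, so the output is always connected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def to_distance(S: np.ndarray) -> np.ndarray:
    """Distance matrix d = 1 - s, clipped to [0, 1], zero diagonal."""
    D = np.clip(1.0 - np.asarray(S, dtype=float), 0.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def minimum_spanning_tree_edges(D: np.ndarray) -> list[tuple[int, int, float]]:
    """Prim's algorithm on a complete distance matrix.

    Runs in O(n^2); handles zero distances (which sparse-matrix MST codes
    conflate with absent edges). Ties resolve to the smallest node index,
    so the tree is deterministic.
    """
    n = len(D)
    in_tree = np.zeros(n, dtype=bool)
    best_dist = np.full(n, np.inf)
    best_from = np.full(n, -1, dtype=int)
    in_tree[0] = True
    best_dist[1:] = D[0, 1:]
    best_from[1:] = 0
    edges: list[tuple[int, int, float]] = []
    for _ in range(n - 1):
        masked = np.where(in_tree, np.inf, best_dist)
        v = int(np.argmin(masked))
        u = int(best_from[v])
        edges.append((min(u, v), max(u, v), float(D[u, v])))
        in_tree[v] = True
        closer = ~in_tree & (D[v] < best_dist)
        best_dist[closer] = D[v, closer]
        best_from[closer] = v
    return edges


def maxlink_matrix(tree_edges: list[tuple[int, int, float]], n: int) -> np.ndarray:
    """Maximum edge weight on the tree path between every pair of nodes.

    Depth-first traversal from each root carries the running path maximum;
    O(n^2) total. The diagonal is zero.
    """
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for u, v, w in tree_edges:
        adj[u].append((v, w))
        adj[v].append((u, w))
    mlink = np.zeros((n, n))
    for root in range(n):
        stack = [(root, 0.0)]
        seen = np.zeros(n, dtype=bool)
        seen[root] = True
        while stack:
            node, running = stack.pop()
            for nbr, w in adj[node]:
                if not seen[nbr]:
                    seen[nbr] = True
                    m = max(running, w)
                    mlink[root, nbr] = m
                    stack.append((nbr, m))
    return mlink


def nearest_neighbour_distances(D: np.ndarray) -> np.ndarray:
    """Distance from each node to its nearest other node."""
    masked = D.astype(float).copy()
    np.fill_diagonal(masked, np.inf)
    return masked.min(axis=1)


@dataclass
class SparseGraph:
    """Undirected weighted graph over the practice set.

    ``edges`` is an (m, 2) int array with i < j; ``weights`` holds the
    similarity 1 - d of each kept edge. Contains every MST edge, hence is
    connected as an unweighted graph (individual weights may be zero when
    the endpoints share no LSOA support).
    """

    n: int
    edges: np.ndarray
    weights: np.ndarray
    gamma: float
    gp_ids: list[str] | None = None

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        A = np.zeros((self.n, self.n))
        A[self.edges[:, 0], self.edges[:, 1]] = self.weights
        A[self.edges[:, 1], self.edges[:, 0]] = self.weights
        return A

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.edges}

    def write_edge_csv(self, path) -> None:
        import pandas as pd

        ids = self.gp_ids if self.gp_ids is not None else [str(i) for i in range(self.n)]
        ids = np.asarray(ids)
        pd.DataFrame({
            "gp_a": ids[self.edges[:, 0]],
            "gp_b": ids[self.edges[:, 1]],
            "weight": self.weights,
        }).to_csv(path, index=False)


def rmst_sparsify(
    D: np.ndarray,
    gamma: float,
    gp_ids: list[str] | None = None,
    variant: str = "divisive",
    _precomputed: tuple[list, np.ndarray, np.ndarray] | None = None,
) -> SparseGraph:
    """Apply the relaxed-MST keep rule at pruning parameter ``gamma``.

    ``_precomputed`` optionally carries (tree_edges, mlink, dnn) so a grid
    of gamma values reuses the gamma-independent work. Boundary equality
    keeps the edge, so the gamma -> infinity limit is the MST plus edges
    tied with their minimax path.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    D = np.asarray(D, dtype=float)
    n = len(D)
    if _precomputed is None:
        tree_edges = minimum_spanning_tree_edges(D)
        mlink = maxlink_matrix(tree_edges, n)
        dnn = nearest_neighbour_distances(D)
    else:
        tree_edges, mlink, dnn = _precomputed

    if variant == "divisive":
        relax = (dnn[:, None] + dnn[None, :]) / gamma
    elif variant == "multiplicative":
        relax = (dnn[:, None] + dnn[None, :]) * gamma
    else:
        raise ValueError(f"unknown RMST variant {variant!r}")

    keep = D <= mlink + relax
    for u, v, _ in tree_edges:
        keep[u, v] = keep[v, u] = True
    iu, ju = np.triu_indices(n, k=1)
    sel = keep[iu, ju]
    edges = np.column_stack([iu[sel], ju[sel]])
    weights = 1.0 - D[iu[sel], ju[sel]]
    return SparseGraph(n=n, edges=edges, weights=weights, gamma=gamma, gp_ids=gp_ids)
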