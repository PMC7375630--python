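"""Markov-stability operators, Louvain optimisation, consensus selection."""

import numpy as np
import pytest
from scipy.linalg import expm

from oracles import best_partition_bruteforce, partition_quality
from pcndetect import (
    Partition,
    canonical_labels,
    consensus_partition,
    louvain_optimise,
    random_walk_operators,
    stability_matrix,
    stability_score,
)


def _adjacency(edges, n):
    A = np.zeros((n, n))
    for i, j in edges:
        A[i, j] = A[j, i] = 1.0
    return A


TRIANGLE_PAIR = _adjacency([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)], 6)
BRIDGED_TRIANGLES = TRIANGLE_PAIR + _adjacency([(2, 3)], 6)


class TestOperators:
    def test_single_edge_stationary_distribution(self):
        model = random_walk_operators(_adjacency([(0, 1)], 2))
        assert np.allclose(model.pi, [0.5, 0.5])

    def test_star_stationary_distribution(self):
        model = random_walk_operators(_adjacency([(0, 1), (0, 2), (0, 3)], 4))
        assert np.allclose(model.pi, [1 / 2, 1 / 6, 1 / 6, 1 / 6])

    @pytest.mark.parametrize("t", [0.0, 0.3, 1.0, 4.0])
    def test_heat_kernel_rows_remain_stochastic(self, t):
        model = random_walk_operators(BRIDGED_TRIANGLES)
        T = expm(t * (model.transition - np.eye(6)))
        assert np.allclose(T.sum(axis=1), 1.0)
        assert T.min() > -1e-12

    def test_zero_weight_graph_rejected(self):
        with pytest.raises(ValueError):
            random_walk_operators(np.zeros((3, 3)))


class TestStabilityScore:
    def test_all_in_one_partition_scores_zero(self):
        model = random_walk_operators(BRIDGED_TRIANGLES)
        for t in [0.0, 0.5, 1.0]:
            R = stability_matrix(model, t)
            assert stability_score(R, [0] * 6) == pytest.approx(0.0, abs=1e-12)

    def test_finest_partition_at_time_zero(self):
        model = random_walk_operators(TRIANGLE_PAIR)
        R = stability_matrix(model, 0.0)
        expected = 1.0 - np.sum(model.pi ** 2)
        assert stability_score(R, range(6)) == pytest.approx(expected, abs=1e-12)

    def test_two_node_closed_form(self):
        """r(t) = exp(-2t)/2 for the singleton partition of a single edge."""
        model = random_walk_operators(_adjacency([(0, 1)], 2))
        for t in [0.1, 0.5, 2.0]:
            R = stability_matrix(model, t)
            assert stability_score(R, [0, 1]) == pytest.approx(np.exp(-2 * t) / 2, abs=1e-12)
        R = stability_matrix(model, 0.5)
        assert stability_score(R, [0, 1]) == pytest.approx(0.18394, abs=5e-6)

    def test_linearised_equals_exponential_to_first_order(self):
        model = random_walk_operators(BRIDGED_TRIANGLES)
        t = 1e-4
        assert np.allclose(stability_matrix(model, t),
                           stability_matrix(model, t, method="linearised"), atol=1e-8)


class TestLouvain:
    def test_disconnected_triangles_found(self):
        model = random_walk_operators(TRIANGLE_PAIR)
        R = stability_matrix(model, 0.5)
        part = louvain_optimise(R, seed=0)
        assert part.labels == (0, 0, 0, 1, 1, 1)
        _, best = best_partition_bruteforce(R)
        assert best == part.labels

    def test_bridged_triangles_across_times(self):
        """Exhaustive enumeration says the finest partition rules at short
        times and the two triangles at t = 1; Louvain agrees with both."""
        model = random_walk_operators(BRIDGED_TRIANGLES)
        R_short = stability_matrix(model, 0.1)
        assert louvain_optimise(R_short, seed=3).labels == tuple(range(6))
        assert best_partition_bruteforce(R_short)[1] == tuple(range(6))
        R_unit = stability_matrix(model, 1.0)
        part = louvain_optimise(R_unit, seed=3)
        assert part.labels == (0, 0, 0, 1, 1, 1)
        assert best_partition_bruteforce(R_unit)[1] == part.labels

    def test_time_zero_gives_finest_partition(self):
        model = random_walk_operators(BRIDGED_TRIANGLES)
        R = stability_matrix(model, 0.0)
        part = louvain_optimise(R, seed=1)
        assert part.n_communities == 6

    def test_score_matches_direct_summation(self):
        model = random_walk_operators(BRIDGED_TRIANGLES)
        R = stability_matrix(model, 0.4)
        part = louvain_optimise(R, seed=7)
        assert part.stability == pytest.approx(partition_quality(R, part.labels), abs=1e-12)

    def test_node_relabelling_equivariance(self):
        """Permuting the nodes permutes the canonical partition identically."""
        model = random_walk_operators(BRIDGED_TRIANGLES)
        R = stability_matrix(model, 0.3)
        perm = np.array([5, 3, 4, 0, 2, 1])
        Rp = R[np.ix_(perm, perm)]
        base = louvain_optimise(R, seed=2)
        moved = louvain_optimise(Rp, seed=2)
        relabelled = canonical_labels([base.labels[p] for p in perm])
        assert moved.labels == relabelled


class TestConsensus:
    def test_most_common_partition_wins(self):
        p1 = Partition(labels=(0, 0, 1), stability=0.5)
        p2 = Partition(labels=(0, 1, 1), stability=0.9)
        out = consensus_partition([p1, p1, p2])
        assert out.labels == (0, 0, 1) and out.multiplicity == 2

    def test_relabelled_duplicates_count_once(self):
        raw = canonical_labels([2, 2, 7])
        assert raw == (0, 0, 1)

    def test_tie_broken_by_higher_mean_stability(self):
        p1 = Partition(labels=(0, 0, 1), stability=0.2)
        p2 = Partition(labels=(0, 1, 1), stability=0.8)
        out = consensus_partition([p1, p2])
        assert out.labels == (0, 1, 1)

    def test_empty_runs_rejected(self):
        with pytest.raises(ValueError):
            consensus_partition([])


def test_louvain_matches_igraph_modularity_at_unit_linearised_time(rng):
    """Linearised stability at t=1 is Newman-Girvan modularity; an
    independent igraph Louvain should agree on quality for a two-block
    planted graph."""
    igraph = pytest.importorskip("igraph")
    n = 30
    blocks = np.repeat([0, 1], n // 2)
    P = np.where(blocks[:, None] == blocks[None, :], 0.6, 0.05)
    A = (rng.random((n, n)) < P).astype(float)
    A = np.triu(A, 1); A = A + A.T
    model = random_walk_operators(A)
    R = stability_matrix(model, 1.0, method="linearised")
    mine = max((louvain_optimise(R, seed=s) for s in range(10)),
               key=lambda p: p.stability)
    g = igraph.Graph.Adjacency((A > 0).tolist(), mode="undirected")
    theirs = g.community_multilevel()
    q_theirs = g.modularity(theirs.membership)
    q_mine_by_igraph = g.modularity(list(mine.labels))
    assert q_mine_by_igraph == pytest.approx(mine.stability, abs=1e-10)
    assert mine.stability >= q_theirs - 0.01
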