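"""Geographic validity filters and the (gamma, t) grid search."""

import numpy as np
import pytest

from pcndetect import (
    Partition,
    SpatialLayout,
    cosine_similarity_matrix,
    filter_communities,
    grid_search,
    hull_containment,
    score_partition,
    spatial_outliers,
)
from pcndetect.stability import canonical_labels


def _layout(points):
    return SpatialLayout(np.asarray(points, dtype=float))


class TestSpatialOutliers:
    def test_remote_practice_flagged(self, rng):
        """Nine practices in a unit cluster plus one ~140 away: only the
        remote one has median co-member distance > 4x the community median."""
        pts = np.vstack([rng.random((9, 2)), [[100.0, 100.0]]])
        layout = _layout(pts)
        assert spatial_outliers(range(10), layout) == [9]

    def test_regular_polygon_has_no_outliers(self):
        theta = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        layout = _layout(np.column_stack([np.cos(theta), np.sin(theta)]))
        assert spatial_outliers(range(8), layout) == []

    def test_small_community_routed_elsewhere(self):
        with pytest.raises(ValueError):
            spatial_outliers([0, 1], _layout([[0, 0], [1, 1], [2, 2]]))

    def test_single_pass_flags_both_remote_practices(self, rng):
        """Two remote practices are each judged against the one
        community-wide median computed over the original membership."""
        pts = np.vstack([rng.random((8, 2)), [[40.0, 40.0], [41.0, 41.0]]])
        layout = _layout(pts)
        flagged = spatial_outliers(range(10), layout)
        assert set(flagged) == {8, 9}


class TestHullContainment:
    SQUARE = [[0, 0], [0, 10], [10, 0], [10, 10]]

    def test_one_foreign_practice_inside(self):
        layout = _layout(self.SQUARE + [[5, 5]] + [[50, 50]])
        assert hull_containment([0, 1, 2, 3], layout) == pytest.approx(1 / 5)

    def test_two_foreign_practices_inside(self):
        layout = _layout(self.SQUARE + [[4, 4], [6, 6]] + [[50, 50]])
        assert hull_containment([0, 1, 2, 3], layout) == pytest.approx(2 / 6)

    def test_no_foreigners(self):
        layout = _layout(self.SQUARE + [[50, 50]])
        assert hull_containment([0, 1, 2, 3], layout) == 0.0

    def test_boundary_point_counts_as_inside(self):
        layout = _layout(self.SQUARE + [[5, 0]])
        assert hull_containment([0, 1, 2, 3], layout) == pytest.approx(1 / 5)

    def test_collinear_members_logged_not_fatal(self):
        layout = _layout([[0, 0], [1, 0], [2, 0], [1.5, 0], [9, 9]])
        assert hull_containment([0, 1, 2], layout) == pytest.approx(1 / 4)


class TestFilterPipeline:
    def _partition(self, labels):
        return Partition(labels=canonical_labels(labels), stability=0.0)

    def test_size_boundaries(self, rng):
        """Communities of 2 and 21 are excluded; 3 and 20 survive.

        The four communities are placed far apart so the containment
        filter stays quiet."""
        sizes = [2, 3, 20, 21]
        centres = np.array([[0, 0], [500, 0], [0, 500], [500, 500]])
        pts, labels = [], []
        for c, (size, centre) in enumerate(zip(sizes, centres)):
            pts.append(centre + rng.random((size, 2)))
            labels += [c] * size
        layout = _layout(np.vstack(pts))
        result = filter_communities(self._partition(labels), layout)
        assert sorted(len(c) for c in result.valid) == [3, 20]
        reasons = dict(result.exclusions)
        assert sum(1 for r in reasons.values() if r == "small_community") == 2
        assert sum(1 for r in reasons.values() if r == "large_community") == 21
        assert result.score + len(result.exclusions) == len(labels)

    def test_outlier_removal_precedes_size_check(self, rng):
        """A 21-member community with one remote member shrinks to 20 and
        becomes valid; the outlier is logged individually."""
        pts = np.vstack([rng.random((20, 2)), [[300.0, 300.0]]])
        layout = _layout(pts)
        result = filter_communities(self._partition([0] * 21), layout)
        assert [len(c) for c in result.valid] == [20]
        assert result.exclusions == [(20, "outlier")]

    def test_community_engulfing_another_fails_containment(self):
        """A ring community whose hull swallows a four-practice core is
        excluded (4 foreigners / 8 inside = 50% > 25%); the compact core
        community, containing no foreigners, survives."""
        ring = [[0, 0], [10, 0], [0, 10], [10, 10]]
        core = [[4, 4], [6, 4], [4, 6], [6, 6]]
        labels = [0] * 4 + [1] * 4
        result = filter_communities(self._partition(labels), _layout(ring + core))
        assert result.valid == [[4, 5, 6, 7]]
        assert result.exclusions == [(i, "containment") for i in range(4)]

    def test_score_is_sum_of_valid_sizes(self, rng):
        pts = np.vstack([rng.random((8, 2)), 500 + rng.random((5, 2))])
        labels = [0] * 8 + [1] * 5
        result = filter_communities(self._partition(labels), _layout(pts))
        assert score_partition(result) == 13


class TestGridSearch:
    def _setup(self, rng, n=18, k=3):
        """Three well-separated practice clusters with noisy LSOA profiles."""
        centres = np.array([[0, 0], [60, 0], [0, 60]])[:k]
        coords = np.vstack([c + rng.normal(0, 3, (n // k, 2)) for c in centres])
        profiles = np.zeros((k * 8, n))
        for j in range(n):
            block = j // (n // k)
            weights = rng.random(8) + 0.5
            profiles[block * 8:(block + 1) * 8, j] = weights
        S = cosine_similarity_matrix(profiles + 1e-3 * rng.random(profiles.shape))
        return S, SpatialLayout(coords)

    def test_recovers_planted_clusters_and_is_deterministic(self, rng):
        S, layout = self._setup(rng)
        kwargs = dict(
            gamma_grid=np.array([2.1, 4.0]),
            t_grid=np.array([0.05, 0.3, 1.0]),
            runs_per_model=8,
            master_seed=5,
        )
        res1 = grid_search(S, layout, **kwargs)
        assert res1.best.score == 18
        assert len(res1.best.filter_result.valid) == 3
        res2 = grid_search(S, layout, **kwargs)
        assert res1.best_index == res2.best_index
        for a, b in zip(res1.points, res2.points):
            assert a.summary() == b.summary()

    def test_conservation_at_every_grid_point(self, rng):
        S, layout = self._setup(rng)
        res = grid_search(S, layout, gamma_grid=np.array([2.1, 6.0]),
                          t_grid=np.array([0.01, 0.2, 1.0]),
                          runs_per_model=5, master_seed=9)
        for point in res.points:
            assert point.filter_result is not None
            assert point.score + len(point.filter_result.exclusions) == 18

    def test_tie_breaks_to_smallest_gamma_then_time(self, rng):
        """A two-community graph scored identically everywhere selects the
        first (smallest gamma, smallest t) grid point."""
        S, layout = self._setup(rng, n=12, k=2)
        res = grid_search(S, layout, gamma_grid=np.array([2.1, 3.0]),
                          t_grid=np.array([0.5, 1.0]),
                          runs_per_model=5, master_seed=2)
        top = [p for p in res.points if p.score == res.best.score]
        assert res.best.gamma == min(p.gamma for p in top)
        assert res.best.t == min(p.t for p in top if p.gamma == res.best.gamma)

    def test_empty_grid_rejected(self, rng):
        S, layout = self._setup(rng)
        with pytest.raises(ValueError):
            grid_search(S, layout, gamma_grid=np.array([]), t_grid=np.array([0.1]),
                        runs_per_model=1, master_seed=0)
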