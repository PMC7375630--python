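"""Geographic validity filtering and optimal-model selection.

Candidate partitions from the (gamma, t) grid are screened for geographic
plausibility community by community: (i) a member practice whose median
straight-line distance to its co-members exceeds ``outlier_factor`` times
the community-wide median pairwise distance is removed as a spatial
outlier; (ii) communities with fewer than ``min_size`` or more than
``max_size`` practices are excluded; (iii) a community is excluded when
the fraction of practices inside its convex hull that are not members
exceeds ``max_containment`` — heavily interpenetrating communities are not
credible service footprints. The score of a partition is the number of
practices in surviving communities, and the (gamma, t) model with the
highest score is selected; score ties go to smaller gamma, then smaller t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import MultiPoint, Point

from .rmst import (
    SparseGraph,
    maxlink_matrix,
    minimum_spanning_tree_edges,
    nearest_neighbour_distances,
    rmst_sparsify,
    to_distance,
)
from .stability import (
    Partition,
    consensus_partition,
    louvain_optimise,
    random_walk_operators,
    stability_matrix,
)

logger = logging.getLogger(__name__)

DEFAULT_OUTLIER_FACTOR = 4.0
DEFAULT_MIN_SIZE = 3
DEFAULT_MAX_SIZE = 20
DEFAULT_MAX_CONTAINMENT = 0.25


@dataclass
class SpatialLayout:
    """Projected planar practice coordinates and pairwise distances."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.distances = squareform(pdist(self.coords))

    @property
    def n(self) -> int:
        return len(self.coords)


def spatial_outliers(
    members: list[int] | np.ndarray,
    layout: SpatialLayout,
    factor: float = DEFAULT_OUTLIER_FACTOR,
) -> list[int]:
    """Members whose median co-member distance exceeds factor x community median.

    Single pass: the community-wide median pairwise distance is computed
    once over the original membership, then each member is compared
    against it; flagged members are not removed before others are tested.
    """
    members = list(members)
    if len(members) < 3:
        raise ValueError("spatial outlier screening needs a community of >= 3")
    sub = layout.distances[np.ix_(members, members)]
    community_median = float(np.median(sub[np.triu_indices(len(members), k=1)]))
    flagged = []
    for pos, m in enumerate(members):
        others = np.delete(sub[pos], pos)
        if float(np.median(others)) > factor * community_median:
            flagged.append(m)
    return flagged


def hull_containment(
    members: list[int] | np.ndarray,
    layout: SpatialLayout,
) -> float:
    """Fraction of practices inside the community hull that are foreign.

    The hull is the convex hull of member coordinates; points on the
    boundary count as inside. Denominator = all practices inside the hull
    (members plus foreigners), so the fraction reads as the degree of
    spatial mixing. A degenerate (collinear) hull is used as-is and logged.
    """
    members = list(members)
    if len(members) < 3:
        raise ValueError("containment check needs a community of >= 3")
    pts = layout.coords[members]
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if hull.geom_type != "Polygon":
        logger.warning("degenerate (collinear) community hull with %d members", len(members))
    member_set = set(members)
    foreign_inside = sum(
        1
        for j in range(layout.n)
        if j not in member_set and hull.covers(Point(*layout.coords[j]))
    )
    return foreign_inside / (len(members) + foreign_inside)


@dataclass
class FilterResult:
    """Valid communities (member index lists) plus a per-practice exclusion log."""

    valid: list[list[int]]
    exclusions: list[tuple[int, str]]   # (practice index, reason)

    @property
    def score(self) -> int:
        return sum(len(c) for c in self.valid)


def filter_communities(
    partition: Partition,
    layout: SpatialLayout,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
    max_containment: float = DEFAULT_MAX_CONTAINMENT,
    outlier_factor: float = DEFAULT_OUTLIER_FACTOR,
) -> FilterResult:
    """Outlier removal, then size bounds, then hull containment, per community."""
    valid: list[list[int]] = []
    exclusions: list[tuple[int, str]] = []
    for members in partition.members():
        if len(members) < min_size:
            exclusions.extend((m, "small_community") for m in members)
            continue
        # outlier screening is defined only for >= 3 members; smaller
        # communities (possible when min_size is lowered) skip straight
        # to the size check
        outliers = (
            spatial_outliers(members, layout, factor=outlier_factor)
            if len(members) >= 3 else []
        )
        exclusions.extend((m, "outlier") for m in outliers)
        kept = [m for m in members if m not in set(outliers)]
        if len(kept) < min_size:
            exclusions.extend((m, "small_community") for m in kept)
            continue
        if len(kept) > max_size:
            exclusions.extend((m, "large_community") for m in kept)
            continue
        if len(kept) >= 3 and hull_containment(kept, layout) > max_containment:
            exclusions.extend((m, "containment") for m in kept)
            continue
        valid.append(kept)
    return FilterResult(valid=valid, exclusions=exclusions)


def score_partition(result: FilterResult) -> int:
    """Number of practices in valid communities."""
    return result.score


def _model_seed(master_seed: int, gi: int, ti: int, run: int) -> np.random.SeedSequence:
    """Counter-based per-run seed: the grid is reproducible from one master seed."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(gi, ti, run))


@dataclass
class GridPoint:
    gamma: float
    t: float
    partition: Partition | None
    filter_result: FilterResult | None
    score: int
    n_edges: int = 0
    error: str | None = None

    def summary(self) -> dict:
        d = {
            "gamma": self.gamma,
            "t": self.t,
            "score": self.score,
            "n_edges": self.n_edges,
        }
        if self.partition is not None:
            d.update(
                n_communities=self.partition.n_communities,
                n_valid=len(self.filter_result.valid),
                stability=self.partition.stability,
                multiplicity=self.partition.multiplicity,
            )
        if self.error:
            d["error"] = self.error
        return d


@dataclass
class GridResult:
    """All (gamma, t) grid points and the selected optimum."""

    points: list[GridPoint]
    best_index: int

    @property
    def best(self) -> GridPoint:
        return self.points[self.best_index]

    def write_jsonl(self, path) -> None:
        import json

        with open(path, "w") as fh:
            for p in self.points:
                fh.write(json.dumps(p.summary(), sort_keys=True) + "\n")


def default_gamma_grid(low: float = 2.1, high: float = 6.0, num: int = 40) -> np.ndarray:
    """Evenly spaced pruning parameters (study default 40 in [2.1, 6.0])."""
    return np.linspace(low, high, num)


def default_t_grid(low: float = 0.01, high: float = 1.0, num: int = 400,
                   spacing: str = "log") -> np.ndarray:
    """Markov-time grid (study default 400 in [0.01, 1]); log-spaced since
    the scan covers two decades."""
    if spacing == "log":
        return np.geomspace(low, high, num)
    if spacing == "linear":
        return np.linspace(low, high, num)
    raise ValueError(f"unknown spacing {spacing!r}")


def grid_search(
    S: np.ndarray,
    layout: SpatialLayout,
    gamma_grid: np.ndarray,
    t_grid: np.ndarray,
    runs_per_model: int = 500,
    master_seed: int = 0,
    gp_ids: list[str] | None = None,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
    max_containment: float = DEFAULT_MAX_CONTAINMENT,
    outlier_factor: float = DEFAULT_OUTLIER_FACTOR,
    rmst_variant: str = "divisive",
    stability_method: str = "exponential",
) -> GridResult:
    """Scan the (gamma, t) grid and select the best-scoring model.

    For each gamma the similarity network is sparsened once; for each
    Markov time the stability matrix is built and ``runs_per_model``
    seeded Louvain runs are combined into a consensus partition, which is
    then geographically filtered and scored. A failing model is logged,
    scored 0, and the scan continues. The optimum maximises the score;
    exact ties resolve to the smaller gamma, then the smaller t.
    """
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if gamma_grid.size == 0 or t_grid.size == 0:
        raise ValueError("parameter grids must be non-empty")

    D = to_distance(S)
    tree_edges = minimum_spanning_tree_edges(D)
    mlink = maxlink_matrix(tree_edges, len(D))
    dnn = nearest_neighbour_distances(D)

    points: list[GridPoint] = []
    best_index = -1
    best_score = -1
    for gi, gamma in enumerate(gamma_grid):
        graph = rmst_sparsify(
            D, gamma, gp_ids=gp_ids, variant=rmst_variant,
            _precomputed=(tree_edges, mlink, dnn),
        )
        try:
            model = random_walk_operators(graph)
        except ValueError as exc:       # e.g. all-zero weights
            for ti, t in enumerate(t_grid):
                points.append(GridPoint(gamma, float(t), None, None, 0,
                                        n_edges=graph.n_edges, error=str(exc)))
            logger.warning("gamma=%.3f: %s", gamma, exc)
            continue
        for ti, t in enumerate(t_grid):
            try:
                R = stability_matrix(model, float(t), method=stability_method)
                runs = []
                for run in range(runs_per_model):
                    seed = _model_seed(master_seed, gi, ti, run)
                    rng_seed = int(seed.generate_state(1)[0] % (2**31))
                    runs.append(louvain_optimise(R, rng_seed, markov_time=float(t)))
                consensus = consensus_partition(runs)
                fr = filter_communities(
                    consensus, layout,
                    min_size=min_size, max_size=max_size,
                    max_containment=max_containment, outlier_factor=outlier_factor,
                )
                point = GridPoint(gamma, float(t), consensus, fr, fr.score,
                                  n_edges=graph.n_edges)
            except Exception as exc:    # noqa: BLE001 - a model failure must not kill the scan
                logger.warning("model gamma=%.3f t=%.4f failed: %s", gamma, t, exc)
                point = GridPoint(gamma, float(t), None, None, 0,
                                  n_edges=graph.n_edges, error=str(exc))
            points.append(point)
            if point.score > best_score:
                best_score = point.score
                best_index = len(points) - 1
    if best_index < 0:
        raise RuntimeError("every grid point failed")
    logger.info(
        "grid search: best score %d at gamma=%.3f t=%.4f (%d grid points)",
        best_score, points[best_index].gamma, points[best_index].t, len(points),
    )
    return GridResult(points=points, best_index=best_index)
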