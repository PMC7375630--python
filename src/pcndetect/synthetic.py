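"""Synthetic city generator: planted practice communities and registrations.

Emulates the post-extraction registration table of an urban primary-care
system: small census neighbourhoods (LSOAs) and general practices embedded
in the plane, grouped into ``k`` planted communities around spatial cluster
centres. Patients register with a practice with probability proportional to
``exp(-d / decay_length)``, attenuated by a leakage factor when the practice
lies in a different planted community. A configurable fraction of patients
carries extra conflicting records so the deduplication rule downstream is
exercised; conflicting records are constructed to be strictly dominated by
the true registration (fewer occurrences, or an earlier date on ties), so
the planted truth is always recoverable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from scipy.spatial.distance import cdist
from shapely.geometry import MultiPoint, Polygon, box, mapping

#: Registration window (inclusive): one financial year.
DATE_WINDOW = (np.datetime64("2017-04-01"), np.datetime64("2018-03-31"))

#: Spacing of planted cluster centres, in the arbitrary planar length unit.
#: Communities are meant to read as distinct neighbourhoods of a city, so
#: centres sit on a jittered grid several scatter lengths apart.
CENTRE_SPACING = 30.0
CENTRE_JITTER = 5.0
CLUSTER_SCATTER = 5.0


@dataclass(frozen=True)
class CityParams:
    n_lsoa: int
    n_gp: int
    k: int
    decay_length: float
    leakage: float
    seed: int


@dataclass
class SyntheticCity:
    """Planted-community city: LSOA centroids, practice sites, labels.

    ``lsoas`` columns: lsoa_id, x, y, population, planted.
    ``practices`` columns: gp_id, x, y, planted, ccg_id.
    Planted labels run 1..k; the CCG of a practice equals its planted
    community, which gives the downstream CCG-span statistics a known truth.
    """

    lsoas: pd.DataFrame
    practices: pd.DataFrame
    params: CityParams

    @property
    def lsoa_xy(self) -> np.ndarray:
        return self.lsoas[["x", "y"]].to_numpy(float)

    @property
    def gp_xy(self) -> np.ndarray:
        return self.practices[["x", "y"]].to_numpy(float)

    def write_csv(self, lsoa_path, gp_path) -> None:
        self.lsoas.to_csv(lsoa_path, index=False)
        self.practices.to_csv(gp_path, index=False)


@dataclass
class RegistrationTable:
    """Patient-level records (patient_id, lsoa_id, gp_id, record_date).

    One patient may appear in several records; ``truth`` holds the planted
    (lsoa, gp) pair per patient for validation and is never consumed by the
    analysis pipeline itself.
    """

    records: pd.DataFrame
    truth: pd.DataFrame

    def write_csv(self, path) -> None:
        out = self.records.copy()
        out["record_date"] = out["record_date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)


def _cluster_centres(k: int, rng: np.random.Generator) -> np.ndarray:
    """Centres on a jittered square grid, CENTRE_SPACING apart."""
    side = int(np.ceil(np.sqrt(k)))
    grid = np.array([(c * CENTRE_SPACING, r * CENTRE_SPACING)
                     for r in range(side) for c in range(side)], dtype=float)
    jitter = rng.uniform(-CENTRE_JITTER, CENTRE_JITTER, size=(k, 2))
    return grid[:k] + jitter


def _planted_labels(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """First k entities round-robin over 1..k, the rest uniform at random.

    Guarantees every planted community is non-empty regardless of n and k.
    """
    head = np.arange(1, k + 1)
    tail = rng.integers(1, k + 1, size=n - k)
    return np.concatenate([head, tail])


def generate_city(
    n_lsoa: int = 300,
    n_gp: int = 60,
    k: int = 6,
    decay_length: float = 20.0,
    leakage: float = 0.05,
    seed: int = 0,
) -> SyntheticCity:
    """Draw a planted-community city, fully reproducible from ``seed``.

    Parameters
    ----------
    n_lsoa, n_gp
        Numbers of residential neighbourhoods and practices.
    k
        Number of planted communities; must not exceed ``n_lsoa`` or ``n_gp``.
    decay_length
        Length scale of the exponential distance-decay registration kernel,
        in the same planar unit as the coordinates. The default (20, i.e.
        four times the within-community scatter) puts the city in the
        dense-urban regime where the catchments of practices in the same
        neighbourhood overlap heavily and patients routinely bypass their
        nearest practice — community identity, not micro-distance, drives
        registration choice.
    leakage
        Multiplier in [0, 1) applied to the registration weight of practices
        outside the patient's planted community; 0 forbids cross-community
        registration entirely.
    """
    if not (1 <= k <= min(n_lsoa, n_gp)):
        raise ValueError(f"need 1 <= k <= min(n_lsoa, n_gp); got k={k}")
    if decay_length <= 0:
        raise ValueError("decay_length must be positive")
    if not (0 <= leakage < 1):
        raise ValueError("leakage must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    centres = _cluster_centres(k, rng)

    lsoa_planted = _planted_labels(n_lsoa, k, rng)
    gp_planted = _planted_labels(n_gp, k, rng)

    lsoa_xy = centres[lsoa_planted - 1] + rng.normal(0.0, CLUSTER_SCATTER, (n_lsoa, 2))
    gp_xy = centres[gp_planted - 1] + rng.normal(0.0, CLUSTER_SCATTER, (n_gp, 2))

    # LSOAs hold ~1,800 residents each; the per-LSOA patient count sampled
    # later is a separate, much smaller cohort parameter.
    population = np.clip(np.round(rng.normal(1800.0, 300.0, n_lsoa)), 500, None).astype(int)

    lsoas = pd.DataFrame({
        "lsoa_id": [f"L{i:04d}" for i in range(n_lsoa)],
        "x": lsoa_xy[:, 0],
        "y": lsoa_xy[:, 1],
        "population": population,
        "planted": lsoa_planted,
    })
    practices = pd.DataFrame({
        "gp_id": [f"G{j:03d}" for j in range(n_gp)],
        "x": gp_xy[:, 0],
        "y": gp_xy[:, 1],
        "planted": gp_planted,
        "ccg_id": [f"C{c}" for c in gp_planted],
    })
    params = CityParams(n_lsoa, n_gp, k, decay_length, leakage, seed)
    return SyntheticCity(lsoas, practices, params)


def sample_registrations(
    city: SyntheticCity,
    patients_per_lsoa: int = 40,
    dup_rate: float = 0.1,
    seed: int = 0,
) -> RegistrationTable:
    """Sample the registration table from the gravity model.

    Every patient receives one true (lsoa, gp) registration. With
    probability ``dup_rate`` the patient additionally carries a conflicting
    record; half of those conflicts are outvoted (the true pair appears
    twice, the conflict once) and half tie on frequency but carry a strictly
    earlier date, so both arms of the deduplication rule are exercised and
    the true pair always wins.
    """
    if not (0 <= dup_rate < 1):
        raise ValueError("dup_rate must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    n_lsoa = len(city.lsoas)
    n_gp = len(city.practices)
    lam = city.params.decay_length
    eps = city.params.leakage

    dist = cdist(city.lsoa_xy, city.gp_xy)
    weights = np.exp(-dist / lam)
    same = city.lsoas["planted"].to_numpy()[:, None] == city.practices["planted"].to_numpy()[None, :]
    weights = np.where(same, weights, eps * weights)

    lsoa_ids = city.lsoas["lsoa_id"].to_numpy()
    gp_ids = city.practices["gp_id"].to_numpy()

    pat_lsoa_idx = np.repeat(np.arange(n_lsoa), patients_per_lsoa)
    n_pat = len(pat_lsoa_idx)
    pat_gp_idx = np.empty(n_pat, dtype=int)
    for i in range(n_lsoa):
        w = weights[i]
        total = w.sum()
        if total <= 0:
            raise ValueError(
                f"LSOA {lsoa_ids[i]} has no admissible practice "
                "(zero leakage and no same-community practice)"
            )
        sel = slice(i * patients_per_lsoa, (i + 1) * patients_per_lsoa)
        pat_gp_idx[sel] = rng.choice(n_gp, size=patients_per_lsoa, p=w / total)

    patient_ids = np.array([f"P{p:06d}" for p in range(n_pat)])
    start, end = DATE_WINDOW
    horizon = int((end - start) / np.timedelta64(1, "D"))
    # true dates leave >= 30 days of slack for strictly earlier conflicts
    true_offsets = rng.integers(30, horizon + 1, size=n_pat)

    rows = [pd.DataFrame({
        "patient_id": patient_ids,
        "lsoa_id": lsoa_ids[pat_lsoa_idx],
        "gp_id": gp_ids[pat_gp_idx],
        "record_date": start + true_offsets.astype("timedelta64[D]"),
    })]

    has_dup = rng.random(n_pat) < dup_rate
    dup_idx = np.flatnonzero(has_dup)
    if len(dup_idx):
        # conflicting pair differs in practice, and in LSOA half the time
        other_gp = (pat_gp_idx[dup_idx] + rng.integers(1, n_gp, size=len(dup_idx))) % n_gp
        move_lsoa = rng.random(len(dup_idx)) < 0.5
        other_lsoa = np.where(
            move_lsoa,
            (pat_lsoa_idx[dup_idx] + rng.integers(1, n_lsoa, size=len(dup_idx))) % n_lsoa,
            pat_lsoa_idx[dup_idx],
        )
        dup_offsets = true_offsets[dup_idx] - rng.integers(1, 30, size=len(dup_idx))
        rows.append(pd.DataFrame({
            "patient_id": patient_ids[dup_idx],
            "lsoa_id": lsoa_ids[other_lsoa],
            "gp_id": gp_ids[other_gp],
            "record_date": start + dup_offsets.astype("timedelta64[D]"),
        }))
        # frequency-dominant arm: the true pair gains a second record
        freq_arm = dup_idx[rng.random(len(dup_idx)) < 0.5]
        if len(freq_arm):
            extra_offsets = true_offsets[freq_arm] - rng.integers(0, 30, size=len(freq_arm))
            rows.append(pd.DataFrame({
                "patient_id": patient_ids[freq_arm],
                "lsoa_id": lsoa_ids[pat_lsoa_idx[freq_arm]],
                "gp_id": gp_ids[pat_gp_idx[freq_arm]],
                "record_date": start + extra_offsets.astype("timedelta64[D]"),
            }))

    records = pd.concat(rows, ignore_index=True)
    records["record_date"] = pd.to_datetime(records["record_date"])
    records = records.sort_values(
        ["patient_id", "record_date", "lsoa_id", "gp_id"], kind="mergesort"
    ).reset_index(drop=True)

    truth = pd.DataFrame({
        "patient_id": patient_ids,
        "lsoa_id": lsoa_ids[pat_lsoa_idx],
        "gp_id": gp_ids[pat_gp_idx],
    })
    return RegistrationTable(records=records, truth=truth)


def read_registration_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "lsoa_id": str, "gp_id": str})
    df["record_date"] = pd.to_datetime(df["record_date"])
    return df


def lsoa_voronoi_polygons(city: SyntheticCity, pad: float = 5.0) -> dict[str, Polygon]:
    """Voronoi tile per LSOA centroid, clipped to the padded bounding box.

    Stands in for real small-area boundary polygons; tiles partition the
    bounding box so per-PCN catchments can be dissolved from them.
    """
    pts = city.lsoa_xy
    if len(pts) < 4:
        # Voronoi needs >= 4 sites in 2D; fall back to equal box splits
        bbox = box(pts[:, 0].min() - pad, pts[:, 1].min() - pad,
                   pts[:, 0].max() + pad, pts[:, 1].max() + pad)
        return {lid: bbox for lid in city.lsoas["lsoa_id"]}
    clip = box(pts[:, 0].min() - pad, pts[:, 1].min() - pad,
               pts[:, 0].max() + pad, pts[:, 1].max() + pad)
    # mirror sites across the clip edges so every finite region is bounded
    minx, miny, maxx, maxy = clip.bounds
    mirrored = np.vstack([
        pts,
        np.column_stack([2 * minx - pts[:, 0], pts[:, 1]]),
        np.column_stack([2 * maxx - pts[:, 0], pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * miny - pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * maxy - pts[:, 1]]),
    ])
    vor = Voronoi(mirrored)
    tiles: dict[str, Polygon] = {}
    for i, lid in enumerate(city.lsoas["lsoa_id"]):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region]).buffer(0).intersection(clip)
        tiles[lid] = poly
    return tiles


def write_lsoa_geojson(city: SyntheticCity, path, extra: pd.DataFrame | None = None) -> None:
    """GeoJSON FeatureCollection of LSOA Voronoi tiles with metadata.

    ``extra`` (indexed by lsoa_id) attaches additional per-LSOA properties,
    e.g. assignments or market statistics.
    """
    tiles = lsoa_voronoi_polygons(city)
    features = []
    for _, row in city.lsoas.iterrows():
        props = {"lsoa_id": row["lsoa_id"], "population": int(row["population"]),
                 "planted": int(row["planted"])}
        if extra is not None and row["lsoa_id"] in extra.index:
            props.update({k: v for k, v in extra.loc[row["lsoa_id"]].items()})
        features.append({
            "type": "Feature",
            "geometry": mapping(tiles[row["lsoa_id"]]),
            "properties": props,
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def community_hull(points: np.ndarray) -> Polygon:
    """Convex hull of a point set as a shapely geometry (may be degenerate)."""
    return MultiPoint([tuple(p) for p in points]).convex_hull
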