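"""End-to-end pipeline: configuration, orchestration, artifact output.

``run_pipeline`` executes registration -> similarity -> grid search ->
assembly on either a simulated city or user-supplied CSV inputs, writing
every intermediate and final artifact into an output directory together
with a provenance manifest (config hash, seed, library versions) that
suffices to reproduce the run exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assembly import (
    UNASSIGNED,
    assign_lsoas,
    coverage_statistics,
    membership_from_communities,
    pcn_summaries,
)
from .registration import (
    DEFAULT_MIN_PATIENTS,
    build_registration_matrix,
    deduplicate_patients,
    lsoa_market_concentration,
)
from .selection import (
    DEFAULT_MAX_CONTAINMENT,
    DEFAULT_MAX_SIZE,
    DEFAULT_MIN_SIZE,
    DEFAULT_OUTLIER_FACTOR,
    SpatialLayout,
    grid_search,
)
from .similarity import cosine_similarity_matrix, gp_profiles, write_similarity_edges
from .synthetic import (
    SyntheticCity,
    generate_city,
    read_registration_csv,
    sample_registrations,
    write_lsoa_geojson,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; study-scale constants are the defaults.

    The full study grid (400 Markov times in [0.01, 1] x 40 pruning
    parameters in [2.1, 6.0], 500 Louvain runs per model) is expensive;
    desk-scale analyses shrink ``gamma_num``/``t_num``/``runs_per_model``.
    """

    # synthetic city (used by `simulate`; ignored when inputs are given)
    n_lsoa: int = 300
    n_gp: int = 60
    k_communities: int = 6
    decay_length: float = 20.0
    leakage: float = 0.05
    patients_per_lsoa: int = 100
    dup_rate: float = 0.1

    # registration
    min_patients: int = DEFAULT_MIN_PATIENTS

    # similarity / sparsification
    profile_mode: str = "practice"
    rmst_variant: str = "divisive"

    # grid
    gamma_min: float = 2.1
    gamma_max: float = 6.0
    gamma_num: int = 40
    t_min: float = 0.01
    t_max: float = 1.0
    t_num: int = 400
    t_spacing: str = "log"
    runs_per_model: int = 500
    stability_method: str = "exponential"

    # geographic filters
    outlier_factor: float = DEFAULT_OUTLIER_FACTOR
    min_size: int = DEFAULT_MIN_SIZE
    max_size: int = DEFAULT_MAX_SIZE
    max_containment: float = DEFAULT_MAX_CONTAINMENT

    master_seed: int = 0
    write_geojson: bool = False

    def validate(self) -> None:
        if self.gamma_num < 1 or self.t_num < 1:
            raise ValueError("parameter grids must be non-empty")
        if self.runs_per_model < 1:
            raise ValueError("runs_per_model must be positive")
        for name in ("outlier_factor", "max_containment", "decay_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_size > self.max_size:
            raise ValueError("min_size exceeds max_size")

    def gamma_grid(self) -> np.ndarray:
        return np.linspace(self.gamma_min, self.gamma_max, self.gamma_num)

    def t_grid(self) -> np.ndarray:
        if self.t_spacing == "log":
            return np.geomspace(self.t_min, self.t_max, self.t_num)
        return np.linspace(self.t_min, self.t_max, self.t_num)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def sha256(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _round_floats(obj, ndigits: int = 10):
    """Round floats recursively so metrics.json is byte-stable."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    registrations: pd.DataFrame | None = None,
    city: SyntheticCity | None = None,
    practice_meta: pd.DataFrame | None = None,
) -> dict:
    """Execute the full pipeline and write all artifacts under ``out_dir``.

    With no ``registrations`` a synthetic city is generated from the
    config and its planted labels are used to report recovery metrics.
    Returns the metrics dictionary (also written to metrics.json).
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- stage: inputs -------------------------------------------------
    if registrations is None:
        logger.info("stage simulate: generating synthetic city")
        city = generate_city(
            n_lsoa=config.n_lsoa, n_gp=config.n_gp, k=config.k_communities,
            decay_length=config.decay_length, leakage=config.leakage,
            seed=config.master_seed,
        )
        table = sample_registrations(
            city, patients_per_lsoa=config.patients_per_lsoa,
            dup_rate=config.dup_rate, seed=config.master_seed + 1,
        )
        registrations = table.records
        table.write_csv(out / "registrations.csv")
        city.write_csv(out / "city_lsoa.csv", out / "city_gp.csv")
    if city is None:
        raise ValueError("a city (practice/LSOA metadata) is required with explicit registrations")

    # ---- stage: registration ------------------------------------------
    logger.info("stage registration: %d records", len(registrations))
    dedup = deduplicate_patients(registrations)
    matrix = build_registration_matrix(dedup, min_patients=config.min_patients)
    matrix.write_triplets(out / "registration_matrix.csv")
    market = lsoa_market_concentration(matrix)
    market.to_csv(out / "lsoa_market.csv", index=False)
    logger.info(
        "stage registration: %d patients, %d practices retained (%d dropped), %d LSOAs",
        matrix.n_patients, len(matrix.gp_ids), len(matrix.dropped_practices),
        len(matrix.lsoa_ids),
    )

    # ---- stage: similarity --------------------------------------------
    profiles = gp_profiles(matrix, mode=config.profile_mode)
    S = cosine_similarity_matrix(profiles)
    write_similarity_edges(S, matrix.gp_ids, out / "similarity_edges.csv")

    # ---- stage: grid search -------------------------------------------
    gp_pos = city.practices.set_index("gp_id").loc[matrix.gp_ids, ["x", "y"]]
    layout = SpatialLayout(gp_pos.to_numpy(float))
    grid = grid_search(
        S, layout, config.gamma_grid(), config.t_grid(),
        runs_per_model=config.runs_per_model, master_seed=config.master_seed,
        gp_ids=matrix.gp_ids, min_size=config.min_size, max_size=config.max_size,
        max_containment=config.max_containment, outlier_factor=config.outlier_factor,
        rmst_variant=config.rmst_variant, stability_method=config.stability_method,
    )
    grid.write_jsonl(out / "grid_results.jsonl")
    best = grid.best

    exclusions = pd.DataFrame(
        [(matrix.gp_ids[i], reason) for i, reason in best.filter_result.exclusions],
        columns=["gp_id", "reason"],
    )
    exclusions.to_csv(out / "exclusions.csv", index=False)

    # ---- stage: assembly ----------------------------------------------
    membership = membership_from_communities(matrix.gp_ids, best.filter_result.valid)
    pd.DataFrame(
        sorted(membership.items()), columns=["gp_id", "pcn_id"]
    ).to_csv(out / "pcn_membership.csv", index=False)

    assignment = assign_lsoas(matrix, membership)
    assignment.to_csv(out / "lsoa_assignment.csv", index=False)
    stats = coverage_statistics(assignment, matrix, membership)

    if practice_meta is None:
        # synthetic metadata: registered patient count stands in for list size
        practice_meta = pd.DataFrame({
            "gp_id": matrix.gp_ids,
            "ccg_id": city.practices.set_index("gp_id").loc[matrix.gp_ids, "ccg_id"].to_numpy(),
            "list_size": matrix.col_totals,
        })
    summaries = pcn_summaries(membership, practice_meta)
    summaries = summaries.merge(
        stats["pcn_coverage"][["pcn_id", "coverage_pct"]], on="pcn_id", how="left"
    )
    summaries.to_csv(out / "pcn_summary.csv", index=False)

    # ---- metrics -------------------------------------------------------
    n_gp = len(matrix.gp_ids)
    n_assigned_gp = int(sum(len(c) for c in best.filter_result.valid))
    assigned_lsoas = assignment["pcn"] != UNASSIGNED
    metrics = {
        "n_patients": matrix.n_patients,
        "n_records": int(len(registrations)),
        "n_practices": n_gp,
        "n_practices_dropped_small": int(len(matrix.dropped_practices)),
        "n_lsoas": len(matrix.lsoa_ids),
        "optimal_gamma": best.gamma,
        "optimal_t": best.t,
        "optimal_score": best.score,
        "n_pcns": len(best.filter_result.valid),
        "n_practices_grouped": n_assigned_gp,
        "pct_practices_grouped": 100.0 * n_assigned_gp / n_gp,
        "n_lsoas_assigned": int(assigned_lsoas.sum()),
        "pct_lsoas_assigned": 100.0 * float(assigned_lsoas.mean()),
        "median_lsoa_ems": float(market["ems"].median()),
        "median_pcn_list_size": float(summaries["list_size"].median()) if len(summaries) else float("nan"),
        "pct_pcns_single_ccg": (
            100.0 * float((summaries["n_ccgs"] == 1).mean()) if len(summaries) else float("nan")
        ),
        **{f"lsoa_coverage_{k}": v for k, v in stats["summary"]["lsoa_coverage_pct"].items()},
        **{f"pcn_coverage_{k}": v for k, v in stats["summary"]["pcn_coverage_pct"].items()},
        "pcn_level_ems_median": stats["summary"]["pcn_level_ems_median"],
    }

    if "planted" in city.practices.columns:
        metrics.update(_recovery_metrics(city, matrix, membership, assignment))

    metrics = _round_floats(metrics)
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, sort_keys=True, indent=2)
        fh.write("\n")

    manifest = {
        "config": asdict(config),
        "config_sha256": config.sha256(),
        "master_seed": config.master_seed,
        "pcndetect_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
        fh.write("\n")

    if config.write_geojson:
        extra = assignment.set_index("lsoa_id")[["pcn", "coverage_pct"]]
        write_lsoa_geojson(city, out / "pcn_catchments.geojson", extra=extra)

    return metrics


def _recovery_metrics(city, matrix, membership, assignment) -> dict:
    """Planted-truth recovery: ARI over grouped practices and the share of
    LSOAs assigned to the PCN carrying their planted community."""
    from sklearn.metrics import adjusted_rand_score

    planted_gp = city.practices.set_index("gp_id").loc[matrix.gp_ids, "planted"]
    grouped = [g for g in matrix.gp_ids if membership[g] != UNASSIGNED]
    ari = float("nan")
    pct_correct = float("nan")
    if grouped:
        ari = float(adjusted_rand_score(
            planted_gp.loc[grouped].to_numpy(),
            [membership[g] for g in grouped],
        ))
        # planted community -> PCN holding most of its practices
        comm_to_pcn: dict[int, object] = {}
        df = pd.DataFrame({
            "planted": planted_gp.loc[grouped].to_numpy(),
            "pcn": [membership[g] for g in grouped],
        })
        for comm, sub in df.groupby("planted"):
            comm_to_pcn[comm] = sub["pcn"].mode().iloc[0]
        planted_lsoa = city.lsoas.set_index("lsoa_id").loc[matrix.lsoa_ids, "planted"]
        expected = planted_lsoa.map(comm_to_pcn)
        pct_correct = 100.0 * float(
            (assignment.set_index("lsoa_id")["pcn"].loc[matrix.lsoa_ids] == expected).mean()
        )
    return {"planted_ari": ari, "pct_lsoas_correct_pcn": pct_correct}
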