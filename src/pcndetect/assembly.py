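"""PCN assembly: catchment assignment, coverage and descriptive statistics.

The valid communities of the optimal partition become numbered PCNs;
practices excluded by the geographic filters form an explicit "unassigned"
pool. Each LSOA is assigned to the PCN holding the largest number of its
patients (ties to the smallest PCN id, with the unassigned pool losing
all ties); an LSOA whose modal provider group is the unassigned pool is
reported separately rather than forced into a PCN. Coverage of an LSOA is
the percentage of its patients registered inside its assigned PCN;
coverage of a PCN aggregates the same quantity over its catchment LSOAs
with patient weights. LSOA-level concentration across PCNs reuses the
HHI / equivalent-market-size statistics with PCNs (plus the unassigned
pool) as the provider units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registration import RegistrationMatrix, market_concentration

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


def membership_from_communities(
    gp_ids: list[str], valid_communities: list[list[int]]
) -> dict[str, object]:
    """Map gp_id -> PCN id (1-based int) or the unassigned sentinel."""
    membership: dict[str, object] = {g: UNASSIGNED for g in gp_ids}
    for pcn, members in enumerate(valid_communities, start=1):
        for m in members:
            membership[gp_ids[m]] = pcn
    return membership


def _pcn_count_matrix(
    matrix: RegistrationMatrix, membership: dict[str, object]
) -> tuple[np.ndarray, list[object]]:
    """Collapse practice columns to PCN-group columns (unassigned pool last)."""
    pcn_ids = sorted({p for p in membership.values() if p != UNASSIGNED})
    groups = pcn_ids + [UNASSIGNED]
    col_group = np.array([groups.index(membership[g]) for g in matrix.gp_ids])
    agg = np.zeros((len(matrix.lsoa_ids), len(groups)), dtype=np.int64)
    np.add.at(agg.T, col_group, matrix.counts.T)
    return agg, groups


def assign_lsoas(
    matrix: RegistrationMatrix, membership: dict[str, object]
) -> pd.DataFrame:
    """Modal PCN assignment per LSOA.

    Returns columns lsoa_id, pcn (int or "unassigned"), assigned_patients,
    total_patients, coverage_pct. Columns are ordered with the unassigned
    pool last, so np.argmax's first-max rule implements both tie-breaks
    (smallest PCN id; a PCN beats the pool on ties).
    """
    missing = [g for g in matrix.gp_ids if g not in membership]
    if missing:
        raise ValueError(f"practices without a membership entry: {missing[:5]}")
    agg, groups = _pcn_count_matrix(matrix, membership)
    modal = np.argmax(agg, axis=1)
    assigned = agg[np.arange(len(agg)), modal]
    totals = agg.sum(axis=1)
    out = pd.DataFrame({
        "lsoa_id": matrix.lsoa_ids,
        "pcn": [groups[m] for m in modal],
        "assigned_patients": assigned,
        "total_patients": totals,
        "coverage_pct": 100.0 * assigned / np.where(totals > 0, totals, 1),
    })
    n_un = int((out["pcn"] == UNASSIGNED).sum())
    if n_un:
        logger.info("%d LSOAs have the unassigned pool as modal provider", n_un)
    return out


def _quantiles(values: np.ndarray) -> dict[str, float]:
    if len(values) == 0:
        return {k: float("nan") for k in ("min", "q1", "median", "q3", "max")}
    return {
        "min": float(np.min(values)),
        "q1": float(np.percentile(values, 25)),
        "median": float(np.median(values)),
        "q3": float(np.percentile(values, 75)),
        "max": float(np.max(values)),
    }


def coverage_statistics(
    assignment: pd.DataFrame,
    matrix: RegistrationMatrix,
    membership: dict[str, object],
) -> dict:
    """Per-LSOA and per-PCN coverage plus PCN-level market concentration.

    Per-PCN coverage = (patients in the PCN's catchment LSOAs registered
    to its member practices) / (all patients resident in the catchment),
    i.e. the patient-weighted aggregate of LSOA coverage. Unassigned LSOAs
    contribute to no PCN catchment and are summarised separately.
    """
    agg, groups = _pcn_count_matrix(matrix, membership)
    pcn_ids = [g for g in groups if g != UNASSIGNED]

    lsoa_cov = assignment.loc[assignment["pcn"] != UNASSIGNED, "coverage_pct"].to_numpy()

    pcn_rows = []
    for pcn in pcn_ids:
        col = groups.index(pcn)
        in_catchment = (assignment["pcn"] == pcn).to_numpy()
        total = int(agg[in_catchment].sum())
        within = int(agg[in_catchment, col].sum())
        pcn_rows.append({
            "pcn_id": pcn,
            "n_lsoas": int(in_catchment.sum()),
            "patients_within": within,
            "patients_total": total,
            "coverage_pct": 100.0 * within / total if total else float("nan"),
        })
    pcn_coverage = pd.DataFrame(pcn_rows)

    pcn_market = market_concentration(agg, matrix.lsoa_ids).rename(
        columns={"unit_id": "lsoa_id"}
    )
    return {
        "lsoa_coverage": assignment,
        "pcn_coverage": pcn_coverage,
        "pcn_level_market": pcn_market,
        "summary": {
            "lsoa_coverage_pct": _quantiles(lsoa_cov),
            "pcn_coverage_pct": _quantiles(
                pcn_coverage["coverage_pct"].dropna().to_numpy()
            ),
            "pcn_level_hhi_median": float(pcn_market["hhi"].median()),
            "pcn_level_ems_median": float(pcn_market["ems"].median()),
            "n_unassigned_lsoas": int((assignment["pcn"] == UNASSIGNED).sum()),
        },
    }


def pcn_summaries(
    membership: dict[str, object],
    practice_meta: pd.DataFrame,
) -> pd.DataFrame:
    """Per-PCN member count, summed list size and CCG span.

    ``practice_meta`` needs columns gp_id, ccg_id and list_size; a missing
    list size contributes 0 and is logged. Returns one row per PCN with
    columns pcn_id, n_practices, list_size, n_ccgs.
    """
    meta = practice_meta.set_index("gp_id")
    rows = []
    pcn_ids = sorted({p for p in membership.values() if p != UNASSIGNED})
    for pcn in pcn_ids:
        members = [g for g, p in membership.items() if p == pcn]
        sizes = []
        ccgs = set()
        for g in members:
            if g not in meta.index:
                logger.warning("practice %s has no metadata; list size counted as 0", g)
                continue
            row = meta.loc[g]
            ccgs.add(row["ccg_id"])
            ls = row.get("list_size", np.nan)
            if pd.isna(ls):
                logger.warning("practice %s has no list size; counted as 0", g)
            else:
                sizes.append(int(ls))
        rows.append({
            "pcn_id": pcn,
            "n_practices": len(members),
            "list_size": int(sum(sizes)),
            "n_ccgs": len(ccgs),
        })
    return pd.DataFrame(rows)
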