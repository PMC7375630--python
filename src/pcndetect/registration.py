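"""Registration table processing: deduplication, counts matrix, market stats.

A patient observed under more than one (LSOA, practice) combination within
the study window keeps the combination with the highest record frequency;
frequency ties are broken by the most recent record date, and the rare
double tie by the lexicographically smallest (gp_id, lsoa_id). Practices
contributing fewer than ``min_patients`` unique patients are excluded along
with their patients. Market concentration per LSOA is the Herfindahl-
Hirschman index HHI_i = sum_j s_ij^2 over practice shares s_ij, and the
equivalent market size EMS_i = 1 / HHI_i — the number of practices that
would serve the LSOA if each held an equal share.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MIN_PATIENTS = 100


@dataclass
class RegistrationMatrix:
    """LSOA x practice matrix of unique-patient counts with marginals."""

    counts: np.ndarray          # int, shape (n_lsoa, n_gp)
    lsoa_ids: list[str]
    gp_ids: list[str]
    dropped_practices: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gp_id", "n_patients"])
    )

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n_patients(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.lsoa_ids, columns=self.gp_ids)

    def write_triplets(self, path) -> None:
        """Sparse triplet CSV: lsoa_id, gp_id, count (non-zero cells only)."""
        ii, jj = np.nonzero(self.counts)
        pd.DataFrame({
            "lsoa_id": np.asarray(self.lsoa_ids)[ii],
            "gp_id": np.asarray(self.gp_ids)[jj],
            "count": self.counts[ii, jj],
        }).to_csv(path, index=False)


def deduplicate_patients(records: pd.DataFrame) -> pd.DataFrame:
    """Resolve each patient to a single (lsoa_id, gp_id) pair.

    Selection: highest frequency of the combination, then latest record
    date of that combination, then smallest (gp_id, lsoa_id). Returns a
    DataFrame with one row per patient (patient_id, lsoa_id, gp_id).
    """
    if records.empty:
        raise ValueError("registration table is empty")

    grouped = (
        records.groupby(["patient_id", "lsoa_id", "gp_id"], sort=False)
        .agg(freq=("record_date", "size"), last_date=("record_date", "max"))
        .reset_index()
    )
    ranked = grouped.sort_values(
        ["patient_id", "freq", "last_date", "gp_id", "lsoa_id"],
        ascending=[True, False, False, True, True],
        kind="mergesort",
    )
    best = ranked.drop_duplicates("patient_id", keep="first")

    # count double ties (frequency AND date) for the log
    top = ranked.groupby("patient_id", sort=False).head(2)
    dup_top = top[top.duplicated(["patient_id", "freq", "last_date"], keep=False)]
    n_double_ties = dup_top["patient_id"].nunique()
    n_conflicted = int((grouped.groupby("patient_id").size() > 1).sum())
    logger.info(
        "deduplication: %d patients, %d with conflicting combinations, "
        "%d double ties broken lexicographically",
        best.shape[0], n_conflicted, n_double_ties,
    )
    return best[["patient_id", "lsoa_id", "gp_id"]].reset_index(drop=True)


def build_registration_matrix(
    dedup: pd.DataFrame, min_patients: int = DEFAULT_MIN_PATIENTS
) -> RegistrationMatrix:
    """Tabulate unique patients by (LSOA, practice) and apply the size filter.

    Practices with fewer than ``min_patients`` unique patients are dropped,
    and their patients with them; LSOA rows left empty by the drop are also
    removed. Label order is sorted for determinism.
    """
    table = pd.crosstab(dedup["lsoa_id"], dedup["gp_id"]).sort_index(axis=0).sort_index(axis=1)
    col_tot = table.sum(axis=0)
    small = col_tot[col_tot < min_patients]
    dropped = pd.DataFrame({"gp_id": small.index, "n_patients": small.to_numpy()})
    if len(small):
        logger.info(
            "excluded %d practices with < %d patients (%d patients removed)",
            len(small), min_patients, int(small.sum()),
        )
    table = table.drop(columns=small.index)
    table = table.loc[table.sum(axis=1) > 0]
    if table.empty:
        raise ValueError("no practices retained after the minimum-patient filter")
    return RegistrationMatrix(
        counts=table.to_numpy(dtype=np.int64),
        lsoa_ids=list(table.index),
        gp_ids=list(table.columns),
        dropped_practices=dropped.reset_index(drop=True),
    )


def market_concentration(counts: np.ndarray, unit_ids: list[str]) -> pd.DataFrame:
    """HHI and EMS per row of a unit x provider count matrix.

    Rows with zero patients are excluded from the summary (logged). The
    returned frame has columns unit_id, hhi, ems with ems * hhi == 1.
    """
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1)
    keep = totals > 0
    if not keep.all():
        logger.info("market concentration: %d zero-patient rows excluded", int((~keep).sum()))
    shares = counts[keep] / totals[keep, None]
    hhi = (shares ** 2).sum(axis=1)
    return pd.DataFrame({
        "unit_id": np.asarray(unit_ids)[keep],
        "hhi": hhi,
        "ems": 1.0 / hhi,
    })


def lsoa_market_concentration(matrix: RegistrationMatrix) -> pd.DataFrame:
    """Per-LSOA practice-level HHI/EMS (columns lsoa_id, hhi, ems)."""
    out = market_concentration(matrix.counts, matrix.lsoa_ids)
    return out.rename(columns={"unit_id": "lsoa_id"})
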