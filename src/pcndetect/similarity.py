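"""Practice-practice cosine similarity from LSOA registration profiles.

Each practice is described by the distribution of its patients over LSOAs
of residence (its column of the registration matrix, normalised to sum to
one); the similarity of two practices is the cosine of the angle between
their profiles. Cosine similarity is invariant to the per-practice
normalisation, so raw count columns give the same matrix; the
normalisation is kept because the profiles are meaningful objects in their
own right. An alternative ``mode="lsoa"`` normalises the matrix by LSOA row
(per-LSOA registration probabilities) before comparing practice columns,
for sensitivity analysis.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics.pairwise import cosine_similarity

from .registration import RegistrationMatrix


def gp_profiles(matrix: RegistrationMatrix, mode: str = "practice") -> np.ndarray:
    """Profile matrix, shape (n_lsoa, n_gp).

    ``mode="practice"``: column j is practice j's distribution over LSOAs
    (columns sum to 1). ``mode="lsoa"``: entries are per-LSOA registration
    probabilities (rows sum to 1); columns are then compared as-is.
    """
    counts = matrix.counts.astype(float)
    if mode == "practice":
        col_tot = counts.sum(axis=0)
        if np.any(col_tot <= 0):
            raise ValueError("practice with zero patients violates the upstream contract")
        return counts / col_tot[None, :]
    if mode == "lsoa":
        row_tot = counts.sum(axis=1)
        if np.any(row_tot <= 0):
            raise ValueError("LSOA row with zero patients violates the upstream contract")
        return counts / row_tot[:, None]
    raise ValueError(f"unknown profile mode {mode!r}")


def cosine_similarity_matrix(profiles: np.ndarray) -> np.ndarray:
    """Symmetric cosine similarity between profile columns, diagonal 1.

    Entries are clipped to [0, 1] (profiles are non-negative, so values
    outside that range can only arise from rounding) and symmetry is
    enforced exactly.
    """
    norms = np.linalg.norm(profiles, axis=0)
    if np.any(norms == 0):
        raise ValueError("zero profile vector")
    S = cosine_similarity(profiles.T)
    if not np.all(np.isfinite(S)):
        raise FloatingPointError("non-finite cosine similarity")
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def write_similarity_edges(S: np.ndarray, gp_ids: list[str], path) -> None:
    """Weighted upper-triangle edge list CSV: gp_a, gp_b, similarity."""
    import pandas as pd

    iu, ju = np.triu_indices(len(S), k=1)
    pd.DataFrame({
        "gp_a": np.asarray(gp_ids)[iu],
        "gp_b": np.asarray(gp_ids)[ju],
        "similarity": S[iu, ju],
    }).to_csv(path, index=False)
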