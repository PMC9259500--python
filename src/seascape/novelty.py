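"""Novelty of GCFs and GCCs against reference BGC databases.

Each representative BGC is scored by its minimum cosine distance to a
reference feature table (computationally predicted references like
BiG-FAM/RefSeq, or experimentally validated ones like MIBiG).  Minima are
averaged per family; a GCF is called novel when its mean distance exceeds
0.2 (the family-defining threshold, i.e. on average complete separation
from the reference) and a GCC is only remotely related when its mean
exceeds 0.4, twice the GCF threshold.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "min_distance_to_reference",
    "min_distances",
    "family_novelty",
    "family_novelty_table",
    "novelty_summary",
    "round_half_up_percent",
]

GCF_NOVELTY_THRESHOLD = 0.2
GCC_NOVELTY_THRESHOLD = 0.4
_LEVEL_THRESHOLDS = {"GCF": GCF_NOVELTY_THRESHOLD, "GCC": GCC_NOVELTY_THRESHOLD}


def _align_columns(query: pd.DataFrame, reference: pd.DataFrame):
    """Union-of-vocabularies alignment; absent domains weigh zero.

    Cosine over the union equals cosine ignoring shared-zero columns, so
    this is exact, not an approximation.
    """
    vocab = query.columns.union(reference.columns)
    q = query.reindex(columns=vocab, fill_value=0.0).to_numpy(dtype=float)
    r = reference.reindex(columns=vocab, fill_value=0.0).to_numpy(dtype=float)
    return q, r


def min_distances(query: pd.DataFrame, reference: pd.DataFrame) -> pd.Series:
    """Minimum cosine distance of every query BGC to the reference rows."""
    if reference.shape[0] == 0:
        raise ValueError("reference database is empty")
    q, r = _align_columns(query, reference)
    qn = np.linalg.norm(q, axis=1)
    rn = np.linalg.norm(r, axis=1)
    if np.any(qn == 0) or np.any(rn == 0):
        raise ValueError("all-zero feature vector: cosine distance undefined")
    sims = (q @ r.T) / np.outer(qn, rn)
    d = np.clip(1.0 - sims.max(axis=1), 0.0, 1.0)
    return pd.Series(d, index=query.index, name="d_min")


def min_distance_to_reference(bgc_vector, reference: pd.DataFrame) -> float:
    """Minimum cosine distance of a single BGC vector to the reference."""
    query = pd.DataFrame([np.asarray(bgc_vector, dtype=float)], columns=reference.columns)
    return float(min_distances(query, reference).iloc[0])


def family_novelty(member_d_min, level: str = "GCF"):
    """Mean of member minimum distances and the novelty flag for the level.

    Strictly greater than the threshold counts as novel ("above 0.2"): a
    family sitting exactly at the threshold is not flagged.
    """
    values = np.asarray(list(member_d_min), dtype=float)
    if values.size == 0:
        raise ValueError("family has no members")
    if np.any((values < 0) | (values > 1)):
        raise ValueError("distances must lie in [0, 1]")
    level = level.upper()
    if level not in _LEVEL_THRESHOLDS:
        raise ValueError("level must be 'GCF' or 'GCC'")
    mean = float(values.mean())
    return mean, mean > _LEVEL_THRESHOLDS[level]


def family_novelty_table(
    d_min: pd.Series, assignments: pd.DataFrame, representative_bgcs=None
) -> pd.DataFrame:
    """Per-family mean distance and flags, computed on representatives.

    ``d_min`` is indexed by bgc_id; ``assignments`` carries bgc_id/gcf/gcc.
    Restricting to dereplicated representatives prevents large families
    dominated by one well-sampled species from biasing the mean.
    """
    table = assignments.copy()
    table["d_min"] = table["bgc_id"].map(d_min)
    if representative_bgcs is not None:
        table = table[table["bgc_id"].isin(set(representative_bgcs))]
    if table["d_min"].isna().any():
        missing = table.loc[table["d_min"].isna(), "bgc_id"].tolist()
        raise ValueError(f"no distance for BGCs: {missing}")
    out = []
    for level, col in (("GCF", "gcf"), ("GCC", "gcc")):
        grouped = table.groupby(col)["d_min"].mean()
        for family, mean in grouped.items():
            out.append(
                {
                    "family": family,
                    "level": level,
                    "mean_d_min": float(mean),
                    "flagged": bool(mean > _LEVEL_THRESHOLDS[level]),
                }
            )
    return pd.DataFrame(out)


def round_half_up_percent(ratio: float) -> int:
    """Round a fraction to integer percent, halves away from zero."""
    return int(Decimal(str(ratio * 100)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def novelty_summary(count: int, denominator: int) -> dict:
    """Count, raw ratio and display percent for one novelty statement."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if count < 0:
        raise ValueError("count must be nonnegative")
    ratio = count / denominator
    # exact rational arithmetic so display rounding never trips on binary floats
    percent = int(
        (Decimal(count) * 100 / Decimal(denominator)).quantize(
            Decimal("1"), rounding=ROUND_HALF_UP
        )
    )
    return {
        "count": int(count),
        "denominator": int(denominator),
        "ratio": ratio,
        "percent": percent,
    }
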