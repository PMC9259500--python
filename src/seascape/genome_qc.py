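"""Genome quality aggregation, species clustering and representative selection.

Draft genomes recovered from metagenomes (MAGs), single cells (SAGs) and
isolates (REFs) come with two independent quality estimates (CheckM-style
completeness/contamination and Anvi'o-style completion/redundancy).  This
module aggregates the two into mean completeness (mcpl) and mean
contamination (mctn), applies the community-standard retention and quality
class rules, scores genomes with Q = mcpl - 5*mctn and its N50/strain
heterogeneity refinement Q', clusters genomes into species at 95% average
nucleotide identity (ANI), and picks one representative genome per species
by maximum Q'.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "QualitySummary",
    "aggregate_quality",
    "classify_quality",
    "quality_scores",
    "cluster_species",
    "select_representative",
    "corrected_genome_size",
    "mapping_rate",
    "summarize_genomes",
]

#: ANI species boundary (percent).
SPECIES_ANI_THRESHOLD = 95.0


@dataclass(frozen=True)
class QualitySummary:
    """Aggregated quality of one genome."""

    genome_id: str
    mcpl: float
    mctn: float
    quality_class: str
    retained: bool
    q_score: float
    q_prime: float


def _pair(completeness, contamination):
    """Return (completeness, contamination) if both present, else None."""
    if completeness is None or contamination is None:
        return None
    if isinstance(completeness, float) and math.isnan(completeness):
        return None
    if isinstance(contamination, float) and math.isnan(contamination):
        return None
    return float(completeness), float(contamination)


def aggregate_quality(record) -> QualitySummary:
    """Aggregate dual estimator output for one genome record.

    ``record`` is any mapping (e.g. a pandas row) exposing
    ``checkm_completeness``, ``checkm_contamination``, ``anvio_completion``,
    ``anvio_redundancy``, ``strain_heterogeneity``, ``n50`` and
    ``genome_id``.  A genome is retained when *either* estimator reports
    completeness >= 50% and contamination <= 10%; mcpl/mctn are the
    arithmetic means of the available estimates (a single estimate stands
    alone when the other estimator is missing).
    """
    checkm = _pair(record.get("checkm_completeness"), record.get("checkm_contamination"))
    anvio = _pair(record.get("anvio_completion"), record.get("anvio_redundancy"))
    if checkm is None and anvio is None:
        raise ValueError(
            f"genome {record.get('genome_id')!r}: both quality estimators missing"
        )
    pairs = [p for p in (checkm, anvio) if p is not None]
    for cpl, ctn in pairs:
        if not (0 <= cpl <= 100 and 0 <= ctn <= 100):
            raise ValueError("completeness/contamination out of [0, 100]")
    mcpl = float(np.mean([p[0] for p in pairs]))
    mctn = float(np.mean([p[1] for p in pairs]))
    retained = any(cpl >= 50 and ctn <= 10 for cpl, ctn in pairs)
    strain_het = float(record.get("strain_heterogeneity") or 0.0)
    n50 = int(record.get("n50") or 1)
    q, q_prime = quality_scores(mcpl, mctn, strain_het, n50)
    return QualitySummary(
        genome_id=str(record.get("genome_id")),
        mcpl=mcpl,
        mctn=mctn,
        quality_class=classify_quality(mcpl, mctn),
        retained=retained,
        q_score=q,
        q_prime=q_prime,
    )


def classify_quality(mcpl: float, mctn: float) -> str:
    """Quality class from mean completeness / mean contamination.

    high: mcpl >= 90 and mctn <= 5; good: mcpl >= 70 and mctn <= 10;
    medium: mcpl >= 50 and mctn <= 10; otherwise fair.
    """
    if not (0 <= mcpl <= 100 and 0 <= mctn <= 100):
        raise ValueError("mcpl/mctn must be percentages in [0, 100]")
    if mcpl >= 90 and mctn <= 5:
        return "high"
    if mcpl >= 70 and mctn <= 10:
        return "good"
    if mcpl >= 50 and mctn <= 10:
        return "medium"
    return "fair"


def quality_scores(mcpl: float, mctn: float, strain_het: float, n50: int):
    """Return (Q, Q').

    Q = mcpl - 5*mctn.  Q' adds a strain-heterogeneity credit (contamination
    that is merely intra-species variation is penalized less) and an
    assembly-contiguity bonus: Q' = Q + mctn*(strain_het/100) + 0.5*log10(N50).
    """
    if n50 < 1:
        raise ValueError("n50 must be >= 1")
    q = mcpl - 5.0 * mctn
    q_prime = q + mctn * (strain_het / 100.0) + 0.5 * math.log10(n50)
    return q, q_prime


def summarize_genomes(genomes: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`aggregate_quality` over a genome table."""
    rows = [aggregate_quality(rec) for rec in genomes.to_dict("records")]
    out = pd.DataFrame([r.__dict__ for r in rows])
    out["n50"] = genomes["n50"].to_numpy()
    return out


def cluster_species(ani: pd.DataFrame, threshold: float = SPECIES_ANI_THRESHOLD) -> pd.DataFrame:
    """Cluster genomes into species from a symmetric ANI matrix.

    Average-linkage hierarchical clustering on distance (100 - ANI)/100,
    cut at (100 - threshold)/100 (0.05 for the 95% species boundary).
    Returns a DataFrame with columns genome_id, species_id,
    representative-ready ordering; species labels are ``sp_0001`` etc.,
    numbered by the lexicographically smallest member genome id.
    """
    if ani.shape[0] != ani.shape[1]:
        raise ValueError("ANI matrix must be square")
    values = ani.to_numpy(dtype=float)
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError("ANI matrix must be symmetric")
    if not np.allclose(np.diag(values), 100.0):
        raise ValueError("ANI matrix diagonal must be 100")
    ids = [str(i) for i in ani.index]
    if len(ids) == 1:
        return pd.DataFrame({"genome_id": ids, "species_id": ["sp_0001"]})
    dist = (100.0 - values) / 100.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    cut = (100.0 - threshold) / 100.0
    raw = fcluster(z, t=cut, criterion="distance")
    return pd.DataFrame(
        {"genome_id": ids, "species_id": _canonical_labels(ids, raw, "sp")}
    )


def _canonical_labels(ids, raw_labels, prefix: str):
    """Rename arbitrary cluster integers to deterministic labels.

    Clusters are ordered by their lexicographically smallest member id so the
    labelling is invariant to input row order.
    """
    smallest = {}
    for i, lab in zip(ids, raw_labels):
        if lab not in smallest or i < smallest[lab]:
            smallest[lab] = i
    order = {lab: k for k, lab in enumerate(sorted(smallest, key=smallest.get), start=1)}
    width = max(4, len(str(len(order))))
    return [f"{prefix}_{order[lab]:0{width}d}" for lab in raw_labels]


def select_representative(member_ids, summaries: pd.DataFrame) -> str:
    """Pick the species representative: max Q', then larger N50, then id.

    ``summaries`` must carry genome_id, q_prime and n50 columns for every
    member.
    """
    members = list(member_ids)
    if not members:
        raise ValueError("empty species cluster")
    table = summaries.set_index("genome_id")
    missing = [m for m in members if m not in table.index]
    if missing:
        raise ValueError(f"members without quality summary: {missing}")
    best = sorted(
        members,
        key=lambda g: (-float(table.at[g, "q_prime"]), -int(table.at[g, "n50"]), g),
    )
    return best[0]


def corrected_genome_size(length_bp: float, completeness_pct: float) -> float:
    """Completeness-corrected genome size: length / (completeness/100).

    A 75%-complete 3 Mb assembly corresponds to a ~4 Mb genome.
    """
    if not 0 < completeness_pct <= 100:
        raise ValueError("completeness must be in (0, 100]")
    return float(length_bp) / (completeness_pct / 100.0)


def mapping_rate(n_filtered_reads: int, n_total_reads: int) -> float:
    """Percent of quality-controlled reads surviving alignment filtering."""
    if n_total_reads <= 0:
        raise ValueError("total read count must be positive")
    if not 0 <= n_filtered_reads <= n_total_reads:
        raise ValueError("filtered read count out of range")
    return 100.0 * n_filtered_reads / n_total_reads
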