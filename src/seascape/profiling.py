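"""Metagenomic and metatranscriptomic abundance profiling.

Takes per-sample alignment summaries (one row per alignment; ambiguous
inserts appear once per candidate target gene) and turns them into
length-normalized gene abundances via a single fractional-assignment pass:
unique inserts count 1 towards their target and each ambiguous insert is
split across its targets in proportion to the targets' unique counts
(uniformly when none of them has unique support).  Gene abundances roll up
to BGC abundances (median of biosynthetic genes), to family abundances
(sum over dereplicated representative BGCs), are cell-normalized by the
per-sample marker-gene (mOTU) abundance — a cell-count proxy that also
absorbs sequencing effort — and summarized as prevalence.  The same
machinery supports per-cell transcript activity (log2 ratio to the marker
median) and abundance-weighted average genome size.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "filter_alignments",
    "assign_inserts",
    "length_normalize",
    "bgc_abundance",
    "family_abundance",
    "cell_normalize",
    "prevalence",
    "average_genome_size",
    "transcript_activity",
    "FILTER_PRESETS",
]

logger = logging.getLogger(__name__)

#: (min aligned bases, min percent identity, min fraction of the read covered)
FILTER_PRESETS = {
    "genome": (45, 97.0, 0.8),
    "gene": (45, 95.0, None),
}


def filter_alignments(
    records: pd.DataFrame,
    min_len: int = 45,
    min_identity: float = 95.0,
    min_cov: float | None = None,
    preset: str | None = None,
) -> pd.DataFrame:
    """Keep alignments meeting length/identity/coverage floors (all inclusive).

    ``preset='genome'`` applies (45 bp, >=97%, >=80% read coverage) as used
    for genome detection; ``preset='gene'`` applies (45 bp, >=95%) for
    gene-catalogue profiling.
    """
    if preset is not None:
        min_len, min_identity, min_cov = FILTER_PRESETS[preset]
    if records.empty:
        return records.copy()
    keep = (records["aln_len_bp"] >= min_len) & (records["pct_identity"] >= min_identity)
    if min_cov is not None:
        keep &= records["read_cov_fraction"] >= min_cov
    return records.loc[keep].copy()


def assign_inserts(records: pd.DataFrame) -> pd.Series:
    """Fractional insert counts per gene for one sample.

    ``records`` has one row per (insert, candidate target); an insert with a
    single row is a best unique alignment.  Returns a Series indexed by
    gene_id whose total equals the number of inserts exactly (conservation).
    """
    if records.empty:
        return pd.Series(dtype=float, name="count")
    targets = records.groupby("insert_id")["target_gene_id"].apply(list)
    if (targets.str.len() == 0).any():
        raise ValueError("insert with zero targets")
    unique_counts: dict = {}
    ambiguous = []
    for insert_id, genes in targets.items():
        genes = list(dict.fromkeys(genes))  # de-duplicate, keep order
        if len(genes) == 1:
            unique_counts[genes[0]] = unique_counts.get(genes[0], 0.0) + 1.0
        else:
            ambiguous.append(genes)
    counts = dict(unique_counts)
    for genes in ambiguous:
        weights = np.array([unique_counts.get(g, 0.0) for g in genes])
        if weights.sum() == 0:
            weights = np.ones(len(genes))
        weights = weights / weights.sum()
        for g, w in zip(genes, weights):
            counts[g] = counts.get(g, 0.0) + w
    return pd.Series(counts, name="count").sort_index()


def length_normalize(counts: pd.Series, gene_len_bp: pd.Series) -> pd.Series:
    """Inserts per kilobase of gene: count / (length/1000)."""
    lengths = gene_len_bp.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError(f"missing gene lengths: {list(counts.index[lengths.isna()])}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    return counts / (lengths / 1000.0)


def bgc_abundance(gene_abundances: pd.Series, biosynthetic_gene_ids) -> float:
    """Median abundance of a BGC's biosynthetic genes in one sample.

    Genes without a profile entry count as absent (zero).  Even-length
    medians are the mean of the two middle values.
    """
    genes = list(biosynthetic_gene_ids)
    if not genes:
        raise ValueError("BGC without biosynthetic genes")
    values = gene_abundances.reindex(genes).fillna(0.0).to_numpy(dtype=float)
    return float(np.median(values))


def family_abundance(representative_abundances) -> float:
    """Family (GCF/GCC) abundance: sum over its representative BGCs."""
    return float(np.sum(np.asarray(list(representative_abundances), dtype=float)))


def cell_normalize(abundance, marker_normalizer):
    """Per-cell abundance: divide by the sample's summed mOTU abundance.

    A zero normalizer yields NaN (missing), never infinity.
    """
    abundance = np.asarray(abundance, dtype=float)
    norm = float(marker_normalizer)
    if norm <= 0:
        logger.warning("zero/negative marker normalizer: emitting missing values")
        return np.full_like(abundance, np.nan) if abundance.ndim else float("nan")
    return abundance / norm


def prevalence(per_sample_abundance) -> float:
    """Percent of samples where the family is present (abundance > 0)."""
    values = np.asarray(list(per_sample_abundance), dtype=float)
    if values.size == 0:
        raise ValueError("prevalence needs at least one sample")
    return 100.0 * float(np.sum(values > 0)) / values.size


def average_genome_size(
    motu_relative_abundance: pd.Series,
    member_sizes: pd.DataFrame,
    completeness_floor: float = 70.0,
) -> float:
    """Abundance-weighted mean of completeness-corrected mOTU genome sizes.

    ``member_sizes`` has columns motu_id, length_bp, completeness_pct (one
    row per member genome).  Members below ``completeness_floor`` are
    excluded from the per-mOTU mean; relative abundances are renormalized
    over the mOTUs that retain at least one member.  Returns NaN when no
    mOTU survives.
    """
    ok = member_sizes[member_sizes["completeness_pct"] >= completeness_floor].copy()
    if ok.empty:
        return float("nan")
    ok["corrected"] = ok["length_bp"] / (ok["completeness_pct"] / 100.0)
    motu_size = ok.groupby("motu_id")["corrected"].mean()
    weights = motu_relative_abundance.reindex(motu_size.index).fillna(0.0)
    total = weights.sum()
    if total <= 0:
        return float("nan")
    weights = weights / total
    return float((weights * motu_size).sum())


def transcript_activity(
    counts: pd.Series,
    gene_len_bp: pd.Series,
    marker_gene_ids,
    n_markers_total: int = 10,
):
    """Per-gene log2 expression relative to marker-gene (housekeeping) level.

    The marker level is the median length-normalized count over marker genes
    with count > 0.  A sample is 'detected' only when strictly more than
    half (>5 of 10) of the marker genes have nonzero counts; undetected
    samples report no activities.  Genes with zero counts are missing (no
    log of zero).

    Returns (activities: Series | None, detected: bool).
    """
    markers = list(marker_gene_ids)
    marker_counts = counts.reindex(markers).fillna(0.0)
    n_detected = int((marker_counts > 0).sum())
    detected = n_detected > n_markers_total / 2
    if not detected:
        return None, False
    ln = length_normalize(counts, gene_len_bp)
    marker_median = float(ln.reindex(markers).fillna(0.0)[marker_counts > 0].median())
    activity = pd.Series(np.nan, index=counts.index, dtype=float)
    positive = counts > 0
    activity[positive] = np.log2(ln[positive] / marker_median)
    return activity, True
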