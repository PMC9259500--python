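"""Clustering of biosynthetic gene clusters into families (GCFs) and clans (GCCs).

BGCs are represented as nonnegative protein-domain weight vectors.  All-vs-all
cosine distances feed a single average-linkage dendrogram that is cut at two
heights: 0.2 defines gene cluster families (BGCs predicted to encode similar
products) and 0.8 defines the coarser gene cluster clans.  Cutting one tree at
two heights makes the GCF-inside-GCC nesting a structural guarantee.

Also implemented here: the >=5 kb scaffold filter applied before quantitative
analyses, the longest-BGC-per-GCF-per-species dereplication that removes
redundant within-species copies, and order-independent canonical keys for
hybrid product types (a proteusin-bacteriocin hybrid equals a
bacteriocin-proteusin hybrid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "FamilyAssignment",
    "cosine_distance",
    "filter_bgcs",
    "cluster_families",
    "dereplicate_bgcs",
    "product_type_key",
]

SCAFFOLD_MIN_BP = 5000
GCF_THRESHOLD = 0.2
GCC_THRESHOLD = 0.8


@dataclass
class FamilyAssignment:
    """GCF/GCC labels per BGC plus the dendrogram they were cut from."""

    assignments: pd.DataFrame  # columns: bgc_id, gcf, gcc
    linkage_tree: np.ndarray  # scipy linkage matrix
    t_gcf: float
    t_gcc: float
    representative_bgcs: set = field(default_factory=set)

    def __post_init__(self):
        # nesting is a hard invariant: every GCF lies wholly inside one GCC
        gcc_per_gcf = self.assignments.groupby("gcf")["gcc"].nunique()
        if (gcc_per_gcf > 1).any():
            raise AssertionError("GCF partition does not refine the GCC partition")

    @property
    def n_gcfs(self) -> int:
        return self.assignments["gcf"].nunique()

    @property
    def n_gccs(self) -> int:
        return self.assignments["gcc"].nunique()


def cosine_distance(u, v) -> float:
    """Cosine distance 1 - u.v/(|u||v|) between nonnegative weight vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("feature weights must be nonnegative")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance undefined for all-zero vector")
    return float(np.clip(1.0 - (u @ v) / (nu * nv), 0.0, 1.0))


def filter_bgcs(
    bgcs: pd.DataFrame,
    detected_genomes=None,
    excludable_genomes=None,
    min_scaffold_bp: int = SCAFFOLD_MIN_BP,
) -> pd.DataFrame:
    """Scaffold-length and detection filter.

    Keeps BGCs on scaffolds >= ``min_scaffold_bp`` (fragmentation guard).  If
    ``excludable_genomes`` is given (externally sourced genomes such as
    isolate REFs/SAGs whose presence in the samples is unconfirmed), BGCs
    from those genomes are dropped unless the genome is in
    ``detected_genomes``.
    """
    if bgcs.empty:
        return bgcs.copy()
    keep = bgcs["scaffold_len_bp"] >= min_scaffold_bp
    if excludable_genomes is not None:
        excludable = set(excludable_genomes)
        detected = set(detected_genomes or ())
        undetected = bgcs["genome_id"].isin(excludable - detected)
        keep &= ~undetected
    return bgcs.loc[keep].copy()


def cluster_families(
    features: pd.DataFrame,
    t_gcf: float = GCF_THRESHOLD,
    t_gcc: float = GCC_THRESHOLD,
) -> FamilyAssignment:
    """Cut one average-linkage cosine dendrogram at the GCF and GCC heights.

    ``features`` is a BGC x domain matrix (rows indexed by bgc_id).  Labels
    are deterministic: families and clans are numbered by their
    lexicographically smallest member bgc_id, so the output is invariant to
    input row order.
    """
    if not 0 < t_gcf < t_gcc <= 1:
        raise ValueError("thresholds must satisfy 0 < t_gcf < t_gcc <= 1")
    if features.shape[0] < 1:
        raise ValueError("need at least one BGC")
    values = features.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)) or np.any(values < 0):
        raise ValueError("feature weights must be finite and nonnegative")
    norms = np.linalg.norm(values, axis=1)
    if np.any(norms == 0):
        bad = list(features.index[norms == 0])
        raise ValueError(f"all-zero feature rows not admitted to clustering: {bad}")
    ids = [str(i) for i in features.index]
    if len(ids) == 1:
        assignments = pd.DataFrame({"bgc_id": ids, "gcf": ["gcf_0001"], "gcc": ["gcc_0001"]})
        return FamilyAssignment(assignments, np.empty((0, 4)), t_gcf, t_gcc)
    dist = np.clip(pdist(values, metric="cosine"), 0.0, 1.0)
    z = linkage(dist, method="average")
    gcf_raw = fcluster(z, t=t_gcf, criterion="distance")
    gcc_raw = fcluster(z, t=t_gcc, criterion="distance")
    from .genome_qc import _canonical_labels

    assignments = pd.DataFrame(
        {
            "bgc_id": ids,
            "gcf": _canonical_labels(ids, gcf_raw, "gcf"),
            "gcc": _canonical_labels(ids, gcc_raw, "gcc"),
        }
    )
    return FamilyAssignment(assignments, z, t_gcf, t_gcc)


def dereplicate_bgcs(assignment: FamilyAssignment, bgcs: pd.DataFrame) -> set:
    """Longest BGC per (GCF, species); ties to the smallest bgc_id.

    BGCs without a species label (unbinned scaffolds) take part in clustering
    but are excluded here.  The selected representatives are recorded on the
    assignment and returned.
    """
    merged = assignment.assignments.merge(
        bgcs[["bgc_id", "species_id", "bgc_len_bp"]], on="bgc_id", how="left"
    )
    merged = merged.dropna(subset=["species_id"])
    merged = merged[merged["species_id"].astype(str).str.len() > 0]
    reps = set()
    for _, group in merged.groupby(["gcf", "species_id"], sort=False):
        best = group.sort_values(
            ["bgc_len_bp", "bgc_id"], ascending=[False, True]
        ).iloc[0]
        reps.add(str(best["bgc_id"]))
    assignment.representative_bgcs = reps
    return reps


def product_type_key(product_types) -> tuple:
    """Canonical, order-independent key for (possibly hybrid) product types.

    The key is the sorted multiset of type strings: [a, b] == [b, a] but
    [a] != [a, a].
    """
    types = [str(t) for t in product_types]
    if not types:
        raise ValueError("product type list must be nonempty")
    return tuple(sorted(types))
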