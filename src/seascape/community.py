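"""Community-level structure and diversity statistics.

Samples are compared by Euclidean distance between their per-cell GCF
abundance profiles, embedded in low dimension, and clustered by density
(HDBSCAN); the minimum cluster size is chosen by maximizing the cumulative
cluster-membership probability (noise points contribute zero).  Cluster
structure is tested against the *non-reduced* distances with PERMANOVA.
Per-species biosynthetic diversity is the Shannon index over canonical
product types, species with a >15-BGC genome are flagged BGC-rich, and the
predatory index is the difference between predatory and non-predatory
marker-gene counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import HDBSCAN
from sklearn.decomposition import PCA

__all__ = [
    "sample_distances",
    "embed_samples",
    "choose_min_cluster_size",
    "permanova",
    "permanova_balanced",
    "shannon_product_diversity",
    "flag_bgc_rich",
    "predatory_index",
    "PredatoryScore",
]

BGC_RICH_FLOOR = 15
DEFAULT_CANDIDATE_SIZES = (2, 5, 10, 20, 50)


def sample_distances(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between sample rows of a GCF matrix."""
    if profiles.shape[0] < 2:
        raise ValueError("need at least two samples")
    if profiles.isna().any().any():
        raise ValueError("profiles contain missing values; drop those samples first")
    d = squareform(pdist(profiles.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def embed_samples(
    profiles: pd.DataFrame, n_components: int = 2, seed: int = 0, method: str = "pca"
) -> np.ndarray:
    """Low-dimensional embedding of sample profiles.

    ``method='pca'`` is the deterministic default; ``method='umap'`` uses
    umap-learn when installed (same call signature, fixed seed).  The
    downstream cluster-size criterion and PERMANOVA are embedding-agnostic.
    """
    x = profiles.to_numpy(dtype=float)
    n_components = min(n_components, min(x.shape) - 1) or 1
    if method == "umap":
        import umap

        reducer = umap.UMAP(n_components=n_components, random_state=seed)
        return np.asarray(reducer.fit_transform(x), dtype=float)
    return PCA(n_components=n_components, random_state=seed).fit_transform(x)


def choose_min_cluster_size(embedding: np.ndarray, candidate_sizes=None):
    """Pick the HDBSCAN min_cluster_size maximizing total membership probability.

    For every candidate size the embedding is density-clustered and the
    per-point membership probabilities are summed (noise points carry
    probability zero).  Ties go to the smallest candidate.  Returns
    (best_size, labels, probabilities).
    """
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if candidate_sizes is None:
        candidate_sizes = DEFAULT_CANDIDATE_SIZES
    candidates = sorted({int(s) for s in candidate_sizes if 2 <= s <= max(2, n // 2)})
    if not candidates:
        raise ValueError("no valid candidate cluster sizes")
    best = None
    for size in candidates:
        model = HDBSCAN(min_cluster_size=size, copy=True).fit(embedding)
        total = float(model.probabilities_.sum())
        if best is None or total > best[0]:
            best = (total, size, model.labels_.copy(), model.probabilities_.copy())
    _, size, labels, probabilities = best
    return size, labels, probabilities


def _pseudo_f(d2: np.ndarray, onehot: np.ndarray, counts: np.ndarray) -> float:
    n = d2.shape[0]
    k = onehot.shape[1]
    ss_total = d2.sum() / (2.0 * n)
    within_pergroup = np.einsum("ik,ij,jk->k", onehot, d2, onehot) / (2.0 * counts)
    ss_within = within_pergroup.sum()
    ss_among = ss_total - ss_within
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def permanova(
    distances: pd.DataFrame | np.ndarray,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
):
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F from the standard sum-of-squared-distances decomposition; the
    p-value uses the add-one estimator
    (1 + #{permuted F >= observed F}) / (1 + n_permutations), so p is never
    zero.  Samples labelled -1 (density-clustering noise) are excluded.
    Returns (pseudo_F, p_value).
    """
    d = np.asarray(distances, dtype=float)
    groups = np.asarray(list(groups))
    mask = groups != -1 if groups.dtype.kind in "iu" else np.ones(len(groups), bool)
    d = d[np.ix_(mask, mask)]
    groups = groups[mask]
    n = d.shape[0]
    if n != len(groups):
        raise ValueError("label vector does not match the distance matrix")
    labels, inverse = np.unique(groups, return_inverse=True)
    k = len(labels)
    counts = np.bincount(inverse).astype(float)
    if k < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least two members")
    d2 = d ** 2
    onehot = np.eye(k)[inverse]
    observed = _pseudo_f(d2, onehot, counts)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(inverse) for _ in range(n_permutations)])
    perm_onehot = np.eye(k)[perms]  # (P, n, k)
    within = np.einsum("pik,ij,pjk->pk", perm_onehot, d2, perm_onehot) / (2.0 * counts)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = within.sum(axis=1)
    f_perm = ((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k))
    p = (1.0 + np.sum(f_perm >= observed)) / (1.0 + n_permutations)
    return float(observed), float(p)


def permanova_balanced(
    distances: pd.DataFrame,
    groups,
    n_permutations: int = 999,
    n_resamples: int = 20,
    seed: int = 0,
):
    """PERMANOVA on seeded equal-size subsamples per group; median p reported.

    Controls for unequal group sizes, which bias the plain test.
    """
    d = np.asarray(distances, dtype=float)
    groups = np.asarray(list(groups))
    mask = groups != -1 if groups.dtype.kind in "iu" else np.ones(len(groups), bool)
    d = d[np.ix_(mask, mask)]
    groups = groups[mask]
    labels, inverse = np.unique(groups, return_inverse=True)
    size = int(np.bincount(inverse).min())
    if size < 2:
        raise ValueError("every group needs at least two members")
    rng = np.random.default_rng(seed)
    pvals, fvals = [], []
    for _ in range(n_resamples):
        idx = np.concatenate(
            [rng.choice(np.where(inverse == g)[0], size=size, replace=False)
             for g in range(len(labels))]
        )
        f, p = permanova(
            d[np.ix_(idx, idx)], inverse[idx], n_permutations,
            seed=int(rng.integers(2 ** 31 - 1)),
        )
        fvals.append(f)
        pvals.append(p)
    return float(np.median(fvals)), float(np.median(pvals))


def shannon_product_diversity(product_type_counts) -> float:
    """Shannon index (natural log) over product-type counts.

    Accepts a mapping type->count or an iterable of counts; zero-count
    categories are ignored.
    """
    if hasattr(product_type_counts, "values") and not isinstance(
        product_type_counts, (pd.Series, np.ndarray)
    ):
        counts = np.asarray(list(product_type_counts.values()), dtype=float)
    else:
        counts = np.asarray(list(product_type_counts), dtype=float)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("need at least one product type count")
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def flag_bgc_rich(bgc_counts: pd.DataFrame, floor: int = BGC_RICH_FLOOR) -> pd.DataFrame:
    """Per-species BGC-richness from per-genome BGC counts.

    ``bgc_counts`` has columns species_id, genome_id, n_bgcs.  The species
    display representative is its genome with the most BGCs; a species is
    BGC-rich when that maximum strictly exceeds ``floor`` (>15 by default).
    """
    if bgc_counts.empty:
        return pd.DataFrame(
            columns=["species_id", "representative_genome", "max_bgcs_per_genome", "bgc_rich"]
        )
    rows = []
    for species, group in bgc_counts.groupby("species_id", sort=True):
        best = group.sort_values(["n_bgcs", "genome_id"], ascending=[False, True]).iloc[0]
        rows.append(
            {
                "species_id": species,
                "representative_genome": best["genome_id"],
                "max_bgcs_per_genome": int(best["n_bgcs"]),
                "bgc_rich": bool(best["n_bgcs"] > floor),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PredatoryScore:
    genome_id: str
    n_predatory_markers: int
    n_nonpredatory_markers: int

    @property
    def index(self) -> int:
        return self.n_predatory_markers - self.n_nonpredatory_markers


def predatory_index(marker_hits: pd.DataFrame, genome_id: str) -> PredatoryScore:
    """Predatory-lifestyle index: #predatory minus #non-predatory marker hits.

    ``marker_hits`` has columns genome_id, marker_id, class with class in
    {'predatory', 'non-predatory'}.
    """
    hits = marker_hits[marker_hits["genome_id"] == genome_id]
    classes = set(hits["class"].unique()) - {"predatory", "non-predatory"}
    if classes:
        raise ValueError(f"unknown marker classes: {sorted(classes)}")
    n_pred = int((hits["class"] == "predatory").sum())
    n_non = int((hits["class"] == "non-predatory").sum())
    return PredatoryScore(str(genome_id), n_pred, n_non)
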