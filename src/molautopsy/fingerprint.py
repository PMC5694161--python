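"""Genetic-fingerprint similarity between samples.

Each sample is reduced to the set of genes carrying at least one variant
of pathogenicity category 1-3 (categories collapsed per gene; category 3
is included to enlarge the sets, since categories 1-2 alone overlap by at
most a few genes between any two cases).  Samples are then compared
pairwise with the Jaccard index J = |Gi n Gj| / |Gi u Gj|, the strict
upper triangle is standardized to Z-scores with the sample-variance
convention over all distinct pairs, and the Z matrix is clustered
hierarchically (complete linkage on Euclidean row distance by default,
mirroring the common R heatmap defaults).

Conventions: J = 0 when the union is empty (two empty gene sets); the
diagonal of J is 1 and the diagonal of Z is undefined and returned as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import VariantRecord, normalize_gene

FINGERPRINT_CATEGORIES = frozenset({1, 2, 3})


@dataclass
class FingerprintResult:
    """Gene sets, similarity matrices and clustering for one cohort."""

    sample_ids: list[str]
    gene_sets: dict[str, frozenset[str]]
    jaccard: np.ndarray
    zscores: np.ndarray
    linkage: np.ndarray  # scipy linkage matrix, (n-1) x 4
    top_pairs: list[dict]

    @property
    def leaf_order(self) -> list[str]:
        return [self.sample_ids[i] for i in hierarchy.leaves_list(self.linkage)]


def collapse_gene_sets(
    variants: list[VariantRecord], categories: frozenset[int] = FINGERPRINT_CATEGORIES
) -> dict[str, frozenset[str]]:
    """Per sample, distinct genes with >= 1 variant in the category band.

    Samples whose variants all fall outside the band are retained with an
    empty set.
    """
    sets: dict[str, set[str]] = {}
    for v in variants:
        sets.setdefault(v.sample_id, set())
        if v.category in categories and v.gene is not None:
            sets[v.sample_id].add(normalize_gene(v.gene))
    return {s: frozenset(g) for s, g in sets.items()}


def jaccard_matrix(gene_sets: dict[str, frozenset[str]], sample_ids: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Symmetric pairwise Jaccard matrix with unit diagonal."""
    if sample_ids is None:
        sample_ids = sorted(gene_sets)
    n = len(sample_ids)
    if n < 2:
        raise ValueError("jaccard_matrix requires at least two samples")
    J = np.eye(n)
    for i in range(n):
        gi = gene_sets[sample_ids[i]]
        for j in range(i + 1, n):
            gj = gene_sets[sample_ids[j]]
            union = len(gi | gj)
            J[i, j] = J[j, i] = len(gi & gj) / union if union else 0.0
    return J, list(sample_ids)


def standardize_zscores(jaccard: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Z-score standardization over all distinct unordered pairs.

    The mean and standard deviation are global (not per row), matching a
    single scalar Z per pair; ``ddof=1`` is the sample-sd convention
    (``ddof=0`` gives the population convention).  Degenerate input where
    all pairs are equal has no defined Z and raises.
    """
    J = np.asarray(jaccard, dtype=float)
    n = J.shape[0]
    if J.shape != (n, n) or n < 3:
        raise ValueError("standardize_zscores needs a square matrix for >= 3 samples")
    iu = np.triu_indices(n, k=1)
    pairs = J[iu]
    mean = pairs.mean()
    sd = pairs.std(ddof=ddof)
    if sd == 0.0:
        raise ValueError("degenerate similarity matrix: all pairs equal, sd is zero")
    Z = (J - mean) / sd
    np.fill_diagonal(Z, np.nan)
    return Z


def rank_pairs(
    zscores: np.ndarray,
    gene_sets: dict[str, frozenset[str]],
    sample_ids: list[str],
    z_threshold: float = 3.0,
) -> list[dict]:
    """Pairs with Z above the threshold, sorted by Z descending.

    Ties break by sample-id order; each entry carries the sorted
    intersection gene list and the intersection/union sizes.
    """
    n = len(sample_ids)
    entries = []
    for i in range(n):
        for j in range(i + 1, n):
            z = zscores[i, j]
            if np.isnan(z) or z <= z_threshold:
                continue
            gi, gj = gene_sets[sample_ids[i]], gene_sets[sample_ids[j]]
            entries.append(
                {
                    "pair": (sample_ids[i], sample_ids[j]),
                    "zscore": float(z),
                    "n_intersection": len(gi & gj),
                    "n_union": len(gi | gj),
                    "intersection_genes": sorted(gi & gj),
                }
            )
    entries.sort(key=lambda e: (-e["zscore"], e["pair"]))
    return entries


def cluster_samples(
    matrix: np.ndarray,
    linkage: str = "complete",
    distance: str = "euclidean_rows",
    jaccard: np.ndarray | None = None,
) -> np.ndarray:
    """Agglomerative clustering of the similarity matrix.

    ``euclidean_rows`` treats each row of the (Z) matrix as a feature
    vector, with any NaN diagonal zeroed first; ``one_minus_jaccard`` uses
    1 - J directly as the pairwise distance.  Returns a scipy linkage
    matrix with n-1 merges; heights are monotone for complete/average
    linkage.
    """
    if linkage not in ("complete", "average", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    M = np.asarray(matrix, dtype=float)
    if distance == "euclidean_rows":
        M = M.copy()
        if M.ndim == 2 and M.shape[0] == M.shape[1]:
            np.fill_diagonal(M, 0.0)  # mask the NaN diagonal of a Z matrix
        if not np.all(np.isfinite(M)):
            raise ValueError("non-finite entries in similarity matrix")
        import warnings

        with warnings.catch_warnings():
            # rows of the square similarity matrix are the feature vectors
            warnings.simplefilter("ignore", hierarchy.ClusterWarning)
            return hierarchy.linkage(M, method=linkage, metric="euclidean")
    if distance == "one_minus_jaccard":
        J = M if jaccard is None else np.asarray(jaccard, dtype=float)
        D = 1.0 - J
        np.fill_diagonal(D, 0.0)
        if not np.all(np.isfinite(D)):
            raise ValueError("non-finite entries in similarity matrix")
        return hierarchy.linkage(squareform(D, checks=False), method=linkage)
    raise ValueError(f"unsupported distance {distance!r}")


def compute_fingerprint(
    variants: list[VariantRecord],
    categories: frozenset[int] = FINGERPRINT_CATEGORIES,
    z_threshold: float = 3.0,
    linkage: str = "complete",
    distance: str = "euclidean_rows",
    ddof: int = 1,
) -> FingerprintResult:
    """End-to-end fingerprint: gene sets -> J -> Z -> ranking -> tree."""
    gene_sets = collapse_gene_sets(variants, categories)
    J, sample_ids = jaccard_matrix(gene_sets)
    Z = standardize_zscores(J, ddof=ddof)
    link = cluster_samples(Z, linkage=linkage, distance=distance, jaccard=J)
    pairs = rank_pairs(Z, gene_sets, sample_ids, z_threshold=z_threshold)
    return FingerprintResult(
        sample_ids=sample_ids,
        gene_sets=gene_sets,
        jaccard=J,
        zscores=Z,
        linkage=link,
        top_pairs=pairs,
    )


def plot_heatmap(result: FingerprintResult, path: str) -> None:
    """Write a clustered heatmap of the Z matrix (optional side-effect)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = [result.sample_ids.index(s) for s in result.leaf_order]
    Z = result.zscores[np.ix_(order, order)]
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(Z, cmap="viridis")
    ax.set_xticks(range(len(order)), [result.sample_ids[i] for i in order], rotation=90, fontsize=5)
    ax.set_yticks(range(len(order)), [result.sample_ids[i] for i in order], fontsize=5)
    fig.colorbar(im, ax=ax, label="pairwise Z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
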