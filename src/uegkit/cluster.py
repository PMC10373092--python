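"""Percentile clustering of genes and the five-way specificity classification.

Percentile clustering groups genes by the shape of their expression
distributions: the feature vector of a gene is its dynamic range (the Q5
... Q95 percentiles of its quantile ranks), and clustering runs on these
vectors. Affinity propagation with a negative squared-Euclidean similarity
and median-similarity preference is the default because it determines the
number of clusters itself and names an exemplar gene per cluster; seeded
k-means is available for sensitivity comparison.

Clusters are then classified into five specificity categories from their
median φ at the two TPM thresholds, first matching rule wins:

1. median φ@TPM:1   >= 0.8  →  UEGs@1.0   (ubiquitous at the strict threshold)
2. median φ@TPM:0.1 >= 0.8  →  UEGs@0.1   (ubiquitous only at the sensitive one)
3. median φ@TPM:0.1 <= 0.3  →  SEGs@0.1   (specific even at the sensitive one)
4. median φ@TPM:1   <= 0.3  →  SEGs@1.0
5. otherwise                →  MSG        (moderately specific)

LoVarUEGs are the members of UEG-category clusters whose median IQR of
quantile ranks falls in the low-variability band (<= 0.2), minus per-cluster
outliers whose raw-TPM fold range contradicts their rank-scale stability;
they are usable as internal reference genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import AffinityPropagation, KMeans
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import pairwise_distances_argmin

from .containers import ExpressionMatrix
from .distribution import DynamicRangeMatrix

logger = logging.getLogger(__name__)

UEG_CATEGORIES = ("UEGs@1.0", "UEGs@0.1")
SEG_CATEGORIES = ("SEGs@0.1", "SEGs@1.0")
CATEGORIES = ("UEGs@1.0", "UEGs@0.1", "MSG", "SEGs@1.0", "SEGs@0.1")


class PercentileClusterer(ClusterMixin, BaseEstimator):
    """Cluster distribution-shape vectors by affinity propagation or k-means.

    Parameters
    ----------
    method : {"affinity", "kmeans"}
    random_state : int
        Seed; both modes are deterministic for a fixed seed.
    damping : float
        Affinity-propagation damping; escalated on non-convergence up to
        ``max_retries`` times before a hard error.
    preference : float or None
        Affinity-propagation preference; None uses the median similarity.
    n_clusters : int or None
        k for k-means (required in kmeans mode).

    Attributes
    ----------
    labels_ : ndarray of cluster ids
    exemplar_indices_ : ndarray, row index of each cluster's exemplar
        (for k-means, the member closest to the centroid)
    n_clusters_ : int
    """

    def __init__(
        self,
        method: str = "affinity",
        random_state: int = 0,
        damping: float = 0.9,
        preference: float | None = None,
        n_clusters: int | None = None,
        max_iter: int = 500,
        max_retries: int = 3,
    ):
        self.method = method
        self.random_state = random_state
        self.damping = damping
        self.preference = preference
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.max_retries = max_retries

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("clustering requires a 2D matrix with >= 2 rows")
        if not np.all(np.isfinite(X)):
            raise ValueError("percentile vectors must be finite")
        if self.method == "affinity":
            self._fit_affinity(X)
        elif self.method == "kmeans":
            self._fit_kmeans(X)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.n_clusters_ = int(len(np.unique(self.labels_)))
        return self

    def _fit_affinity(self, X: np.ndarray) -> None:
        damping = self.damping
        last_exc: Exception | None = None
        for attempt in range(self.max_retries + 1):
            ap = AffinityPropagation(
                damping=damping,
                preference=self.preference,
                max_iter=self.max_iter,
                convergence_iter=15,
                random_state=self.random_state,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                try:
                    ap.fit(X)
                except ConvergenceWarning as exc:  # escalate damping, retry
                    last_exc = exc
                    logger.warning(
                        "affinity propagation did not converge at damping=%.3f", damping
                    )
                    damping = damping + (0.99 - damping) * 0.5
                    continue
            self.labels_ = ap.labels_
            self.exemplar_indices_ = ap.cluster_centers_indices_
            self.damping_ = damping
            return
        raise RuntimeError(
            "affinity propagation failed to converge after "
            f"{self.max_retries + 1} attempts (final damping {damping:.3f}): {last_exc}"
        )

    def _fit_kmeans(self, X: np.ndarray) -> None:
        if self.n_clusters is None:
            raise ValueError("kmeans mode requires n_clusters")
        km = KMeans(
            n_clusters=self.n_clusters,
            n_init=10,
            random_state=self.random_state,
        ).fit(X)
        self.labels_ = km.labels_
        self.cluster_centers_ = km.cluster_centers_
        # exemplar = member nearest to its centroid
        exemplars = np.empty(self.n_clusters, dtype=int)
        for c in range(self.n_clusters):
            members = np.flatnonzero(km.labels_ == c)
            d = np.linalg.norm(X[members] - km.cluster_centers_[c], axis=1)
            exemplars[c] = members[np.argmin(d)]
        self.exemplar_indices_ = exemplars


@dataclass
class ClusterResult:
    """Gene → cluster assignment plus per-cluster shape/specificity medians."""

    labels: pd.Series  # gene_id → cluster_id
    exemplars: pd.Series  # cluster_id → exemplar gene_id
    medians: pd.DataFrame  # cluster_id × {size, phi medians, iqr, skewness, q50}
    method: str

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)


def cluster_genes(
    drm: DynamicRangeMatrix,
    spec_table: pd.DataFrame,
    method: str = "affinity",
    seed: int = 0,
    **params,
) -> ClusterResult:
    """Run percentile clustering and attach per-cluster medians.

    *spec_table* must carry per-gene φ columns (``phi@TPM:0.1`` etc.) aligned
    on gene IDs; its medians per cluster feed the category rules.
    """
    X = drm.percentiles.to_numpy(dtype=float)
    clusterer = PercentileClusterer(method=method, random_state=seed, **params).fit(X)
    genes = drm.percentiles.index
    labels = pd.Series(clusterer.labels_, index=genes, name="cluster_id")
    exemplars = pd.Series(
        genes[clusterer.exemplar_indices_],
        index=range(clusterer.n_clusters_),
        name="exemplar",
    )
    stats = pd.concat(
        [
            spec_table.reindex(genes),
            drm.summary[["q50", "iqr", "skewness"]].reindex(genes),
        ],
        axis=1,
    )
    med = stats.groupby(labels.to_numpy()).median()
    med.columns = [f"median_{c}" for c in med.columns]
    med.insert(0, "size", labels.value_counts().sort_index())
    med.insert(1, "exemplar", exemplars)
    med.index.name = "cluster_id"
    return ClusterResult(labels=labels, exemplars=exemplars, medians=med, method=method)


def cluster_homogeneity(drm: DynamicRangeMatrix, result: ClusterResult) -> float:
    """Mean within-cluster Euclidean distance to the cluster exemplar.

    Zero iff every member equals its exemplar; lower is tighter. k-means
    results may alternatively be scored against centroids via
    :func:`centroid_homogeneity`.
    """
    X = drm.percentiles
    d = 0.0
    n = 0
    for c, exemplar in result.exemplars.items():
        members = result.labels.index[result.labels == c]
        diff = X.loc[members].to_numpy() - X.loc[exemplar].to_numpy()
        d += float(np.linalg.norm(diff, axis=1).sum())
        n += len(members)
    if n == 0:
        raise ValueError("labels cover no genes")
    return d / n


def centroid_homogeneity(drm: DynamicRangeMatrix, labels: pd.Series) -> float:
    """Mean within-cluster Euclidean distance to the cluster centroid."""
    X = drm.percentiles.to_numpy(dtype=float)
    lab = labels.reindex(drm.percentiles.index).to_numpy()
    total = 0.0
    for c in np.unique(lab):
        members = X[lab == c]
        total += float(np.linalg.norm(members - members.mean(axis=0), axis=1).sum())
    return total / len(lab)


@dataclass
class CategoryAssignment:
    """Five-way specificity category per cluster, inherited per gene."""

    cluster_category: pd.Series  # cluster_id → category
    gene_category: pd.Series  # gene_id → category
    ueg_cut: float
    seg_cut: float


def assign_categories(
    clusters: ClusterResult,
    ueg_cut: float = 0.8,
    seg_cut: float = 0.3,
    phi_strict: str = "median_phi@TPM:1",
    phi_sensitive: str = "median_phi@TPM:0.1",
) -> CategoryAssignment:
    """Classify each cluster into one of the five specificity categories."""
    med = clusters.medians
    for col in (phi_strict, phi_sensitive):
        if col not in med.columns:
            raise KeyError(f"cluster medians lack required column {col!r}")
    strict = med[phi_strict]
    sensitive = med[phi_sensitive]
    cat = pd.Series("MSG", index=med.index, name="category")
    cat[strict <= seg_cut] = "SEGs@1.0"
    cat[sensitive <= seg_cut] = "SEGs@0.1"
    cat[sensitive >= ueg_cut] = "UEGs@0.1"
    cat[strict >= ueg_cut] = "UEGs@1.0"
    gene_cat = clusters.labels.map(cat)
    gene_cat.name = "category"
    return CategoryAssignment(
        cluster_category=cat, gene_category=gene_cat, ueg_cut=ueg_cut, seg_cut=seg_cut
    )


@dataclass
class LoVarSet:
    """Low-variability UEG selection (candidate internal reference genes)."""

    selected: list[str]
    source_clusters: list[int]
    stats: pd.DataFrame  # per considered gene: cluster, iqr, fold stat, z
    outliers_removed: pd.DataFrame  # gene_id, cluster, reason
    removed_fraction: float


def select_lovar(
    clusters: ClusterResult,
    categories: CategoryAssignment,
    drm: DynamicRangeMatrix,
    raw: ExpressionMatrix | None = None,
    iqr_cut: float = 0.2,
    outlier_rule: str = "robust_z",
    z_cut: float = 3.0,
    fold_cap_pct: float = 97.0,
) -> LoVarSet:
    """Select stable UEGs from low-variability UEG clusters, minus outliers.

    Gate: clusters whose category is UEG and whose median rank IQR <=
    ``iqr_cut``. Outlier screen (``robust_z``): within each source cluster,
    genes whose log10 raw-TPM Q95/Q5 fold range has a robust z-score above
    ``z_cut`` are removed — their raw-scale swing contradicts rank-scale
    stability. ``percentile_cap`` instead removes genes above the
    ``fold_cap_pct`` percentile of fold range across all selected genes.
    """
    med = clusters.medians
    ueg_clusters = [
        int(c)
        for c in med.index
        if categories.cluster_category.loc[c] in UEG_CATEGORIES
        and med.loc[c, "median_iqr"] <= iqr_cut
    ]
    if not ueg_clusters:
        logger.warning("no UEG cluster passed the IQR gate; LoVar set is empty")
        empty = pd.DataFrame(columns=["cluster", "iqr", "log10_fold", "z"])
        return LoVarSet([], [], empty, empty.assign(reason=[]), 0.0)

    member_mask = clusters.labels.isin(ueg_clusters)
    members = clusters.labels.index[member_mask]
    stats = pd.DataFrame(
        {
            "cluster": clusters.labels.loc[members],
            "iqr": drm.summary["iqr"].reindex(members),
        }
    )
    if raw is not None:
        raw.require_unit("TPM", "RPKM")
        vals = raw.values.reindex(members).to_numpy(dtype=float)
        q5, q95 = np.percentile(vals, [5, 95], axis=1)
        eps = 1e-3  # TPM-scale guard for undetected tails
        stats["log10_fold"] = np.log10((q95 + eps) / (q5 + eps))
    else:
        # fall back to rank-scale spread when no raw matrix is supplied
        stats["log10_fold"] = drm.summary["iqr"].reindex(members)

    if outlier_rule == "robust_z":
        z = np.full(len(stats), 0.0)
        for c in ueg_clusters:
            sel = stats["cluster"] == c
            x = stats.loc[sel, "log10_fold"].to_numpy()
            mad = np.median(np.abs(x - np.median(x)))
            if mad > 0:
                z[sel.to_numpy()] = (x - np.median(x)) / (1.4826 * mad)
        stats["z"] = z
        out_mask = np.abs(stats["z"].to_numpy()) > z_cut
        reason = f"|robust z| > {z_cut:g} on log10 raw fold range"
    elif outlier_rule == "percentile_cap":
        cap = np.percentile(stats["log10_fold"].to_numpy(), fold_cap_pct)
        stats["z"] = np.nan
        out_mask = stats["log10_fold"].to_numpy() > cap
        reason = f"log10 fold range above the {fold_cap_pct:g}th percentile"
    else:
        raise ValueError(f"unknown outlier_rule {outlier_rule!r}")

    outliers = stats.loc[out_mask].copy()
    outliers["reason"] = reason
    selected = [g for g, o in zip(members, out_mask) if not o]
    removed_fraction = float(out_mask.mean()) if len(stats) else 0.0
    return LoVarSet(
        selected=selected,
        source_clusters=ueg_clusters,
        stats=stats,
        outliers_removed=outliers,
        removed_fraction=removed_fraction,
    )
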