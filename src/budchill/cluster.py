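"""k-means clustering of gene expression trajectories.

Each gene is one observation whose feature vector concatenates its mean
relative expression across all (timepoint, cultivar) cells.  Profiles are
z-scored per gene by default so that trajectory *shape*, not amplitude,
drives cluster membership.  k-means is restarted from many random
assignments and the solution with the smallest total within-cluster sum of
squares (WSS) is kept; restart sub-seeds derive deterministically from a
master seed, so results are exactly reproducible.

Cluster labels are arbitrary in k-means; they are reported in a canonical
order (sorted by the time index at which each centroid peaks) so repeated
runs and permuted inputs yield comparable labelings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .expression import ExpressionProfileMatrix

__all__ = [
    "ClusteringError",
    "ClusteringResult",
    "build_feature_matrix",
    "kmeans_best_of_n",
    "wss_curve",
]


class ClusteringError(ValueError):
    pass


@dataclass(frozen=True)
class ClusteringResult:
    k: int
    assignments: pd.Series  # gene -> cluster id in 1..k
    centroids: pd.DataFrame  # one row per cluster id
    total_wss: float
    per_run_wss: list[float]
    seed: int

    def __post_init__(self) -> None:
        if abs(self.total_wss - min(self.per_run_wss)) > 1e-9 * max(1.0, self.total_wss):
            raise ClusteringError("chosen WSS is not the minimum over restarts")


def build_feature_matrix(
    profiles: ExpressionProfileMatrix,
    standardize: bool = True,
    max_missing_frac: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x feature matrix for clustering, with a drop log.

    Genes missing in more than ``max_missing_frac`` of cells are dropped
    (logged with the missing fraction); remaining gaps are linearly
    interpolated along the column (time) axis.  With ``standardize`` each
    row is z-scored; zero-variance rows become all-zero rather than NaN.
    """
    values = profiles.values
    if values.empty:
        raise ClusteringError("empty profile matrix")
    frac_missing = values.isna().mean(axis=1)
    dropped = frac_missing[frac_missing > max_missing_frac]
    drop_log = pd.DataFrame(
        {"gene": dropped.index, "missing_fraction": dropped.values}
    )
    kept = values.loc[frac_missing <= max_missing_frac].copy()
    if kept.empty:
        raise ClusteringError("all genes dropped by the missing-data filter")
    if kept.isna().any().any():
        filled = kept.T.interpolate(method="linear", limit_direction="both").T
        kept = filled
    X = kept
    if standardize:
        mu = X.mean(axis=1)
        sd = X.std(axis=1, ddof=0)
        sd_safe = sd.replace(0.0, 1.0)
        X = X.sub(mu, axis=0).div(sd_safe, axis=0)
    return X, drop_log


def _canonical_relabel(labels: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Renumber clusters 1..k by the time of each centroid's maximum."""
    order = np.lexsort((-np.bincount(labels, minlength=len(centers)), centers.argmax(axis=1)))
    remap = np.empty(len(centers), dtype=int)
    remap[order] = np.arange(1, len(centers) + 1)
    return remap[labels], centers[order]


def kmeans_best_of_n(
    features: pd.DataFrame,
    k: int,
    n_starts: int = 25,
    seed: int = 0,
) -> ClusteringResult:
    """Best-of-``n_starts`` k-means on gene trajectory features.

    Each restart uses a random initial assignment with its own sub-seed
    derived from the master seed; the run with the smallest total
    within-cluster sum of squares wins.
    """
    n_genes = len(features)
    if not 2 <= k < n_genes:
        raise ClusteringError(f"k must satisfy 2 <= k < {n_genes} genes")
    if n_starts < 1:
        raise ClusteringError("n_starts must be >= 1")
    X = features.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ClusteringError("feature matrix contains missing values")

    sub_seeds = np.random.SeedSequence(seed).generate_state(n_starts) % (2**31 - 1)
    per_run, best = [], None
    for s in sub_seeds:
        km = KMeans(n_clusters=k, init="random", n_init=1, random_state=int(s)).fit(X)
        per_run.append(float(km.inertia_))
        if best is None or km.inertia_ < best.inertia_:
            best = km
    labels, centers = _canonical_relabel(best.labels_, best.cluster_centers_)
    assignments = pd.Series(labels, index=features.index, name="cluster")
    centroids = pd.DataFrame(centers, index=pd.RangeIndex(1, k + 1, name="cluster"),
                             columns=features.columns)
    return ClusteringResult(
        k=k,
        assignments=assignments,
        centroids=centroids,
        total_wss=float(best.inertia_),
        per_run_wss=per_run,
        seed=seed,
    )


def wss_curve(
    features: pd.DataFrame,
    k_min: int = 1,
    k_max: int = 10,
    n_starts: int = 25,
    seed: int = 0,
) -> tuple[pd.DataFrame, int | None]:
    """Best-of-n WSS per k, plus an elbow suggestion.

    The suggested k maximizes the second difference of the WSS curve; the
    final choice of k remains with the analyst.  For k = 1 the WSS is the
    total sum of squared deviations from the grand centroid.
    """
    n_genes = len(features)
    if not 1 <= k_min <= k_max < n_genes:
        raise ClusteringError("require 1 <= k_min <= k_max < number of genes")
    X = features.to_numpy(dtype=float)
    rows = []
    for k in range(k_min, k_max + 1):
        if k == 1:
            wss = float(((X - X.mean(axis=0)) ** 2).sum())
        else:
            wss = kmeans_best_of_n(features, k, n_starts=n_starts, seed=seed).total_wss
        rows.append({"k": k, "total_wss": wss})
    curve = pd.DataFrame(rows)
    elbow = None
    if len(curve) >= 3:
        w = curve["total_wss"].to_numpy()
        second_diff = w[:-2] - 2 * w[1:-1] + w[2:]
        elbow = int(curve["k"].iloc[int(np.argmax(second_diff)) + 1])
    return curve, elbow
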