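"""ARE module discovery and group assignment.

Reference AREs are clustered into coactivity modules by k-centroids on a
binarized signal matrix under the Jaccard distance, reference samples are
clustered hierarchically, and modules are assigned to named groups
(broadly-active, multitissue, newly-detected, or per-sample-cluster) from
their ubiquitous scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "binarize_signal",
    "jaccard_distance",
    "kcentroid_cluster",
    "ubiquitous_score",
    "cluster_samples",
    "assign_groups",
    "ModuleAssignment",
    "GroupAssignment",
]

BROADLY_ACTIVE = "broadly-active"
MULTITISSUE = "multitissue"
NEWLY_DETECTED = "newly-detected"


@dataclass
class ModuleAssignment:
    labels: pd.Series  # are_id -> module index in [1..k]
    k: int
    centroids: np.ndarray  # (k, n_epigenomes)
    within_distance: float  # total generalized-Jaccard distance


@dataclass
class GroupAssignment:
    table: pd.DataFrame  # index: module; columns: group, ubiquitous_score, strongest_cluster


def binarize_signal(signal: pd.DataFrame, cutoff: float = 2.0) -> pd.DataFrame:
    """Binarize a signal matrix: entry = 1 iff signal >= cutoff."""
    return (signal >= cutoff).astype(np.int8)


def jaccard_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - |u AND v| / |u OR v| for binary vectors; two empty vectors -> 0."""
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    union = np.logical_or(u, v).sum()
    if union == 0:
        return 0.0
    return 1.0 - np.logical_and(u, v).sum() / union


def _generalized_jaccard_dist(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Pairwise 1 - sum(min) / sum(max) between rows of X and centroids."""
    # (n, 1, m) vs (1, k, m); fine at module-clustering scale
    mins = np.minimum(X[:, None, :], centroids[None, :, :]).sum(axis=2)
    maxs = np.maximum(X[:, None, :], centroids[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - mins / maxs
    d[maxs == 0] = 0.0  # both empty -> identical
    return d


def kcentroid_cluster(
    binary_matrix: pd.DataFrame,
    k: int,
    n_restarts: int = 5,
    seed: int = 0,
    max_iter: int = 100,
) -> ModuleAssignment:
    """Lloyd-style k-centroids under the generalized Jaccard distance.

    Each ARE (row) is assigned to its nearest real-valued centroid by
    1 - sum(min)/sum(max); centroids are recomputed as the mean of their
    members, accepted only when the mean does not increase the cluster's
    summed distance (the mean is not the exact Jaccard minimizer, so the
    acceptance test keeps the objective monotonically non-increasing).
    The best of ``n_restarts`` random initializations (by total
    within-cluster distance) is returned; ties in assignment go to the
    lowest module index.
    """
    if binary_matrix is None or binary_matrix.size == 0:
        raise ValueError("empty matrix")
    X = binary_matrix.to_numpy(float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_restarts):
        centroids = X[rng.choice(n, size=k, replace=False)].copy()
        prev_total = np.inf
        labels = np.zeros(n, dtype=int)
        for _it in range(max_iter):
            d = _generalized_jaccard_dist(X, centroids)
            labels = d.argmin(axis=1)  # argmin returns lowest index on ties
            total = d[np.arange(n), labels].sum()
            assert total <= prev_total + 1e-9, "within-cluster distance increased"
            for c in range(k):
                members = X[labels == c]
                if len(members):
                    cand = members.mean(axis=0)
                    old_cost = d[labels == c, c].sum()
                    new_cost = _generalized_jaccard_dist(
                        members, cand[None, :]
                    ).sum()
                    if new_cost <= old_cost:
                        centroids[c] = cand
                else:  # re-seed empty cluster at the worst-fit point
                    centroids[c] = X[d[np.arange(n), labels].argmax()]
            if abs(prev_total - total) < 1e-12:
                break
            prev_total = total
        d = _generalized_jaccard_dist(X, centroids)
        labels = d.argmin(axis=1)
        total = d[np.arange(n), labels].sum()
        if best is None or total < best[0]:
            best = (total, labels.copy(), centroids.copy())

    total, labels, centroids = best
    return ModuleAssignment(
        labels=pd.Series(labels + 1, index=binary_matrix.index, name="module"),
        k=k,
        centroids=centroids,
        within_distance=float(total),
    )


def ubiquitous_score(
    module_mean_activity: pd.Series | np.ndarray, activity_threshold: float = 0.2
) -> float:
    """Fraction of samples whose module-mean activity >= threshold."""
    a = np.asarray(module_mean_activity, float)
    return float((a >= activity_threshold).mean())


def cluster_samples(module_mean_matrix: pd.DataFrame, n_clusters: int = 11) -> pd.Series:
    """Average-linkage hierarchical clustering with 1 - Pearson distance.

    ``module_mean_matrix`` is module x sample; the tree over samples is
    cut at ``n_clusters``.  Constant sample vectors are rejected
    (correlation undefined).
    """
    X = module_mean_matrix.to_numpy(float).T  # samples x modules
    if X.shape[0] < n_clusters:
        raise ValueError("need at least n_clusters samples")
    if (X.std(axis=1) == 0).any():
        bad = module_mean_matrix.columns[X.std(axis=1) == 0].tolist()
        raise ValueError(f"constant sample vectors (correlation undefined): {bad}")
    corr = np.corrcoef(X)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=module_mean_matrix.columns, name="sample_cluster")


def assign_groups(
    modules: ModuleAssignment,
    activities: pd.DataFrame,
    sample_clusters: pd.Series,
    activity_threshold: float = 0.2,
    broad_cutoff: float = 0.5,
    multi_cutoff: float = 0.1,
) -> GroupAssignment:
    """Assign each module to a named group from its ubiquitous score.

    Rules (boundaries go to the lower category, "above 0.5" is strict):
    score > 0.5 -> broadly-active; 0.1 < score <= 0.5 -> multitissue;
    all-zero activity in every sample -> newly-detected; otherwise the
    sample cluster where the module's mean signal is strongest.
    """
    rows = []
    for m in sorted(modules.labels.unique()):
        member_acts = activities.loc[modules.labels.index[modules.labels == m]]
        means = member_acts.mean(axis=0)  # per-sample module mean
        score = ubiquitous_score(means, activity_threshold)
        if (member_acts.to_numpy() == 0).all():
            group, strongest = NEWLY_DETECTED, None
        elif score > broad_cutoff:
            group, strongest = BROADLY_ACTIVE, None
        elif score > multi_cutoff:
            group, strongest = MULTITISSUE, None
        else:
            per_cluster = means.groupby(sample_clusters).mean()
            strongest = per_cluster.idxmax()
            group = f"cluster-{strongest}"
        rows.append(
            {
                "module": m,
                "group": group,
                "ubiquitous_score": score,
                "strongest_cluster": strongest,
            }
        )
    return GroupAssignment(table=pd.DataFrame(rows).set_index("module"))
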