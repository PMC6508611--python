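"""Ward clustering of DE-gene fold-change profiles with silhouette-based
choice of the number of clusters.

Genes are clustered on their log2FC-versus-healthy profiles across all
conditions (disease plus every treatment arm) with agglomerative
hierarchical clustering under Ward's minimum-variance criterion on
Euclidean distances.  The cluster count is chosen by maximising the mean
silhouette width over a candidate range, breaking ties toward the smaller
(more parsimonious) k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from .metrics import profile_distance

log = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    k: int
    labels: pd.Series                      # gene -> cluster id in 1..k
    silhouette_by_k: dict[int, float]
    feature_columns: list[str]


def ward_cluster(profiles: pd.DataFrame, k: int) -> pd.Series:
    """Cut a Ward dendrogram of the profile rows into ``k`` clusters.

    Deterministic for a fixed row order; cluster ids are renumbered 1..k in
    order of first appearance.
    """
    n = len(profiles)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} profiles")
    if profiles.isna().any().any():
        raise ValueError("profiles contain missing values")
    if k == n:
        raw = np.arange(1, n + 1)
    else:
        z = linkage(profiles.to_numpy(), method="ward")
        raw = fcluster(z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    ordered = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        ordered[i] = relabel[lab]
    return pd.Series(ordered, index=profiles.index, name="cluster")


def select_k_silhouette(
    profiles: pd.DataFrame,
    k_min: int = 2,
    k_max: int = 15,
) -> ClusterAssignment:
    """Ward labels at the silhouette-optimal cluster count.

    Mean silhouette width (Euclidean) is evaluated for each k in the
    candidate range (clamped to [2, n-1]); the assignment at the argmax is
    returned, ties resolved toward the smallest k.  Degenerate input where
    every row is identical yields k=1 with a warning.
    """
    n = len(profiles)
    x = profiles.to_numpy()
    if np.all(x == x[0]):
        log.warning("all profiles identical; silhouette undefined, returning k=1")
        return ClusterAssignment(
            k=1,
            labels=pd.Series(1, index=profiles.index, name="cluster"),
            silhouette_by_k={},
            feature_columns=list(profiles.columns),
        )
    lo = max(2, k_min)
    hi = min(k_max, n - 1)
    if hi < lo:
        raise ValueError(f"cluster range [{k_min}, {k_max}] infeasible for n={n}")
    sil: dict[int, float] = {}
    labels_by_k: dict[int, pd.Series] = {}
    for k in range(lo, hi + 1):
        labels = ward_cluster(profiles, k)
        labels_by_k[k] = labels
        sil[k] = float(silhouette_score(x, labels.to_numpy(), metric="euclidean"))
    best = max(sil, key=lambda k: (sil[k], -k))
    return ClusterAssignment(
        k=best,
        labels=labels_by_k[best],
        silhouette_by_k=sil,
        feature_columns=list(profiles.columns),
    )


def cluster_summaries(
    assignment: ClusterAssignment, profiles: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster size, mean profile and distance-from-healthy per condition.

    The distance-from-healthy of a cluster under a condition is the mean
    absolute log2FC of the cluster's genes in that condition (the profile
    distance to an all-zero, i.e. healthy, profile).
    """
    if not assignment.labels.index.equals(profiles.index):
        raise ValueError("assignment and profiles are not aligned")
    zero = pd.Series(0.0, index=profiles.index)
    rows = []
    for cid in sorted(assignment.labels.unique()):
        genes = assignment.labels.index[assignment.labels == cid]
        row: dict[str, object] = {"cluster": int(cid), "size": len(genes)}
        for cond in profiles.columns:
            sub = profiles.loc[genes, cond]
            row[f"mean_{cond}"] = float(sub.mean())
            row[f"dist_wt_{cond}"] = profile_distance(sub, zero.loc[genes])
        rows.append(row)
    return pd.DataFrame(rows)
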