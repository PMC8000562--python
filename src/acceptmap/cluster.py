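"""Acceptability reference partition: HCPC, v-tests and zone labelling.

Evaluations are clustered on the retained three MCA dimensions by Ward
hierarchical clustering (HCPC) followed by a k-means consolidation seeded
from the tree-cut cluster means (single run, hence deterministic).  Each
cluster is then characterized by the observed measures significantly
over-represented within it relative to the whole dataset — the v-test.

For a category j carried by n_j of the N evaluations, of which n_kj fall
in a cluster of size n_k, the null is hypergeometric (drawing n_k of the
N evaluations).  The two-sided tail probability
p = min(1, 2 * min(P(X >= n_kj), P(X <= n_kj))) is mapped through the
normal quantile, v = sign * Phi^{-1}(1 - p/2), signed by the direction of
the deviation (positive when the category is over-represented).  |v| >
1.96 flags a significant enrichment; the whole dataset taken as one
cluster gives v = 0 for every category.

With two clusters, the one whose significant enrichments contain more
positively connoted measures is named "Positively accepted" — the green
zone of the map — and the other "Negatively accepted" (red).  The zone of
an arbitrary map point is that of its nearest consolidated centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom, norm
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .codebook import DEFAULT_CODEBOOK, Codebook

__all__ = [
    "HCPC",
    "CategoryEnrichment",
    "ClusterPartition",
    "assign_zone",
    "enrichment_table",
    "hcpc",
    "label_profiles",
    "vtest",
    "vtest_value",
]

POSITIVE_NAME = "Positively accepted"
NEGATIVE_NAME = "Negatively accepted"
V_THRESHOLD = 1.96


class DegenerateClusterError(ValueError):
    """All points identical, empty cluster, or unlabellable partition."""


@dataclass
class ClusterPartition:
    """Consolidated k-cluster partition of the map.

    ``zone_names``/``profile_names`` are filled by :func:`label_profiles`.
    """

    labels: np.ndarray  # cluster id per evaluation, 0..k-1
    centroids: np.ndarray  # (k, 3) consolidated centroids
    dendrogram_heights: np.ndarray
    profile_names: dict[int, str] = field(default_factory=dict)
    zone_names: dict[int, str] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.centroids)

    @property
    def green_cluster(self) -> int:
        for cid, zone in self.zone_names.items():
            if zone == "green":
                return cid
        raise DegenerateClusterError("partition has not been zone-labelled")


@dataclass(frozen=True)
class CategoryEnrichment:
    cluster: int
    variable: str
    category: str
    n_kj: int
    n_k: int
    n_j: int
    N: int
    v: float
    p: float

    @property
    def significant(self) -> bool:
        return abs(self.v) > V_THRESHOLD


class HCPC(BaseEstimator, ClusterMixin):
    """Ward hierarchy on map coordinates with k-means consolidation.

    Fitted attributes: ``labels_``, ``cluster_centers_``,
    ``dendrogram_heights_``, ``tree_labels_`` (pre-consolidation cut).
    """

    def __init__(self, n_clusters: int = 2):
        self.n_clusters = n_clusters

    def fit(self, X: np.ndarray, y=None) -> "HCPC":
        X = np.asarray(X, dtype=float)
        k = self.n_clusters
        if len(np.unique(X, axis=0)) < k:
            raise DegenerateClusterError(
                f"need at least {k} distinct coordinates to form {k} clusters"
            )
        if k == 1:
            self.labels_ = np.zeros(len(X), dtype=int)
            self.tree_labels_ = self.labels_.copy()
            self.cluster_centers_ = X.mean(axis=0, keepdims=True)
            self.dendrogram_heights_ = np.array([])
            return self
        link = linkage(X, method="ward")
        self.dendrogram_heights_ = link[:, 2]
        tree = fcluster(link, t=k, criterion="maxclust") - 1
        self.tree_labels_ = tree
        seeds = np.vstack([X[tree == c].mean(axis=0) for c in range(k)])
        km = KMeans(n_clusters=k, init=seeds, n_init=1, max_iter=300, algorithm="lloyd")
        km.fit(X)
        self.labels_ = km.labels_
        self.cluster_centers_ = km.cluster_centers_
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d = np.linalg.norm(X[:, None, :] - self.cluster_centers_[None, :, :], axis=2)
        return d.argmin(axis=1)


def hcpc(coordinates: np.ndarray, k: int = 2) -> ClusterPartition:
    """Run HCPC and return a :class:`ClusterPartition` (unlabelled)."""
    model = HCPC(n_clusters=k).fit(coordinates)
    return ClusterPartition(
        labels=model.labels_,
        centroids=model.cluster_centers_,
        dendrogram_heights=model.dendrogram_heights_,
    )


def vtest_value(N, n_j, n_k, n_kj):
    """(v, p) for counts (N, n_j, n_k, n_kj) under the hypergeometric null.

    Two-sided tail p = min(1, 2 min(P(X >= n_kj), P(X <= n_kj))), floored
    at the smallest positive float before taking the normal quantile;
    v is signed by the direction of the deviation.  Accepts scalars or
    broadcastable arrays.
    """
    N, n_j, n_k, n_kj = (np.asarray(a) for a in (N, n_j, n_k, n_kj))
    p_hi = hypergeom.sf(n_kj - 1, N, n_j, n_k)  # P(X >= n_kj)
    p_lo = hypergeom.cdf(n_kj, N, n_j, n_k)  # P(X <= n_kj)
    p = np.minimum(1.0, 2.0 * np.minimum(p_hi, p_lo))
    p = np.maximum(p, np.finfo(float).tiny)
    sign = np.where(n_kj * N >= n_j * n_k, 1.0, -1.0)
    v = sign * norm.isf(p / 2.0)
    if v.ndim == 0:
        return float(v), float(p)
    return v, p


def vtest(
    labels: np.ndarray,
    Z: pd.DataFrame,
    cluster: int,
    column: tuple[str, str],
) -> CategoryEnrichment:
    """v-test of one category's enrichment in one cluster.

    ``Z`` is the hard (0/1) indicator matrix; ``column`` a
    (variable, category) pair.
    """
    labels = np.asarray(labels)
    member = labels == cluster
    n_k = int(member.sum())
    if n_k == 0:
        raise DegenerateClusterError(f"cluster {cluster} is empty")
    z = Z[column].to_numpy(dtype=float)
    N = len(z)
    n_j = int(round(z.sum()))
    n_kj = int(round(z[member].sum()))
    v, p = vtest_value(N, n_j, n_k, n_kj)
    return CategoryEnrichment(
        cluster=int(cluster),
        variable=column[0],
        category=column[1],
        n_kj=n_kj,
        n_k=n_k,
        n_j=n_j,
        N=N,
        v=float(v),
        p=float(p),
    )


def enrichment_table(
    partition: ClusterPartition, Z: pd.DataFrame
) -> pd.DataFrame:
    """All cluster x category v-tests as a tidy DataFrame."""
    rows = []
    for cid in range(partition.k):
        for column in Z.columns:
            e = vtest(partition.labels, Z, cid, tuple(column))
            rows.append(
                {
                    "cluster": cid,
                    "variable": e.variable,
                    "category": e.category,
                    "n_kj": e.n_kj,
                    "n_k": e.n_k,
                    "n_j": e.n_j,
                    "N": e.N,
                    "v": e.v,
                    "p": e.p,
                    "significant": e.significant,
                }
            )
    return pd.DataFrame(rows)


def label_profiles(
    partition: ClusterPartition,
    Z: pd.DataFrame,
    codebook: Codebook | None = None,
) -> ClusterPartition:
    """Name the two clusters and paint the green/red zones.

    The cluster whose significantly over-represented categories include
    more positively connoted measures becomes "Positively accepted"
    (green); ties break toward the cluster with the larger share of
    fully-taken intakes.
    """
    codebook = codebook or DEFAULT_CODEBOOK
    if partition.k != 2:
        raise DegenerateClusterError("profile labelling requires exactly 2 clusters")
    table = enrichment_table(partition, Z)
    if not table["significant"].any():
        raise DegenerateClusterError(
            "neither cluster shows any significant enrichment; "
            "the framework is not meaningful"
        )
    scores = {}
    fully_share = {}
    for cid in range(2):
        sub = table[(table["cluster"] == cid) & table["significant"] & (table["v"] > 0)]
        scores[cid] = sum(
            codebook.is_positive(r["variable"], r["category"]) for _, r in sub.iterrows()
        )
        member = partition.labels == cid
        fully_share[cid] = float(
            Z[("result_intake", "fully")].to_numpy()[member].mean()
        )
    if scores[0] != scores[1]:
        green = max(scores, key=scores.get)
    else:
        green = max(fully_share, key=fully_share.get)
    red = 1 - green
    partition.profile_names = {green: POSITIVE_NAME, red: NEGATIVE_NAME}
    partition.zone_names = {green: "green", red: "red"}
    return partition


def assign_zone(points: np.ndarray, partition: ClusterPartition) -> np.ndarray:
    """Zone ("green"/"red") of each 3D map point by nearest centroid.

    Exact ties break toward green.
    """
    if not partition.zone_names:
        raise DegenerateClusterError("partition has not been zone-labelled")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = np.linalg.norm(pts[:, None, :] - partition.centroids[None, :, :], axis=2)
    green = partition.green_cluster
    nearest = d.argmin(axis=1)
    tie = d[:, green] <= d.min(axis=1)
    nearest[tie] = green
    zones = np.array([partition.zone_names[c] for c in nearest])
    return zones if np.asarray(points).ndim > 1 else zones[0]
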