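"""Automated clustering with silhouette-optimised cluster number.

Features (genes, miRNAs, or consensus peaks) are grouped by the similarity
of their profiles across samples. The number of clusters is not a user
input: every k in a scan range is clustered (k-means or agglomerative) and
the k with the best mean silhouette coefficient wins, ties going to the
smaller k. A 2-D t-SNE embedding and a cluster-ordered heatmap layout are
produced for display only — labels always come from the full-dimensional
data.

The silhouette of point i contrasts cohesion a(i) (mean distance to the
rest of its cluster) with separation b(i) (smallest mean distance to
another cluster): s(i) = (b - a) / max(a, b), with s(i) = 0 for singleton
clusters and for the 0/0 case of coincident points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .consensus_matrix import SignalMatrix
from .errors import ValidationError

logger = logging.getLogger(__name__)

METRICS = ("euclidean", "correlation")
LINKAGES = ("average", "complete", "ward")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances between features."""

    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValidationError(f"distance matrix must be square, got {self.values.shape}")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValidationError("distance matrix diagonal must be exactly 0")
        if np.any(self.values < 0):
            raise ValidationError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusteringResult:
    labels: np.ndarray
    k: int
    algorithm: str
    silhouette_by_k: dict[int, float]
    seed: int
    embedding: np.ndarray | None = None
    heatmap: "HeatmapData | None" = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        used = set(self.labels.tolist())
        if used != set(range(self.k)):
            raise ValidationError(
                f"labels must use every cluster id in [0, {self.k}), got {sorted(used)}"
            )
        best = min(
            (kk for kk, s in self.silhouette_by_k.items()
             if s == max(self.silhouette_by_k.values()))
        )
        if best != self.k:
            raise ValidationError(
                f"selected k={self.k} is not the silhouette argmax ({best})"
            )


@dataclass
class HeatmapData:
    """Cluster-ordered matrix rows for heatmap display."""

    values: np.ndarray
    row_order: np.ndarray
    feature_ids: list[str]
    boundaries: list[int]


# ---------------------------------------------------------------------------
# distances & silhouette
# ---------------------------------------------------------------------------

def pairwise_distances(matrix: SignalMatrix, metric: str = "euclidean") -> DistanceMatrix:
    """Pairwise feature distances over the sample dimensions.

    euclidean is the L2 norm; correlation is 1 - Pearson r. Constant rows
    have no defined correlation: their distance is 0 to identical rows and
    1 to everything else, with a logged warning.
    """
    if metric not in METRICS:
        raise ValidationError(f"metric must be one of {METRICS}, got {metric!r}")
    if matrix.kind not in ("normalized", "neg_log10_q"):
        raise ValidationError(
            f"distances expect a normalized or neg_log10_q matrix, got {matrix.kind}"
        )
    X = matrix.values
    n = X.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 features for pairwise distances")

    if metric == "euclidean":
        D = squareform(pdist(X, metric="euclidean"))
    else:
        D = squareform(pdist(X, metric="correlation"))
        const = np.ptp(X, axis=1) == 0
        if np.any(const):
            logger.warning(
                "%d constant feature row(s): correlation undefined, distance set "
                "to 1 (0 to identical rows)", int(const.sum()),
            )
            for i in np.where(const)[0]:
                same = np.all(X == X[i], axis=1)
                D[i, :] = np.where(same, 0.0, 1.0)
                D[:, i] = D[i, :]
        D = np.clip(D, 0.0, None)  # guard fp noise around r = 1
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return DistanceMatrix(values=D, metric=metric)


def silhouette(labels: np.ndarray, dist: DistanceMatrix) -> tuple[float, np.ndarray]:
    """Mean and per-point silhouette coefficients from a distance matrix.

    a(i) is the mean distance from i to the other members of its cluster
    (excluding itself); b(i) is the smallest mean distance from i to the
    members of any other cluster. Singletons score 0, as does the 0/0 case.
    """
    labels = np.asarray(labels, dtype=int)
    n = dist.n
    if labels.shape != (n,):
        raise ValidationError(f"labels length {labels.shape} != n = {n}")
    ids = np.unique(labels)
    if len(ids) < 2:
        raise ValidationError("silhouette needs at least 2 clusters")
    if set(ids.tolist()) != set(range(len(ids))):
        raise ValidationError(
            f"cluster ids must be 0..k-1 with no empty cluster, got {ids.tolist()}"
        )

    D = dist.values
    k = len(ids)
    sizes = np.bincount(labels, minlength=k)
    # sum of distances from each point to every cluster
    cluster_sums = np.zeros((n, k))
    for c in range(k):
        cluster_sums[:, c] = D[:, labels == c].sum(axis=1)

    own = labels
    a = np.zeros(n)
    nontrivial = sizes[own] > 1
    a[nontrivial] = (
        cluster_sums[np.arange(n), own][nontrivial] / (sizes[own][nontrivial] - 1)
    )

    mean_to = cluster_sums / sizes[np.newaxis, :]
    mean_to[np.arange(n), own] = np.inf
    b = mean_to.min(axis=1)

    denom = np.maximum(a, b)
    s = np.zeros(n)
    ok = denom > 0
    s[ok] = (b[ok] - a[ok]) / denom[ok]
    s[sizes[own] == 1] = 0.0  # singleton convention
    return float(s.mean()), s


# ---------------------------------------------------------------------------
# clustering algorithms
# ---------------------------------------------------------------------------

def cluster_kmeans(
    matrix: SignalMatrix,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
) -> np.ndarray:
    """K-means (Lloyd, k-means++ seeding, best of n_init restarts by WCSS)."""
    n = matrix.shape[0]
    if not 2 <= k <= n - 1:
        raise ValidationError(f"k must satisfy 2 <= k <= n-1 = {n - 1}, got {k}")
    km = KMeans(
        n_clusters=k, n_init=n_init, max_iter=max_iter, random_state=seed,
        init="k-means++", algorithm="lloyd",
    )
    return km.fit_predict(matrix.values)


def cluster_agglomerative(
    dist: DistanceMatrix, k: int, linkage: str = "average"
) -> np.ndarray:
    """Bottom-up hierarchical clustering cut at k clusters.

    Ward linkage assumes squared-euclidean geometry, so it is rejected for
    the correlation metric. Merging is deterministic given the distance
    matrix (scipy breaks ties by the smaller pair index).
    """
    if linkage not in LINKAGES:
        raise ValidationError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    if linkage == "ward" and dist.metric != "euclidean":
        raise ValidationError("ward linkage requires the euclidean metric")
    n = dist.n
    if not 2 <= k <= n:
        raise ValidationError(f"k must satisfy 2 <= k <= n = {n}, got {k}")
    condensed = squareform(dist.values, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # relabel to 0..k-1 in order of first appearance for a stable contract
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap)
        labels[i] = remap[r]
    return labels


def select_k(
    matrix: SignalMatrix,
    algorithm: str = "kmeans",
    k_range: tuple[int, int] | None = None,
    seed: int = 0,
    metric: str = "euclidean",
    linkage: str = "average",
    n_init: int = 10,
    max_iter: int = 300,
) -> ClusteringResult:
    """Cluster at every k in the range and keep the silhouette argmax.

    The default scan range is [2, min(15, n - 1)]. Ties are broken toward
    the smaller k (parsimony). All per-k mean silhouettes are retained in
    the result for plotting the selection curve.
    """
    if algorithm not in ("kmeans", "agglomerative"):
        raise ValidationError(f"unknown algorithm {algorithm!r}")
    n = matrix.shape[0]
    if k_range is None:
        k_range = (2, min(15, n - 1))
    k_min, k_max = k_range
    if not 2 <= k_min <= k_max <= n - 1:
        raise ValidationError(
            f"k_range must satisfy 2 <= k_min <= k_max <= n-1 = {n - 1}, got {k_range}"
        )

    dist = pairwise_distances(matrix, metric=metric)
    silhouette_by_k: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(k_min, k_max + 1):
        if algorithm == "kmeans":
            labels = cluster_kmeans(matrix, k, seed=seed, n_init=n_init, max_iter=max_iter)
        else:
            labels = cluster_agglomerative(dist, k, linkage=linkage)
        # k-means can return fewer distinct clusters than requested on
        # degenerate data; compact the ids so silhouette stays defined
        _, labels = np.unique(labels, return_inverse=True)
        labels_by_k[k] = labels
        mean_s, _ = silhouette(labels, dist)
        silhouette_by_k[k] = mean_s

    best_score = max(silhouette_by_k.values())
    best_k = min(k for k, s in silhouette_by_k.items() if s == best_score)
    labels = labels_by_k[best_k]
    logger.info(
        "selected k=%d (%s, mean silhouette %.4f) over range [%d, %d]",
        best_k, algorithm, best_score, k_min, k_max,
    )
    return ClusteringResult(
        labels=labels,
        k=int(labels.max()) + 1,
        algorithm=algorithm,
        silhouette_by_k=silhouette_by_k,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# visualisation data
# ---------------------------------------------------------------------------

def embed_2d(matrix: SignalMatrix, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """t-SNE 2-D embedding of the features, for display only.

    Deterministic for a fixed seed. Never used for clustering: labels come
    from the full-dimensional data.
    """
    n = matrix.shape[0]
    if perplexity >= n:
        raise ValidationError(f"perplexity must be < n = {n}, got {perplexity}")
    tsne = TSNE(
        n_components=2, random_state=seed, perplexity=perplexity, init="pca",
    )
    return tsne.fit_transform(matrix.values)


def heatmap_data(matrix: SignalMatrix, result: ClusteringResult) -> HeatmapData:
    """Reorder matrix rows for heatmap display.

    Rows are sorted by cluster id, then by within-cluster mean signal
    descending (stable, so equal means preserve input order). Boundaries
    mark the cumulative cluster extents. Values pass through unchanged.
    """
    n = matrix.shape[0]
    if result.labels.shape[0] != n:
        raise ValidationError(
            f"labels length {result.labels.shape[0]} != {n} matrix features"
        )
    means = matrix.values.mean(axis=1)
    order = sorted(range(n), key=lambda i: (result.labels[i], -means[i]))
    order = np.asarray(order, dtype=int)
    sizes = np.bincount(result.labels, minlength=result.k)
    boundaries = np.cumsum(sizes).tolist()
    return HeatmapData(
        values=matrix.values[order],
        row_order=order,
        feature_ids=[matrix.feature_ids[i] for i in order],
        boundaries=boundaries,
    )
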