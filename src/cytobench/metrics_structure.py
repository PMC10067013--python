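"""Global and local structure-preservation metrics.

Global metrics compare the Point-Cluster Distance (PCD) representations
of the original space and the embedding: the N x C matrix of Euclidean
distances from every cell to every original-space cluster centroid. PCD
keeps per-cell granularity while avoiding the O(N^2) memory cost of full
pairwise distances, which is prohibitive at CyTOF sample sizes.

Local metrics compare k-nearest-neighbor sets (k = 100 by default, self
excluded) between the two spaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._types import LabelVector, as_labels, as_matrix

EXACT_NEIGHBOR_LIMIT = 20_000

__all__ = [
    "PointClusterDistance",
    "NeighborSets",
    "cluster_centroids",
    "compute_pcd",
    "minmax_normalize",
    "global_spearman",
    "global_emd",
    "build_neighbors",
    "knn_score",
    "npe",
]


@dataclass
class PointClusterDistance:
    """N x C matrix of cell-to-centroid Euclidean distances."""

    dists: np.ndarray
    cluster_ids: list

    def flatten(self) -> np.ndarray:
        return self.dists.ravel()


@dataclass
class NeighborSets:
    """Per-cell k-nearest-neighbor index sets (self excluded)."""

    k: int
    neighbors: np.ndarray  # (N, k) int array of cell indices

    @property
    def n_cells(self) -> int:
        return self.neighbors.shape[0]


def cluster_centroids(X, labels) -> tuple[np.ndarray, list]:
    """Arithmetic-mean centroid per cluster, clusters in sorted label order."""
    data = as_matrix(X)
    lab = as_labels(labels)
    if len(lab) != len(data):
        raise ValueError("labels length must match row count")
    ids = np.unique(lab)
    cents = np.vstack([data[lab == c].mean(axis=0) for c in ids])
    return cents, list(ids)


def compute_pcd(X, labels=None, centroids=None, cluster_ids=None) -> PointClusterDistance:
    """Euclidean distance from each cell to each cluster centroid.

    Centroids are computed from ``labels`` (original-space clustering)
    unless given explicitly — the latter is how the embedding-space PCD
    reuses original-space cluster memberships.
    """
    data = as_matrix(X)
    if centroids is None:
        if labels is None:
            raise ValueError("need labels or explicit centroids")
        centroids, cluster_ids = cluster_centroids(data, labels)
    centroids = np.asarray(centroids, dtype=float)
    if centroids.shape[1] != data.shape[1]:
        raise ValueError("centroid dimensionality does not match data")
    from scipy.spatial.distance import cdist

    d = cdist(data, centroids, metric="euclidean")
    if cluster_ids is None:
        cluster_ids = list(range(centroids.shape[0]))
    return PointClusterDistance(dists=d, cluster_ids=list(cluster_ids))


def minmax_normalize(v: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1]; a constant vector maps to all zeros."""
    v = np.asarray(v, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def _flat(pcd) -> np.ndarray:
    if isinstance(pcd, PointClusterDistance):
        return pcd.flatten()
    return np.asarray(pcd, dtype=float).ravel()


def global_spearman(pcd_orig, pcd_emb) -> float:
    """Spearman correlation of the flattened PCD vectors (higher better).

    Returns NaN when either vector is constant (correlation undefined).
    """
    a, b = _flat(pcd_orig), _flat(pcd_emb)
    if a.shape != b.shape:
        raise ValueError("PCD shapes differ")
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        return float("nan")
    rho, _ = stats.spearmanr(a, b)
    return float(rho)


def global_emd(pcd_orig, pcd_emb) -> float:
    """1-D Wasserstein distance between min-max-normalized PCD vectors.

    Both flattened vectors are min-max scaled to remove the arbitrary
    scale difference between spaces, then compared as empirical
    distributions (lower is better; 0 iff they coincide).
    """
    a = minmax_normalize(_flat(pcd_orig))
    b = minmax_normalize(_flat(pcd_emb))
    return float(stats.wasserstein_distance(a, b))


def build_neighbors(
    X, k: int = 100, mode: str = "auto", seed: int | None = None
) -> NeighborSets:
    """k nearest neighbors per cell by Euclidean distance, self excluded.

    ``mode="exact"`` uses scikit-learn's tree/brute search (ties broken
    by lowest cell index); ``"approximate"`` uses a random-projection-
    forest index (pynndescent) and trades a little recall for speed at
    large N. ``"auto"`` picks exact below 20,000 cells.
    """
    data = as_matrix(X)
    n = len(data)
    if n < 2:
        raise ValueError("need at least 2 cells")
    k_eff = min(k, n - 1)
    if mode == "auto":
        mode = "exact" if n <= EXACT_NEIGHBOR_LIMIT else "approximate"
    if mode == "exact":
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(data)
        dist, idx = nn.kneighbors(data)
        neigh = np.empty((n, k_eff), dtype=int)
        for i in range(n):
            row = idx[i][idx[i] != i][:k_eff]
            if len(row) < k_eff:  # self not returned (duplicate points)
                row = idx[i][:k_eff]
            neigh[i] = row
    elif mode == "approximate":
        from pynndescent import NNDescent

        index = NNDescent(
            data, n_neighbors=k_eff + 1, random_state=seed, metric="euclidean"
        )
        idx, _ = index.neighbor_graph
        neigh = np.empty((n, k_eff), dtype=int)
        for i in range(n):
            row = idx[i][idx[i] != i][:k_eff]
            if len(row) < k_eff:
                row = idx[i][:k_eff]
            neigh[i] = row
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return NeighborSets(k=k_eff, neighbors=neigh)


def knn_score(nb_orig: NeighborSets, nb_emb: NeighborSets) -> float:
    """Mean fraction of each cell's neighbors preserved across spaces."""
    if nb_orig.n_cells != nb_emb.n_cells or nb_orig.k != nb_emb.k:
        raise ValueError("neighbor sets must share N and k")
    k = nb_orig.k
    overlaps = np.fromiter(
        (
            len(np.intersect1d(nb_orig.neighbors[i], nb_emb.neighbors[i], assume_unique=True))
            for i in range(nb_orig.n_cells)
        ),
        dtype=float,
        count=nb_orig.n_cells,
    )
    return float(overlaps.mean() / k)


def same_cluster_proportions(nb: NeighborSets, labels) -> np.ndarray:
    """Per cell, fraction of its k neighbors sharing the cell's cluster."""
    lab = as_labels(labels)
    counts = (lab[nb.neighbors] == lab[:, None]).sum(axis=1)
    return counts / nb.k


def npe(
    nb_orig: NeighborSets,
    nb_emb: NeighborSets,
    labels,
    grid_size: int = 1024,
) -> float:
    """Neighborhood proportion error (lower is better).

    For every cell, the fraction of its k neighbors belonging to the
    cell's own (original-space) cluster is computed in both spaces. Per
    cluster, Gaussian KDEs (Scott's bandwidth) of the two proportion
    vectors are evaluated on a uniform grid over [0, 1] and the sup of
    the absolute density difference taken; clusters whose proportion
    vector is a point mass in either space cannot be density-estimated
    and are skipped. The per-cluster sups are averaged; NaN when every
    cluster is skipped.
    """
    lab = as_labels(labels)
    if len(lab) != nb_orig.n_cells or nb_orig.n_cells != nb_emb.n_cells:
        raise ValueError("labels and neighbor sets must align")
    p_orig = same_cluster_proportions(nb_orig, lab)
    p_emb = same_cluster_proportions(nb_emb, lab)
    grid = np.linspace(0.0, 1.0, grid_size)
    sups = []
    for c in np.unique(lab):
        mask = lab == c
        a, b = p_orig[mask], p_emb[mask]
        if np.var(a) == 0 or np.var(b) == 0 or mask.sum() < 2:
            continue  # inestimable point mass
        try:
            kde_a = stats.gaussian_kde(a)
            kde_b = stats.gaussian_kde(b)
        except np.linalg.LinAlgError:
            continue
        sups.append(float(np.max(np.abs(kde_a(grid) - kde_b(grid)))))
    if not sups:
        return float("nan")
    return float(np.mean(sups))
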