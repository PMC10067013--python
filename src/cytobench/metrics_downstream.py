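"""Downstream-analysis metrics: clustering quality and partition agreement.

Three sub-families:

* cluster reconstruction — how well the original-space clustering looks
  in the embedding (silhouette, Davies-Bouldin, Calinski-Harabasz, and
  random-forest predictability of the cluster labels from the 2-D
  coordinates);
* cluster concordance — ARI/NMI between original-space and
  embedding-space clusterings;
* cell-type concordance — the same statistics between annotated cell
  types and the embedding-space clustering.
"""

from __future__ import annotations

import numpy as np
from sklearn import metrics as skm

from ._types import LabelVector, as_labels, as_matrix

__all__ = [
    "cluster_embedding",
    "silhouette",
    "davies_bouldin",
    "calinski_harabasz",
    "rf_cluster_prediction",
    "ari",
    "nmi",
    "celltype_clustering_concordance",
]


class _SOM:
    """Minimal rectangular self-organizing map (online training).

    A small stand-in for cytometry-style SOM clustering: a grid of
    codebook vectors is trained with exponentially decaying learning rate
    and Gaussian neighborhood, then meta-clustered.
    """

    def __init__(self, rows: int, cols: int, dim: int, seed: int | None):
        rng = np.random.default_rng(seed)
        self.rows, self.cols = rows, cols
        self.codebook = rng.normal(size=(rows * cols, dim))
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        self.grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        self.rng = rng

    def train(self, X: np.ndarray, epochs: int = 10) -> None:
        n = len(X)
        # init codebook from data range
        lo, hi = X.min(axis=0), X.max(axis=0)
        self.codebook = self.rng.uniform(lo, hi, size=(len(self.codebook), X.shape[1]))
        total = epochs * n
        sigma0 = max(self.rows, self.cols) / 2.0
        step = 0
        for _ in range(epochs):
            for i in self.rng.permutation(n):
                frac = step / total
                lr = 0.5 * np.exp(-3.0 * frac)
                sigma = max(sigma0 * np.exp(-3.0 * frac), 0.5)
                x = X[i]
                bmu = int(np.argmin(((self.codebook - x) ** 2).sum(axis=1)))
                g2 = ((self.grid - self.grid[bmu]) ** 2).sum(axis=1)
                h = np.exp(-g2 / (2 * sigma * sigma))
                self.codebook += (lr * h)[:, None] * (x - self.codebook)
                step += 1

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = ((X[:, None, :] - self.codebook[None, :, :]) ** 2).sum(axis=2)
        return d.argmin(axis=1)


def cluster_embedding(
    E,
    n_clusters_hint: int,
    algorithm: str = "som_meta",
    seed: int | None = None,
    grid_shape: tuple[int, int] = (10, 10),
) -> LabelVector:
    """Cluster a 2-D embedding down to ``n_clusters_hint`` labels.

    ``som_meta`` trains a SOM grid and Ward-meta-clusters the codebook
    vectors down to the hint (the cytometry-standard recipe: over-cluster
    on the grid, then consolidate). ``kmeans`` is the deterministic
    fallback preferred in controlled comparisons.
    """
    data = as_matrix(E)
    n = len(data)
    if n_clusters_hint < 1:
        raise ValueError("n_clusters_hint must be >= 1")
    if n_clusters_hint > n:
        raise ValueError("more clusters requested than cells")
    if algorithm == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=n_clusters_hint, n_init=10, random_state=seed)
        return LabelVector(labels=km.fit_predict(data))
    if algorithm != "som_meta":
        raise ValueError(f"unknown clustering algorithm {algorithm!r}")

    rows, cols = grid_shape
    while rows * cols > max(n_clusters_hint, n // 2) and rows * cols > 4:
        rows, cols = max(rows - 1, 2), max(cols - 1, 2)
    som = _SOM(rows, cols, data.shape[1], seed)
    sub = data
    if n > 20_000:  # SOM codebooks converge long before this
        sub = data[np.random.default_rng(seed).choice(n, 20_000, replace=False)]
    som.train(sub, epochs=5)
    node_of = som.predict(data)

    from sklearn.cluster import AgglomerativeClustering

    used, inv = np.unique(node_of, return_inverse=True)
    k = min(n_clusters_hint, len(used))
    agg = AgglomerativeClustering(n_clusters=k, linkage="ward")
    meta = agg.fit_predict(som.codebook[used])
    return LabelVector(labels=meta[inv])


def _check_clusters(labels: np.ndarray, min_clusters: int = 2) -> None:
    if np.unique(labels).size < min_clusters:
        raise ValueError(f"need at least {min_clusters} clusters")


def silhouette(E, labels) -> float:
    """Mean silhouette coefficient (Euclidean); in [-1, 1], higher better."""
    data, lab = as_matrix(E), as_labels(labels)
    _check_clusters(lab)
    return float(skm.silhouette_score(data, lab, metric="euclidean"))


def davies_bouldin(E, labels) -> float:
    """Davies-Bouldin index; >= 0, lower better (0 for point-mass clusters)."""
    data, lab = as_matrix(E), as_labels(labels)
    _check_clusters(lab)
    return float(skm.davies_bouldin_score(data, lab))


def calinski_harabasz(E, labels) -> float:
    """Calinski-Harabasz variance-ratio index; higher better.

    Returns NaN when within-cluster variance is exactly zero (the ratio
    would be infinite, which would poison rank tables).
    """
    data, lab = as_matrix(E), as_labels(labels)
    _check_clusters(lab)
    if len(data) <= np.unique(lab).size:
        raise ValueError("need more cells than clusters")
    within = sum(
        float(((data[lab == c] - data[lab == c].mean(axis=0)) ** 2).sum())
        for c in np.unique(lab)
    )
    if within == 0.0:
        return float("nan")
    return float(skm.calinski_harabasz_score(data, lab))


def rf_cluster_prediction(
    E, labels, train_fraction: float = 0.67, seed: int | None = None
) -> float:
    """Held-out accuracy of a random forest predicting cluster labels.

    The embedding is split 67%/33% (stratified); a 100-tree forest is
    trained on the first part and scored on the second. High accuracy
    means the original-space clusters remain distinguishable in 2-D.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import train_test_split

    data = as_matrix(E)
    lab = as_labels(labels)
    _, counts = np.unique(lab, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 members for a stratified split")
    X_tr, X_te, y_tr, y_te = train_test_split(
        data, lab, train_size=train_fraction, stratify=lab, random_state=seed
    )
    rf = RandomForestClassifier(n_estimators=100, random_state=seed)
    rf.fit(X_tr, y_tr)
    return float(rf.score(X_te, y_te))


def ari(a, b) -> float:
    """Adjusted Rand index between two labelings (1 iff identical partitions)."""
    la, lb = as_labels(a), as_labels(b)
    if len(la) != len(lb):
        raise ValueError("labelings must have equal length")
    return float(skm.adjusted_rand_score(la, lb))


def nmi(a, b) -> float:
    """Normalized mutual information, arithmetic-mean normalization.

    Mutual information divided by the mean of the two marginal
    entropies; 0 by convention when either labeling is constant
    (a constant partition carries no information).
    """
    la, lb = as_labels(a), as_labels(b)
    if len(la) != len(lb):
        raise ValueError("labelings must have equal length")
    if np.unique(la).size < 2 or np.unique(lb).size < 2:
        return 0.0
    return float(skm.normalized_mutual_info_score(la, lb, average_method="arithmetic"))


def celltype_clustering_concordance(cell_types, emb_clusters) -> dict[str, float]:
    """ARI/NMI between annotated cell types and embedding-space clusters."""
    return {"ari": ari(cell_types, emb_clusters), "nmi": nmi(cell_types, emb_clusters)}
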