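"""Cross-modality concordance between a CyTOF embedding and a matched
scRNA-seq reference.

Absolute distances are meaningless across modalities, so all comparisons
run on *ranks* of distances among the cell types the two datasets share:

* Cluster Distance — per ordered type pair (a, b), the rank of
  d(centroid_a, centroid_b) among a's distances to all other centroids,
  normalized by the number of common types; the metric is the L1
  distance between the two modalities' rank vectors.
* concordance EMD — the fine-grained analogue using every cell: ranks of
  b's cells within the distances from a's centroid to all cells,
  normalized by the modality's cell count, pooled over pairs, compared
  with the 1-D Wasserstein distance.
* gating concordance — ARI/NMI between original-space and
  embedding-space cell typings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from ._types import as_labels, as_matrix
from .metrics_downstream import ari, nmi
from .metrics_structure import cluster_centroids

__all__ = [
    "RankDistanceVector",
    "common_cell_types",
    "rank_distance_centroids",
    "cluster_distance",
    "concordance_emd",
    "gating_concordance",
]


@dataclass
class RankDistanceVector:
    """Normalized centroid-distance ranks per ordered cell-type pair."""

    values: np.ndarray  # length T*(T-1), entries in (0, 1]
    pair_index: list[tuple]  # ordered (a, b) type pairs, a != b


def common_cell_types(types_a, types_b) -> list:
    """Cell types present in both labelings (exact match, sorted)."""
    sa = set(np.unique(as_labels(types_a)).tolist())
    sb = set(np.unique(as_labels(types_b)).tolist())
    return sorted(sa & sb, key=str)


def _stable_ranks(d: np.ndarray) -> np.ndarray:
    """1-based ascending ranks, distance ties broken by lower index."""
    order = np.lexsort((np.arange(len(d)), d))
    ranks = np.empty(len(d), dtype=int)
    ranks[order] = np.arange(1, len(d) + 1)
    return ranks


def rank_distance_centroids(data, cell_types, common_types: list) -> RankDistanceVector:
    """Normalized rank of each centroid pair distance, per vantage point.

    For ordered pair (a, b): among a's distances to every other common
    centroid, the rank of d(a, b) (ascending, 1 = nearest) divided by the
    number of common types T. Not symmetric: the rank from a's vantage
    depends on a's other neighbors.
    """
    if len(common_types) < 2:
        raise ValueError("need at least 2 common cell types")
    X = as_matrix(data)
    lab = as_labels(cell_types)
    cents = {}
    for t in common_types:
        mask = lab == t
        if not mask.any():
            raise ValueError(f"cell type {t!r} absent from data")
        cents[t] = X[mask].mean(axis=0)
    T = len(common_types)
    values, pairs = [], []
    for a in common_types:
        others = [t for t in common_types if t != a]
        d = np.array([np.linalg.norm(cents[a] - cents[t]) for t in others])
        ranks = _stable_ranks(d)
        for t, r in zip(others, ranks):
            pairs.append((a, t))
            values.append(r / T)
    order = np.argsort([f"{a}\x00{b}" for a, b in pairs])
    return RankDistanceVector(
        values=np.asarray(values)[order],
        pair_index=[pairs[i] for i in order],
    )


def cluster_distance(cytof: RankDistanceVector, rna: RankDistanceVector) -> float:
    """L1 distance between the two modalities' rank vectors (lower better)."""
    if cytof.pair_index != rna.pair_index:
        raise ValueError("rank vectors cover different cell-type pairs")
    return float(np.abs(cytof.values - rna.values).sum())


def _pooled_cell_ranks(data, cell_types, common_types: list) -> np.ndarray:
    X = as_matrix(data)
    lab = as_labels(cell_types)
    n = len(X)
    cents = {t: X[lab == t].mean(axis=0) for t in common_types}
    pooled = []
    for a in common_types:
        d = cdist(cents[a][None, :], X)[0]
        ranks = _stable_ranks(d)
        for b in common_types:
            if b == a:
                continue
            pooled.append(ranks[lab == b] / n)
    return np.concatenate(pooled)


def concordance_emd(
    cytof_data, cytof_types, rna_data, rna_types, common_types: list | None = None
) -> float:
    """Wasserstein distance between pooled normalized cell-rank vectors.

    For each ordered common-type pair (a, b) and each modality: distances
    from a's centroid to *all* cells are ranked; the ranks of b's cells,
    divided by the modality's total cell count, enter a pooled vector.
    The two pooled vectors are compared as empirical distributions.
    0 when the modalities have identical rank structure; rank-based, so
    invariant to uniform scaling of either modality.
    """
    if common_types is None:
        common_types = common_cell_types(cytof_types, rna_types)
    if len(common_types) < 2:
        raise ValueError("need at least 2 common cell types")
    x = _pooled_cell_ranks(cytof_data, cytof_types, common_types)
    y = _pooled_cell_ranks(rna_data, rna_types, common_types)
    return float(stats.wasserstein_distance(x, y))


def gating_concordance(orig_space_types, emb_space_types) -> dict[str, float]:
    """ARI/NMI agreement of original- vs embedding-space cell typings."""
    return {
        "ari": ari(orig_space_types, emb_space_types),
        "nmi": nmi(orig_space_types, emb_space_types),
    }
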