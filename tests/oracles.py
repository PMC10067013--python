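"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately written as plain loops over definitions,
kept separate from (and never importing the internals of) the package's
own metric code paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats


def spearman_loop(a, b):
    """Spearman correlation via Pearson on midranks, computed by hand."""

    def midranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    ra, rb = midranks(a), midranks(b)
    ma, mb = sum(ra) / len(ra), sum(rb) / len(rb)
    num = sum((x - ma) * (y - mb) for x, y in zip(ra, rb))
    den = math.sqrt(sum((x - ma) ** 2 for x in ra) * sum((y - mb) ** 2 for y in rb))
    return num / den


def wasserstein_1d_loop(u, v):
    """1-D Wasserstein distance by integrating |F_u - F_v| over knots."""
    pts = sorted(set(u) | set(v))
    u, v = sorted(u), sorted(v)

    def cdf(sample, x):
        return sum(1 for s in sample if s <= x) / len(sample)

    total = 0.0
    for lo, hi in zip(pts[:-1], pts[1:]):
        total += abs(cdf(u, lo) - cdf(v, lo)) * (hi - lo)
    return total


def minmax_loop(v):
    lo, hi = min(v), max(v)
    if hi == lo:
        return [0.0] * len(v)
    return [(x - lo) / (hi - lo) for x in v]


def pcd_loop(X, labels):
    """N x C Euclidean distances to cluster centroids (sorted label order)."""
    X = np.asarray(X, dtype=float)
    ids = sorted(set(labels), key=str)
    cents = []
    for c in ids:
        rows = [X[i] for i in range(len(X)) if labels[i] == c]
        cents.append(np.mean(rows, axis=0))
    out = np.zeros((len(X), len(ids)))
    for i in range(len(X)):
        for j, cent in enumerate(cents):
            out[i, j] = math.sqrt(float(((X[i] - cent) ** 2).sum()))
    return out


def knn_loop(X, k):
    """Exact k-nearest neighbor sets by full pairwise argsort."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    out = []
    for i in range(n):
        d = [(float(((X[i] - X[j]) ** 2).sum()), j) for j in range(n) if j != i]
        d.sort()
        out.append({j for _, j in d[:k]})
    return out


def knn_score_loop(nb_a, nb_b, k):
    return sum(len(a & b) / k for a, b in zip(nb_a, nb_b)) / len(nb_a)


def npe_loop(nb_orig, nb_emb, labels, k, grid_size=1024):
    """NPE per its five printed steps, with scipy's Gaussian KDE."""
    labels = list(labels)
    n = len(labels)
    p_orig = [sum(1 for j in nb_orig[i] if labels[j] == labels[i]) / k for i in range(n)]
    p_emb = [sum(1 for j in nb_emb[i] if labels[j] == labels[i]) / k for i in range(n)]
    grid = np.linspace(0, 1, grid_size)
    sups = []
    for c in sorted(set(labels), key=str):
        a = np.array([p_orig[i] for i in range(n) if labels[i] == c])
        b = np.array([p_emb[i] for i in range(n) if labels[i] == c])
        if len(a) < 2 or np.var(a) == 0 or np.var(b) == 0:
            continue
        pa = stats.gaussian_kde(a)(grid)
        pb = stats.gaussian_kde(b)(grid)
        sups.append(max(abs(x - y) for x, y in zip(pa, pb)))
    return float(np.mean(sups)) if sups else float("nan")


def silhouette_loop(X, labels):
    X = np.asarray(X, dtype=float)
    n = len(X)

    def d(i, j):
        return math.sqrt(float(((X[i] - X[j]) ** 2).sum()))

    vals = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            vals.append(0.0)
            continue
        a = sum(d(i, j) for j in same) / len(same)
        b = math.inf
        for c in set(labels):
            if c == labels[i]:
                continue
            other = [j for j in range(n) if labels[j] == c]
            b = min(b, sum(d(i, j) for j in other) / len(other))
        vals.append((b - a) / max(a, b))
    return sum(vals) / n


def davies_bouldin_loop(X, labels):
    X = np.asarray(X, dtype=float)
    ids = sorted(set(labels), key=str)
    cents, scatters = [], []
    for c in ids:
        rows = np.array([X[i] for i in range(len(X)) if labels[i] == c])
        cent = rows.mean(axis=0)
        cents.append(cent)
        scatters.append(np.mean([np.linalg.norm(r - cent) for r in rows]))
    k = len(ids)
    total = 0.0
    for i in range(k):
        worst = 0.0
        for j in range(k):
            if i == j:
                continue
            m = np.linalg.norm(cents[i] - cents[j])
            worst = max(worst, (scatters[i] + scatters[j]) / m)
        total += worst
    return total / k


def calinski_harabasz_loop(X, labels):
    X = np.asarray(X, dtype=float)
    n, k = len(X), len(set(labels))
    overall = X.mean(axis=0)
    between = within = 0.0
    for c in set(labels):
        rows = np.array([X[i] for i in range(n) if labels[i] == c])
        cent = rows.mean(axis=0)
        between += len(rows) * float(((cent - overall) ** 2).sum())
        within += float(((rows - cent) ** 2).sum())
    return (between / (k - 1)) / (within / (n - k))


def ari_loop(a, b):
    """ARI by counting agreements over all unordered pairs."""
    n = len(a)
    same_a = same_b = same_both = 0
    for i, j in itertools.combinations(range(n), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        same_a += sa
        same_b += sb
        same_both += sa and sb
    total = n * (n - 1) / 2
    expected = same_a * same_b / total
    max_index = (same_a + same_b) / 2
    if max_index == expected:
        return 1.0
    return (same_both - expected) / (max_index - expected)


def nmi_loop(a, b):
    """Plug-in NMI with arithmetic-mean normalization."""
    n = len(a)

    def entropy(lab):
        h = 0.0
        for c in set(lab):
            p = sum(1 for x in lab if x == c) / n
            h -= p * math.log(p)
        return h

    mi = 0.0
    for ca in set(a):
        for cb in set(b):
            pab = sum(1 for i in range(n) if a[i] == ca and b[i] == cb) / n
            if pab == 0:
                continue
            pa = sum(1 for x in a if x == ca) / n
            pb = sum(1 for x in b if x == cb) / n
            mi += pab * math.log(pab / (pa * pb))
    ha, hb = entropy(a), entropy(b)
    if ha == 0 or hb == 0:
        return 0.0
    return mi / ((ha + hb) / 2)


def rank_distance_loop(X, labels, common):
    """Normalized centroid-distance ranks per ordered type pair."""
    X = np.asarray(X, dtype=float)
    cents = {
        t: np.mean([X[i] for i in range(len(X)) if labels[i] == t], axis=0)
        for t in common
    }
    T = len(common)
    out = {}
    for a in common:
        ds = sorted(
            (np.linalg.norm(cents[a] - cents[t]), i, t)
            for i, t in enumerate(common)
            if t != a
        )
        for rank, (_, _, t) in enumerate(ds, start=1):
            out[(a, t)] = rank / T
    return out


def concordance_emd_loop(Xa, la, Xb, lb, common):
    """Pooled normalized cell ranks per modality, then 1-D Wasserstein."""

    def pooled(X, lab):
        X = np.asarray(X, dtype=float)
        n = len(X)
        vals = []
        for a in common:
            cent = np.mean([X[i] for i in range(n) if lab[i] == a], axis=0)
            ds = sorted((np.linalg.norm(cent - X[i]), i) for i in range(n))
            rank_of = {i: r for r, (_, i) in enumerate(ds, start=1)}
            for b in common:
                if b == a:
                    continue
                vals.extend(rank_of[i] / n for i in range(n) if lab[i] == b)
        return vals

    return wasserstein_1d_loop(pooled(Xa, la), pooled(Xb, lb))


def aggregate_loop(methods, specs, values):
    """Spreadsheet-style recomputation of the hierarchical rank averages.

    specs: list of (name, direction, major, sub-or-None); values: 2-D list
    (methods x metrics) with None for failures. Returns dict with metric
    ranks, major scores and overall per method.
    """
    K = len(methods)
    n_metrics = len(specs)
    ranks = [[0.0] * n_metrics for _ in range(K)]
    for j, (_, direction, _, _) in enumerate(specs):
        col = [values[i][j] for i in range(K)]
        oriented = [
            None if v is None else (v if direction == "higher_better" else -v)
            for v in col
        ]
        n_na = sum(1 for v in oriented if v is None)
        for i in range(K):
            if oriented[i] is None:
                ranks[i][j] = n_na
            else:
                ranks[i][j] = n_na + sum(
                    1 for v in oriented if v is not None and v <= oriented[i]
                )
    majors = {}
    for j, (_, _, major, sub) in enumerate(specs):
        majors.setdefault(major, {}).setdefault(sub, []).append(j)
    out = {"ranks": ranks, "major": {}, "overall": [0.0] * K}
    for i in range(K):
        major_scores = []
        for major, subs in majors.items():
            sub_means = []
            for _, cols in subs.items():
                sub_means.append(sum(ranks[i][j] for j in cols) / len(cols))
            s = sum(sub_means) / len(sub_means)
            out["major"].setdefault(major, [0.0] * K)[i] = s
            major_scores.append(s)
        out["overall"][i] = sum(major_scores) / len(major_scores)
    return out
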