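"""Hierarchical equal-weight rank aggregation and complementarity.

Raw metric values are converted to ranks per metric (higher rank =
better; ties take the maximum rank of their block; methods that failed a
metric are ranked last, tied among themselves). Ranks are then averaged
with equal weights up a two-level hierarchy: metrics within a
sub-category, sub-categories within a major category (major categories
without sub-categories average their metrics directly), and finally the
available major categories into one overall accuracy score.

Complementarity asks how likely a small set of methods is to contain the
top performer for a dataset: a greedy sweep adds, at each step, the
method covering the most additional datasets' top spots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MetricSpec",
    "ScoreTable",
    "RankTable",
    "rank_metric",
    "aggregate_scores",
    "complementarity",
    "DEFAULT_TREE",
]

HIGHER = "higher_better"
LOWER = "lower_better"


@dataclass(frozen=True)
class MetricSpec:
    """A metric's name, orientation, and place in the category tree."""

    name: str
    direction: str  # higher_better | lower_better
    major: str
    sub: str | None = None

    def __post_init__(self):
        if self.direction not in (HIGHER, LOWER):
            raise ValueError(f"bad direction {self.direction!r}")


# The framework's default accuracy hierarchy. Global and Local have no
# sub-categories; Downstream and scRNA-seq concordance do.
DEFAULT_TREE: list[MetricSpec] = [
    MetricSpec("cor", HIGHER, "global"),
    MetricSpec("emd", LOWER, "global"),
    MetricSpec("knn", HIGHER, "local"),
    MetricSpec("npe", LOWER, "local"),
    MetricSpec("silhouette", HIGHER, "downstream", "cluster_reconstruction"),
    MetricSpec("dbi", LOWER, "downstream", "cluster_reconstruction"),
    MetricSpec("chi", HIGHER, "downstream", "cluster_reconstruction"),
    MetricSpec("rf", HIGHER, "downstream", "cluster_reconstruction"),
    MetricSpec("cc_ari", HIGHER, "downstream", "cluster_concordance"),
    MetricSpec("cc_nmi", HIGHER, "downstream", "cluster_concordance"),
    MetricSpec("ct_ari", HIGHER, "downstream", "celltype_concordance"),
    MetricSpec("ct_nmi", HIGHER, "downstream", "celltype_concordance"),
    MetricSpec("cluster_distance", LOWER, "scrna", "cluster_distance"),
    MetricSpec("concordance_emd", LOWER, "scrna", "emd"),
    MetricSpec("gating_ari", HIGHER, "scrna", "gating"),
    MetricSpec("gating_nmi", HIGHER, "scrna", "gating"),
]


@dataclass
class ScoreTable:
    """Raw methods x metrics values; NaN marks a failed metric."""

    methods: list[str]
    metrics: list[MetricSpec]
    values: np.ndarray  # methods x metrics, NaN = failure

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.methods), len(self.metrics)):
            raise ValueError("values shape must be methods x metrics")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.methods, columns=[m.name for m in self.metrics]
        )


@dataclass
class RankTable:
    """Per-metric ranks plus category and overall scores (higher = better)."""

    methods: list[str]
    metric_ranks: pd.DataFrame
    sub_scores: pd.DataFrame
    major_scores: pd.DataFrame
    overall: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = self.metric_ranks.copy()
        for c in self.sub_scores.columns:
            out[f"sub:{c}"] = self.sub_scores[c]
        for c in self.major_scores.columns:
            out[f"major:{c}"] = self.major_scores[c]
        out["overall"] = self.overall
        return out


def rank_metric(values, direction: str = HIGHER) -> np.ndarray:
    """Rank one metric's values over K methods, best = K.

    Values are oriented so larger is better, then ranked ascending with
    maximum-rank tie handling. NaNs (failures) sit below every finite
    value, tied among themselves: with the maximum-rank convention each
    receives rank = (number of NaNs).
    """
    v = np.asarray(values, dtype=float)
    if direction == LOWER:
        v = -v
    elif direction != HIGHER:
        raise ValueError(f"bad direction {direction!r}")
    ranks = np.empty(len(v), dtype=float)
    na = np.isnan(v)
    n_na = int(na.sum())
    ranks[na] = n_na if n_na else 0
    if (~na).any():
        from scipy.stats import rankdata

        ranks[~na] = rankdata(v[~na], method="max") + n_na
    return ranks


def aggregate_scores(table: ScoreTable) -> RankTable:
    """Rank every metric, then average equally up the category tree."""
    if not table.metrics:
        raise ValueError("empty score table")
    names = [m.name for m in table.metrics]
    ranks = pd.DataFrame(index=table.methods, columns=names, dtype=float)
    for j, spec in enumerate(table.metrics):
        ranks[spec.name] = rank_metric(table.values[:, j], spec.direction)

    majors: dict[str, dict[str | None, list[str]]] = {}
    for spec in table.metrics:
        majors.setdefault(spec.major, {}).setdefault(spec.sub, []).append(spec.name)

    sub_scores = {}
    major_scores = {}
    for major, subs in majors.items():
        parts = []
        for sub, members in subs.items():
            mean = ranks[members].mean(axis=1)
            if sub is not None:
                sub_scores[f"{major}/{sub}"] = mean
            parts.append(mean)
        major_scores[major] = pd.concat(parts, axis=1).mean(axis=1)

    sub_df = pd.DataFrame(sub_scores, index=table.methods)
    major_df = pd.DataFrame(major_scores, index=table.methods)
    overall = major_df.mean(axis=1)
    return RankTable(
        methods=list(table.methods),
        metric_ranks=ranks,
        sub_scores=sub_df,
        major_scores=major_df,
        overall=overall,
    )


def complementarity(
    top_method_per_dataset: list[str], candidate_methods: list[str] | None = None
) -> list[tuple[str, float]]:
    """Greedy coverage curve of top-performing methods across datasets.

    At each step the unchosen method adding the most datasets whose top
    performer would then be covered is appended (ties broken
    lexicographically by method name); the cumulative covered fraction is
    reported. The first entry is the method most often on top. Methods
    adding nothing are appended with unchanged coverage, in name order.
    """
    tops = list(top_method_per_dataset)
    if not tops:
        raise ValueError("need at least one dataset")
    d = len(tops)
    if candidate_methods is None:
        candidate_methods = sorted(set(tops))
    remaining = sorted(set(candidate_methods))
    covered: set[int] = set()
    curve: list[tuple[str, float]] = []
    while remaining:
        gains = {
            m: sum(1 for i, t in enumerate(tops) if t == m and i not in covered)
            for m in remaining
        }
        # lexicographic tie-break: among max-gain methods pick smallest name
        max_gain = max(gains.values())
        best = min(m for m in remaining if gains[m] == max_gain)
        covered.update(i for i, t in enumerate(tops) if t == best)
        curve.append((best, len(covered) / d))
        remaining.remove(best)
    return curve
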