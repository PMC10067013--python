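"""Rank aggregation: tie rules, NA handling, hierarchy, complementarity."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytobench import MetricSpec, ScoreTable, aggregate_scores, complementarity, rank_metric

import oracles

NA = np.nan


class TestRankMetric:
    def test_max_rank_ties(self):
        np.testing.assert_array_equal(
            rank_metric([0.3, 0.5, 0.5], "higher_better"), [1, 3, 3]
        )

    def test_lower_better_orientation(self):
        np.testing.assert_array_equal(
            rank_metric([0.1, 0.2, 0.3], "lower_better"), [3, 2, 1]
        )

    def test_na_ranked_last(self):
        np.testing.assert_array_equal(
            rank_metric([0.9, NA, 0.1], "higher_better"), [3, 1, 2]
        )

    def test_multiple_nas_tie_at_bottom(self):
        np.testing.assert_array_equal(
            rank_metric([NA, 0.7, NA, 0.2], "higher_better"), [2, 4, 2, 3]
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(-100, 100, allow_nan=False).map(lambda x: round(x, 3)),
            min_size=1,
            max_size=12,
        )
    )
    def test_rank_sum_without_ties(self, values):
        k = len(values)
        if len(set(values)) != k:
            return  # property applies to tie-free vectors
        ranks = rank_metric(values, "higher_better")
        assert ranks.sum() == k * (k + 1) / 2


def toy_specs():
    return [
        MetricSpec("cor", "higher_better", "global"),
        MetricSpec("emd", "lower_better", "global"),
        MetricSpec("knn", "higher_better", "local"),
        MetricSpec("npe", "lower_better", "local"),
        MetricSpec("sil", "higher_better", "downstream", "reco"),
        MetricSpec("dbi", "lower_better", "downstream", "reco"),
        MetricSpec("chi", "higher_better", "downstream", "reco"),
        MetricSpec("rf", "higher_better", "downstream", "reco"),
        MetricSpec("cc_ari", "higher_better", "downstream", "cc"),
        MetricSpec("cc_nmi", "higher_better", "downstream", "cc"),
        MetricSpec("ct_ari", "higher_better", "downstream", "ct"),
        MetricSpec("ct_nmi", "higher_better", "downstream", "ct"),
    ]


class TestAggregateScores:
    def test_single_metric_degenerate(self):
        t = ScoreTable(
            methods=["a", "b"],
            metrics=[MetricSpec("cor", "higher_better", "global")],
            values=np.array([[0.2], [0.9]]),
        )
        r = aggregate_scores(t)
        np.testing.assert_array_equal(r.overall.to_numpy(), [1.0, 2.0])

    def test_category_mean(self):
        t = ScoreTable(
            methods=["a", "b"],
            metrics=[
                MetricSpec("cor", "higher_better", "global"),
                MetricSpec("emd", "lower_better", "global"),
            ],
            # ranks become (2,1) and (1,2) -> global scores (1.5, 1.5)
            values=np.array([[0.9, 0.9], [0.1, 0.1]]),
        )
        r = aggregate_scores(t)
        np.testing.assert_allclose(r.major_scores["global"].to_numpy(), [1.5, 1.5])

    def test_hand_table_matches_spreadsheet_recompute(self, rng):
        specs = toy_specs()
        values = rng.random((5, 12))
        values[1, 3] = NA
        values[4, 0] = NA
        values[4, 7] = NA
        t = ScoreTable(
            methods=list("abcde"), metrics=specs, values=values.copy()
        )
        r = aggregate_scores(t)
        vals_list = [
            [None if np.isnan(v) else float(v) for v in row] for row in values
        ]
        spec_tuples = [(s.name, s.direction, s.major, s.sub) for s in specs]
        expected = oracles.aggregate_loop(list("abcde"), spec_tuples, vals_list)
        np.testing.assert_allclose(r.overall.to_numpy(), expected["overall"], atol=1e-12)
        for major in ("global", "local", "downstream"):
            np.testing.assert_allclose(
                r.major_scores[major].to_numpy(), expected["major"][major], atol=1e-12
            )
        np.testing.assert_allclose(
            r.metric_ranks.to_numpy(), np.array(expected["ranks"], dtype=float)
        )

    def test_metric_order_invariance(self, rng):
        specs = toy_specs()
        values = rng.random((4, 12))
        t1 = ScoreTable(methods=list("wxyz"), metrics=specs, values=values)
        perm = rng.permutation(12)
        t2 = ScoreTable(
            methods=list("wxyz"),
            metrics=[specs[i] for i in perm],
            values=values[:, perm],
        )
        np.testing.assert_allclose(
            aggregate_scores(t1).overall.to_numpy(),
            aggregate_scores(t2).overall.to_numpy(),
            atol=1e-12,
        )

    def test_all_na_method_is_minimum(self, rng):
        specs = toy_specs()
        values = rng.random((3, 12))
        values[2, :] = NA
        r = aggregate_scores(ScoreTable(methods=list("abc"), metrics=specs, values=values))
        assert r.overall["c"] == r.overall.min()
        assert r.overall["c"] == 1.0  # single NA per metric -> rank 1 everywhere


class TestComplementarity:
    def test_worked_example(self):
        curve = complementarity(["M1", "M1", "M2", "M3"])
        assert curve[0] == ("M1", 0.5)
        assert curve[1] == ("M2", 0.75)  # M2/M3 tie broken lexicographically
        assert curve[2] == ("M3", 1.0)

    def test_single_dominant_method(self):
        curve = complementarity(["M1", "M1", "M1"])
        assert curve == [("M1", 1.0)]

    def test_coverage_non_decreasing(self, rng):
        tops = [f"M{i}" for i in rng.integers(0, 6, 30)]
        curve = complementarity(tops)
        covs = [c for _, c in curve]
        assert covs == sorted(covs)
        assert covs[-1] == pytest.approx(1.0)

    def test_greedy_matches_exhaustive_on_toy(self):
        tops = ["A", "B", "B", "C"]
        methods = sorted(set(tops))
        curve = complementarity(tops, methods)
        # exhaustive: for every prefix length, greedy coverage must equal
        # the best coverage achievable by any same-size subset
        d = len(tops)
        for step in range(1, len(methods) + 1):
            best = max(
                sum(1 for t in tops if t in subset) / d
                for subset in itertools.combinations(methods, step)
            )
            assert curve[step - 1][1] == pytest.approx(best)

    def test_first_step_dominates_any_single_method(self):
        tops = ["A", "B", "B", "C", "B", "A"]
        curve = complementarity(tops)
        for m in set(tops):
            single = sum(1 for t in tops if t == m) / len(tops)
            assert curve[0][1] >= single
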