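"""Monte Carlo propagation and quantile summaries."""

import numpy as np
import pandas as pd
import pytest

from aquaval import (
    AggregationSpec,
    AttributeSampleSet,
    Cell,
    InvalidInputError,
    ObjectiveNode,
    evaluate_hierarchy,
    grab_sample,
    grab_statistic,
    make_value_function,
    propagate,
    summarize,
)

CELL = Cell("outlet", "CurrPrac", "status_quo", "present")


def two_leaf_min_tree():
    vf_a = make_value_function("a", (1, 2, 3, 4), 8)
    vf_b = make_value_function("b", (1, 2, 3, 4), 8)
    root = ObjectiveNode(
        id="root",
        children=[
            ObjectiveNode(id="la", value_function=vf_a),
            ObjectiveNode(id="lb", value_function=vf_b),
        ],
        weights=[0.5, 0.5],
        aggregation=AggregationSpec("minimum"),
    )
    root.validate()
    return root


class TestSummarize:
    def test_linear_interpolation_median(self):
        sample = np.arange(0.1, 1.01, 0.1)  # 0.1 ... 1.0
        assert summarize(sample, [0.5])[0] == pytest.approx(0.55)

    def test_single_value_sample(self):
        out = summarize([0.37], [0.0, 0.05, 0.5, 0.95, 1.0])
        np.testing.assert_allclose(out, 0.37)

    def test_uniform_draws_recover_probs(self, rng):
        draws = rng.uniform(0, 1, size=1000)
        out = summarize(draws, [0.05, 0.5, 0.95])
        np.testing.assert_allclose(out, [0.05, 0.5, 0.95], atol=0.03)

    def test_matches_sort_and_interpolate_oracle(self, rng):
        draws = rng.normal(size=101)
        s = np.sort(draws)
        for p in (0.05, 0.5, 0.95, 0.123):
            h = p * (len(s) - 1)
            lo, frac = int(np.floor(h)), h - np.floor(h)
            expected = s[lo] + frac * (s[min(lo + 1, len(s) - 1)] - s[lo])
            assert summarize(draws, [p])[0] == pytest.approx(expected, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            summarize([], [0.5])

    def test_bad_probs_rejected(self):
        with pytest.raises(InvalidInputError):
            summarize([1.0], [1.5])


class TestPropagate:
    def test_single_draw_summaries_collapse(self):
        tree = two_leaf_min_tree()
        ss = AttributeSampleSet(CELL, {"a": [2.0], "b": [1.0]})
        res = propagate(tree, ss)
        s = res.summary("root")
        assert s.q05 == s.median == s.q95
        assert s.median == pytest.approx(
            evaluate_hierarchy(tree, {"a": 2.0, "b": 1.0})["root"]
        )

    def test_constant_draws_have_degenerate_interval(self):
        tree = two_leaf_min_tree()
        ss = AttributeSampleSet(CELL, {"a": [2.0] * 20, "b": [3.0] * 20})
        s = propagate(tree, ss).summary("root")
        assert s.q05 == s.median == s.q95

    def test_anticorrelated_leaves_show_why_summaries_must_not_aggregate(self):
        """Min of anti-correlated leaves: root median < min of leaf medians."""
        n = 400
        # leaf a bad exactly when leaf b is good and vice versa
        a_levels = np.concatenate([np.full(n // 2, 1.0), np.full(n // 2, 4.0)])
        b_levels = np.concatenate([np.full(n // 2, 4.0), np.full(n // 2, 1.0)])
        tree = two_leaf_min_tree()
        ss = AttributeSampleSet(CELL, {"a": a_levels, "b": b_levels})
        res = propagate(tree, ss)
        leaf_medians = min(res.median("la"), res.median("lb"))
        assert res.median("root") < leaf_medians
        # exact agreement with a per-draw loop oracle
        looped = np.array(
            [
                evaluate_hierarchy(tree, {"a": a_levels[i], "b": b_levels[i]})["root"]
                for i in range(n)
            ]
        )
        np.testing.assert_allclose(np.sort(res.samples["root"]), np.sort(looped), atol=1e-12)
        np.testing.assert_allclose(res.samples["root"], looped, atol=1e-12)

    def test_permutation_invariance_of_summaries(self, rng):
        tree = two_leaf_min_tree()
        a = rng.uniform(0, 8, 100)
        b = rng.uniform(0, 8, 100)
        perm = rng.permutation(100)
        s1 = propagate(tree, AttributeSampleSet(CELL, {"a": a, "b": b})).summary("root")
        s2 = propagate(tree, AttributeSampleSet(CELL, {"a": a[perm], "b": b[perm]})).summary("root")
        assert (s1.q05, s1.median, s1.q95) == (s2.q05, s2.median, s2.q95)

    def test_summaries_ordered_and_bounded(self, rng):
        tree = two_leaf_min_tree()
        ss = AttributeSampleSet(CELL, {"a": rng.uniform(0, 10, 200), "b": rng.uniform(0, 10, 200)})
        res = propagate(tree, ss)
        for node in res.samples:
            s = res.summary(node)
            assert 0.0 <= s.q05 <= s.median <= s.q95 <= 1.0

    def test_more_pollution_never_raises_medians(self, rng):
        tree = two_leaf_min_tree()
        a = rng.uniform(0, 4, 200)
        b = rng.uniform(0, 4, 200)
        res0 = propagate(tree, AttributeSampleSet(CELL, {"a": a, "b": b}))
        res1 = propagate(tree, AttributeSampleSet(CELL, {"a": a * 1.5, "b": b * 1.5}))
        for node in res0.samples:
            assert res1.median(node) <= res0.median(node) + 1e-12

    def test_inconsistent_draw_lengths_rejected(self):
        with pytest.raises(InvalidInputError):
            AttributeSampleSet(CELL, {"a": [1.0, 2.0], "b": [1.0]})


class TestGrabSampling:
    @pytest.fixture
    def series(self):
        idx = pd.date_range("2020-01-01", periods=30, freq="D")
        return pd.Series(np.linspace(1.0, 30.0, 30), index=idx)

    def test_full_schedule_returns_full_series(self, series):
        out = grab_sample(series, list(series.index))
        pd.testing.assert_series_equal(out, series, check_freq=False)

    def test_subset_schedule_matches_direct_indexing(self, series):
        schedule = series.index[::7]
        out = grab_sample(series, schedule)
        np.testing.assert_allclose(out.to_numpy(), series.iloc[::7].to_numpy())

    def test_empty_schedule_rejected(self, series):
        with pytest.raises(InvalidInputError):
            grab_sample(series, [])

    def test_out_of_range_date_rejected(self, series):
        with pytest.raises(InvalidInputError, match="outside"):
            grab_sample(series, [pd.Timestamp("2021-06-01")])

    def test_default_statistic_is_90th_percentile(self, series):
        got = grab_statistic(series.to_numpy())
        assert got == pytest.approx(np.percentile(series.to_numpy(), 90))

    def test_statistic_percentile_configurable(self, series):
        assert grab_statistic(series.to_numpy(), 50) == pytest.approx(series.median())
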