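"""Aggregation operators and bottom-up hierarchy evaluation."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aquaval import (
    AggregationSpec,
    InvalidConfigError,
    InvalidInputError,
    MissingDataError,
    ObjectiveNode,
    aggregate,
    evaluate_hierarchy,
    make_value_function,
)
from conftest import build_three_leaf_tree


def straight_line_formula(values, weights, method, alpha=0.5, delta=0.1):
    """Direct transcription of the four formulas (the oracle)."""
    v_min = min(values)
    v_add = sum(w * v for w, v in zip(weights, values))
    if method == "minimum":
        return v_min
    if method == "additive":
        return v_add
    if method == "additive_minimum":
        return alpha * v_add + (1 - alpha) * v_min
    prod = 1.0
    for w, v in zip(weights, values):
        prod *= (v + delta) ** w
    return prod - delta


class TestAggregateWorkedExample:
    """One sub-objective at 0, the other at 1, equal weights."""

    def test_minimum(self):
        assert aggregate([0, 1], [0.5, 0.5], AggregationSpec("minimum")) == 0.0

    def test_additive(self):
        assert aggregate([0, 1], [0.5, 0.5], AggregationSpec("additive")) == 0.5

    def test_additive_minimum(self):
        spec = AggregationSpec("additive_minimum", alpha=0.5)
        assert aggregate([0, 1], [0.5, 0.5], spec) == 0.25

    def test_geometric_offset(self):
        spec = AggregationSpec("geometric_offset", delta=0.1)
        out = aggregate([0, 1], [0.5, 0.5], spec)
        assert out == pytest.approx(math.sqrt(0.11) - 0.1, abs=1e-12)
        assert out == pytest.approx(0.23, abs=0.005)


METHODS = [
    ("minimum", {}),
    ("additive", {}),
    ("additive_minimum", {"alpha": 0.5}),
    ("geometric_offset", {"delta": 0.1}),
]


class TestAggregate:
    @pytest.mark.parametrize("method,kwargs", METHODS)
    def test_matches_straight_line_oracle(self, method, kwargs):
        values, weights = [0.0, 0.7, 1.0], [0.2, 0.5, 0.3]
        got = aggregate(values, weights, AggregationSpec(method, **kwargs))
        assert got == pytest.approx(
            straight_line_formula(values, weights, method, **kwargs), abs=1e-12
        )

    @pytest.mark.parametrize("method,kwargs", METHODS)
    @pytest.mark.parametrize("v", [0.0, 0.37, 1.0])
    def test_idempotence(self, method, kwargs, v):
        got = aggregate([v, v, v], [0.5, 0.3, 0.2], AggregationSpec(method, **kwargs))
        assert got == pytest.approx(v, abs=1e-12)

    @pytest.mark.parametrize("method,kwargs", METHODS)
    def test_single_child_returns_value(self, method, kwargs):
        assert aggregate([0.42], [1.0], AggregationSpec(method, **kwargs)) == pytest.approx(0.42)

    def test_geometric_mean_zero_annihilates(self):
        spec = AggregationSpec("geometric_offset", delta=0.0)
        assert aggregate([0.0, 0.9], [0.5, 0.5], spec) == 0.0

    def test_zero_weight_child_ignored_in_geometric(self):
        spec = AggregationSpec("geometric_offset", delta=0.0)
        assert aggregate([0.0, 0.9], [0.0, 1.0], spec) == pytest.approx(0.9)

    def test_draw_wise_aggregation_matches_loop(self, rng):
        values = rng.uniform(0, 1, size=(3, 50))
        weights = [0.2, 0.5, 0.3]
        for method, kwargs in METHODS:
            spec = AggregationSpec(method, **kwargs)
            out = aggregate(values, weights, spec)
            looped = [aggregate(values[:, j], weights, spec) for j in range(50)]
            np.testing.assert_allclose(out, looped, atol=1e-12)

    def test_bad_weights_rejected(self):
        with pytest.raises(InvalidConfigError):
            aggregate([0.5, 0.5], [0.6, 0.3], AggregationSpec("additive"))

    def test_out_of_range_values_rejected(self):
        with pytest.raises(InvalidInputError):
            aggregate([0.5, 1.4], [0.5, 0.5], AggregationSpec("additive"))

    @pytest.mark.parametrize(
        "method,alpha,delta", [("nope", 0.5, 0.1), ("additive_minimum", 1.2, 0.1), ("geometric_offset", 0.5, -0.1)]
    )
    def test_invalid_spec_rejected(self, method, alpha, delta):
        with pytest.raises(InvalidConfigError):
            AggregationSpec(method, alpha=alpha, delta=delta)


values_strategy = st.lists(st.floats(0, 1), min_size=2, max_size=6)


@settings(deadline=None, max_examples=200)
@given(values=values_strategy, alpha=st.floats(0, 1), delta=st.floats(0, 10), seed=st.integers(0, 2**16))
def test_operator_invariants(values, alpha, delta, seed):
    """Boundedness, ordering v_min <= v_add-min <= v_add, and AM-GM."""
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.ones(len(values)))
    v_min = aggregate(values, w, AggregationSpec("minimum"))
    v_add = aggregate(values, w, AggregationSpec("additive"))
    v_am = aggregate(values, w, AggregationSpec("additive_minimum", alpha=alpha))
    v_go = aggregate(values, w, AggregationSpec("geometric_offset", delta=delta))
    for v in (v_min, v_add, v_am, v_go):
        assert 0.0 <= v <= 1.0
    assert v_min - 1e-12 <= v_am <= v_add + 1e-12
    assert v_go <= v_add + 1e-9  # AM-GM (shift-invariant)


@settings(deadline=None, max_examples=100)
@given(values=values_strategy, seed=st.integers(0, 2**16))
def test_alpha_and_delta_limits(values, seed):
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.ones(len(values)))
    v_min = aggregate(values, w, AggregationSpec("minimum"))
    v_add = aggregate(values, w, AggregationSpec("additive"))
    assert aggregate(values, w, AggregationSpec("additive_minimum", alpha=1.0)) == pytest.approx(v_add, abs=1e-12)
    assert aggregate(values, w, AggregationSpec("additive_minimum", alpha=0.0)) == pytest.approx(v_min, abs=1e-12)
    # delta -> infinity tends to the weighted arithmetic mean
    v_inf = aggregate(values, w, AggregationSpec("geometric_offset", delta=1e6))
    assert v_inf == pytest.approx(v_add, abs=1e-4)
    # delta = 0 is the weighted geometric mean
    v_gm = aggregate(values, w, AggregationSpec("geometric_offset", delta=0.0))
    expected = 0.0 if any(v == 0 and wi > 0 for v, wi in zip(values, w)) else float(
        np.exp(np.sum(w[np.asarray(values) > 0] * np.log(np.asarray(values)[np.asarray(values) > 0])))
        if all(v > 0 for v in values) else 0.0
    )
    if all(v > 0 for v in values):
        assert v_gm == pytest.approx(expected, rel=1e-9)


@settings(deadline=None, max_examples=100)
@given(
    values=st.lists(st.floats(0, 0.99), min_size=2, max_size=5),
    idx=st.integers(0, 4),
    bump=st.floats(0.001, 1.0),
)
def test_weak_monotonicity_in_every_component(values, idx, bump):
    idx = idx % len(values)
    improved = list(values)
    improved[idx] = min(1.0, improved[idx] + bump)
    w = np.ones(len(values)) / len(values)
    for method, kwargs in METHODS:
        spec = AggregationSpec(method, **kwargs)
        assert aggregate(improved, w, spec) >= aggregate(values, w, spec) - 1e-12


class TestEvaluateHierarchy:
    def test_unpolluted_catchment_scores_one_everywhere(self, three_leaf_tree):
        out = evaluate_hierarchy(three_leaf_tree, {"a": 0.0, "b": 0.0, "c": 0.0})
        assert set(out) == {"root", "pair", "leaf_a", "leaf_b", "leaf_c"}
        for v in out.values():
            assert v == pytest.approx(1.0)

    @pytest.mark.parametrize("method,kwargs", METHODS)
    def test_matches_hand_chained_aggregation(self, rng, method, kwargs):
        tree = build_three_leaf_tree(method, **kwargs)
        spec = AggregationSpec(method, **kwargs)
        for _ in range(10):
            levels = {k: float(rng.uniform(0, 12)) for k in ("a", "b", "c")}
            out = evaluate_hierarchy(tree, levels)
            v_pair = aggregate([out["leaf_a"], out["leaf_b"]], [0.6, 0.4], spec)
            v_root = aggregate([v_pair, out["leaf_c"]], [0.7, 0.3], spec)
            assert out["pair"] == pytest.approx(v_pair, abs=1e-12)
            assert out["root"] == pytest.approx(v_root, abs=1e-12)

    def test_partial_compensation_brackets_root(self):
        """One branch ruined, the rest perfect: root between min and additive."""
        tree = build_three_leaf_tree("additive_minimum", alpha=0.5)
        out = evaluate_hierarchy(tree, {"a": 0.0, "b": 0.0, "c": 16.0})
        tree_min = build_three_leaf_tree("minimum")
        tree_add = build_three_leaf_tree("additive")
        lo = evaluate_hierarchy(tree_min, {"a": 0.0, "b": 0.0, "c": 16.0})["root"]
        hi = evaluate_hierarchy(tree_add, {"a": 0.0, "b": 0.0, "c": 16.0})["root"]
        assert lo < out["root"] < hi

    def test_unknown_attribute_warns(self, three_leaf_tree):
        with pytest.warns(UserWarning, match="without a bound leaf"):
            evaluate_hierarchy(three_leaf_tree, {"a": 1, "b": 1, "c": 1, "zz": 5})

    def test_missing_leaf_renormalizes_with_warning(self, three_leaf_tree):
        with pytest.warns(UserWarning, match="renormalized"):
            out = evaluate_hierarchy(three_leaf_tree, {"a": 1.0, "c": 2.0})
        # pair collapses to leaf_a alone
        assert out["pair"] == pytest.approx(out["leaf_a"])
        assert "leaf_b" not in out

    def test_missing_leaf_strict_errors(self, three_leaf_tree):
        with pytest.raises(MissingDataError, match="'b'"):
            evaluate_hierarchy(three_leaf_tree, {"a": 1.0, "c": 2.0}, missing="strict")

    def test_duplicate_node_ids_rejected(self):
        vf = make_value_function("a", (1, 2, 3, 4), 8)
        bad = ObjectiveNode(
            id="n",
            children=[
                ObjectiveNode(id="n", value_function=vf),
                ObjectiveNode(id="m", value_function=vf),
            ],
            weights=[0.5, 0.5],
            aggregation=AggregationSpec("additive"),
        )
        with pytest.raises(InvalidConfigError, match="duplicate"):
            bad.validate()

    def test_bad_sibling_weights_rejected(self):
        vf = make_value_function("a", (1, 2, 3, 4), 8)
        bad = ObjectiveNode(
            id="root",
            children=[
                ObjectiveNode(id="x", value_function=vf),
                ObjectiveNode(id="y", value_function=vf.__class__(
                    "b", "mg/L", vf.levels, vf.values)),
            ],
            weights=[0.5, 0.4],
            aggregation=AggregationSpec("additive"),
        )
        with pytest.raises(InvalidConfigError, match="sum to 1"):
            bad.validate()
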