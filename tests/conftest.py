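import numpy as np
import pytest

from aquaval import AggregationSpec, ObjectiveNode, make_value_function


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def simple_vf():
    """Standard six-breakpoint value function: boundaries 1,2,3,4, worst 8."""
    return make_value_function("x", (1, 2, 3, 4), 8, unit="mg/L")


def build_three_leaf_tree(method="additive_minimum", alpha=0.5, delta=0.1):
    """Toy hierarchy: root over one internal pair node and one extra leaf."""
    vf_a = make_value_function("a", (1, 2, 3, 4), 8)
    vf_b = make_value_function("b", (0.5, 1, 2, 4), 10)
    vf_c = make_value_function("c", (2, 4, 6, 8), 16)
    spec = AggregationSpec(method, alpha=alpha, delta=delta)
    pair = ObjectiveNode(
        id="pair",
        children=[
            ObjectiveNode(id="leaf_a", value_function=vf_a),
            ObjectiveNode(id="leaf_b", value_function=vf_b),
        ],
        weights=[0.6, 0.4],
        aggregation=spec,
    )
    root = ObjectiveNode(
        id="root",
        children=[pair, ObjectiveNode(id="leaf_c", value_function=vf_c)],
        weights=[0.7, 0.3],
        aggregation=spec,
    )
    root.validate()
    return root


@pytest.fixture
def three_leaf_tree():
    return build_three_leaf_tree()
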