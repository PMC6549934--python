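"""Objectives hierarchy and aggregation of sub-objective values.

Higher-level objectives combine the 0-1 values of their sub-objectives with
one of four aggregation operators:

* ``minimum`` — worst case / one-out-all-out: no compensation at all,
  v = min(v_1, ..., v_n).
* ``additive`` — weighted arithmetic mean, v = sum(w_i * v_i): a bad
  sub-objective can be fully compensated by good ones.
* ``additive_minimum`` — convex blend alpha * v_add + (1 - alpha) * v_min,
  allowing partial compensation (alpha in [0, 1]).
* ``geometric_offset`` — shifted weighted geometric mean
  (prod (v_i + delta)^w_i) - delta. delta = 0 gives the weighted geometric
  mean (which is 0 as soon as any sub-value is 0); delta -> infinity tends
  to the weighted arithmetic mean.

The two hybrid operators are the interesting ones for water-quality
assessment: they respond to every sub-objective (unlike minimum) but never
let a catastrophic sub-objective be talked away (unlike additive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import InvalidConfigError, InvalidInputError, MissingDataError
from .valfun import ValueFunction, evaluate_value

__all__ = [
    "AGGREGATION_METHODS",
    "AggregationSpec",
    "ObjectiveNode",
    "aggregate",
    "evaluate_hierarchy",
]

AGGREGATION_METHODS = ("minimum", "additive", "additive_minimum", "geometric_offset")

WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class AggregationSpec:
    """Aggregation operator and its parameters.

    ``alpha`` is the additive share for ``additive_minimum`` (default 0.5);
    ``delta`` the offset for ``geometric_offset`` (default 0.1). Parameters
    irrelevant to the chosen method are ignored.
    """

    method: str = "additive_minimum"
    alpha: float = 0.5
    delta: float = 0.1

    def __post_init__(self) -> None:
        if self.method not in AGGREGATION_METHODS:
            raise InvalidConfigError(
                f"unknown aggregation method {self.method!r}; "
                f"expected one of {AGGREGATION_METHODS}"
            )
        if not 0.0 <= self.alpha <= 1.0:
            raise InvalidConfigError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.delta < 0.0:
            raise InvalidConfigError(f"delta must be >= 0, got {self.delta}")


def _check_weights(weights: np.ndarray, n: int, where: str = "") -> np.ndarray:
    if weights.shape != (n,):
        raise InvalidConfigError(f"{where}expected {n} weights, got shape {weights.shape}")
    if np.any(weights < 0) or not np.all(np.isfinite(weights)):
        raise InvalidConfigError(f"{where}weights must be finite and >= 0")
    s = float(weights.sum())
    if abs(s - 1.0) > 1e-6:
        raise InvalidConfigError(f"{where}weights must sum to 1, got {s!r}")
    return weights / s


def _geometric_offset(values: np.ndarray, weights: np.ndarray, delta: float) -> np.ndarray:
    # prod over children of (v_i + delta)^w_i, minus delta. Log-space for
    # stability; a zero base with positive weight forces the product to 0
    # (the limit value), and 0^0 counts as 1 so zero-weight children never
    # contribute.
    shifted = values + delta
    active = weights > 0
    w = weights[active]
    s = shifted[active]
    if s.size == 0:
        return np.zeros(values.shape[1:]) + (1.0 - delta)  # pragma: no cover
    with np.errstate(divide="ignore"):
        logs = np.log(s)
    # broadcast weights over any trailing draw axis
    w_shaped = w.reshape((-1,) + (1,) * (values.ndim - 1))
    log_prod = np.sum(np.where(np.isneginf(logs), -np.inf, logs) * w_shaped, axis=0)
    return np.exp(log_prod) - delta


def aggregate(values, weights, spec: AggregationSpec) -> float | np.ndarray:
    """Aggregate sub-objective values into the parent objective's value.

    ``values`` may be a 1-D sequence of n values in [0, 1], or an array of
    shape ``(n, m)`` holding m joint draws per sub-objective, in which case
    an array of m aggregated values is returned (the operator is applied
    draw-wise). ``weights`` are n non-negative numbers summing to 1.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim == 0 or v.shape[0] < 1:
        raise InvalidInputError("need at least one sub-objective value")
    if not np.all(np.isfinite(v)) or np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
        raise InvalidInputError("sub-objective values must lie in [0, 1]")
    v = np.clip(v, 0.0, 1.0)
    n = v.shape[0]
    w = _check_weights(np.asarray(weights, dtype=float), n)

    w_shaped = w.reshape((-1,) + (1,) * (v.ndim - 1))
    if spec.method == "minimum":
        out = np.min(v, axis=0)
    elif spec.method == "additive":
        out = np.sum(w_shaped * v, axis=0)
    elif spec.method == "additive_minimum":
        v_add = np.sum(w_shaped * v, axis=0)
        v_min = np.min(v, axis=0)
        out = spec.alpha * v_add + (1.0 - spec.alpha) * v_min
    else:  # geometric_offset
        out = _geometric_offset(v, w, spec.delta)
    out = np.clip(out, 0.0, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class ObjectiveNode:
    """A node of the objectives hierarchy.

    Internal nodes carry child weights (summing to 1) and an aggregation
    spec; leaves carry a value function bound to a measurable attribute.
    """

    id: str
    label: str = ""
    children: list["ObjectiveNode"] = field(default_factory=list)
    weights: list[float] = field(default_factory=list)
    aggregation: AggregationSpec | None = None
    value_function: ValueFunction | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def validate(self) -> None:
        """Check tree structure: unique ids, weights, leaf bindings."""
        seen: set[str] = set()

        def _walk(node: "ObjectiveNode") -> None:
            if node.id in seen:
                raise InvalidConfigError(f"duplicate node id {node.id!r} in hierarchy")
            seen.add(node.id)
            if node.is_leaf:
                if node.value_function is None:
                    raise InvalidConfigError(
                        f"leaf node {node.id!r} has no attribute binding"
                    )
            else:
                if node.value_function is not None:
                    raise InvalidConfigError(
                        f"internal node {node.id!r} must not bind an attribute"
                    )
                if node.aggregation is None:
                    raise InvalidConfigError(
                        f"internal node {node.id!r} has no aggregation spec"
                    )
                w = np.asarray(node.weights, dtype=float)
                _check_weights(w, len(node.children), where=f"node {node.id!r}: ")
                for child in node.children:
                    _walk(child)

        _walk(self)

    def iter_nodes(self):
        yield self
        for child in self.children:
            yield from child.iter_nodes()

    def leaf_attributes(self) -> list[str]:
        return [
            n.value_function.attribute_id for n in self.iter_nodes() if n.is_leaf
        ]


def evaluate_hierarchy(
    root: ObjectiveNode,
    levels: Mapping[str, float | np.ndarray],
    missing: str = "renormalize",
) -> dict[str, float | np.ndarray]:
    """Evaluate the hierarchy bottom-up for one set of attribute levels.

    Leaves are evaluated through their value functions; each internal node
    aggregates its children. ``levels`` maps attribute ids to levels; level
    entries may be arrays of joint Monte Carlo draws, in which case every
    node value is an array of the same length.

    ``missing`` controls what happens when a leaf's attribute is absent from
    ``levels``: ``"renormalize"`` (default) drops the leaf and renormalizes
    its siblings' weights, emitting a warning; ``"strict"`` raises
    :class:`MissingDataError`. Attribute ids in ``levels`` that bind to no
    leaf produce a warning.

    Returns a mapping node id -> value (or value sample) covering every node
    that could be evaluated.
    """
    if missing not in ("renormalize", "strict"):
        raise InvalidConfigError(f"unknown missing-data policy {missing!r}")
    root.validate()
    bound = set(root.leaf_attributes())
    unknown = set(levels) - bound
    if unknown:
        warnings.warn(
            f"attribute ids without a bound leaf ignored: {sorted(unknown)}",
            stacklevel=2,
        )

    out: dict[str, float | np.ndarray] = {}

    def _eval(node: ObjectiveNode):
        if node.is_leaf:
            vf = node.value_function
            if vf.attribute_id not in levels:
                if missing == "strict":
                    raise MissingDataError(
                        f"no level supplied for attribute {vf.attribute_id!r} "
                        f"(leaf {node.id!r})"
                    )
                return None
            val = evaluate_value(vf, levels[vf.attribute_id])
            out[node.id] = val
            return val
        child_vals = []
        child_weights = []
        for child, w in zip(node.children, node.weights):
            cv = _eval(child)
            if cv is not None:
                child_vals.append(cv)
                child_weights.append(w)
        if not child_vals:
            return None
        if len(child_vals) < len(node.children):
            warnings.warn(
                f"node {node.id!r}: {len(node.children) - len(child_vals)} child(ren) "
                "missing; sibling weights renormalized",
                stacklevel=2,
            )
        w = np.asarray(child_weights, dtype=float)
        w = w / w.sum()
        val = aggregate(np.asarray(child_vals, dtype=float), w, node.aggregation)
        out[node.id] = val
        return val

    if _eval(root) is None:
        raise MissingDataError("no attribute levels available for any leaf")
    return out
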