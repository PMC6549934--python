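"""Monte Carlo propagation of attribute samples through the hierarchy.

Prediction uncertainty arrives as a joint sample of all leaf attributes (one
draw = one internally consistent realisation of the water-quality model).
Each draw is pushed through the full objectives hierarchy, yielding a value
sample at every node; only then are the samples summarized as the median and
the 5%/95% quantiles. Summarizing first and aggregating the summaries would
be wrong whenever an operator is nonlinear (the minimum being the extreme
case), so propagation is always draw-wise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .hierarchy import ObjectiveNode, evaluate_hierarchy
from .valfun import classify

__all__ = [
    "Cell",
    "AttributeSampleSet",
    "NodeSummary",
    "AssessmentResult",
    "DEFAULT_INTERVAL_PROBS",
    "summarize",
    "propagate",
    "grab_sample",
    "grab_statistic",
]

#: Default reporting interval: the 90% band between the 5% and 95% quantiles.
DEFAULT_INTERVAL_PROBS = (0.05, 0.5, 0.95)


class Cell(NamedTuple):
    """One (site, alternative, scenario, climate) combination."""

    site: str
    alternative: str
    scenario: str
    climate: str


@dataclass
class AttributeSampleSet:
    """Joint Monte Carlo draws of all leaf attributes for one cell.

    ``draws`` maps each attribute id to an array of length ``n_draws``; draw
    index i across attributes forms one joint realisation.
    """

    cell: Cell
    draws: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not self.draws:
            raise InvalidInputError(f"{self.cell}: no attribute draws supplied")
        lengths = {k: np.asarray(v).shape for k, v in self.draws.items()}
        sizes = {s for s in lengths.values()}
        if any(len(s) != 1 for s in sizes) or len({s[0] for s in sizes}) != 1:
            raise InvalidInputError(
                f"{self.cell}: inconsistent draw arrays across attributes: {lengths}"
            )
        self.draws = {k: np.asarray(v, dtype=float) for k, v in self.draws.items()}
        for k, v in self.draws.items():
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise InvalidInputError(
                    f"{self.cell}: attribute {k!r} has non-finite or negative levels"
                )

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def attributes(self) -> list[str]:
        return sorted(self.draws)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: site, alternative, scenario, climate, draw, attribute, level."""
        records = []
        for attr in self.attributes:
            vals = self.draws[attr]
            for i, level in enumerate(vals):
                records.append((*self.cell, i, attr, level))
        return pd.DataFrame(
            records,
            columns=["site", "alternative", "scenario", "climate", "draw", "attribute", "level"],
        )


@dataclass(frozen=True)
class NodeSummary:
    """Median, interval bounds and median quality class for one node."""

    node_id: str
    median: float
    q05: float
    q95: float
    class_label: str
    color: str


@dataclass
class AssessmentResult:
    """Per-node value samples and summaries for one cell."""

    cell: Cell
    samples: dict[str, np.ndarray]
    interval_probs: tuple[float, float] = (0.05, 0.95)

    def summary(self, node_id: str) -> NodeSummary:
        lo, hi = self.interval_probs
        q_lo, med, q_hi = summarize(self.samples[node_id], (lo, 0.5, hi))
        qc = classify(med)
        return NodeSummary(node_id, med, q_lo, q_hi, qc.label, qc.color)

    def median(self, node_id: str) -> float:
        return float(summarize(self.samples[node_id], (0.5,))[0])

    def to_frame(self) -> pd.DataFrame:
        """Summary table: one row per node with median, interval and class."""
        rows = []
        for node_id in self.samples:
            s = self.summary(node_id)
            rows.append(
                (*self.cell, node_id, s.median, s.q05, s.q95, s.class_label, s.color)
            )
        return pd.DataFrame(
            rows,
            columns=[
                "site", "alternative", "scenario", "climate",
                "node", "median", "q05", "q95", "class", "color",
            ],
        )


def summarize(values: Sequence[float], probs: Sequence[float]) -> np.ndarray:
    """Empirical quantiles by linear interpolation of order statistics.

    The rule is numpy's ``method="linear"`` (Hyndman-Fan type 7), fixed so
    results are bit-reproducible; the median is the 0.5 quantile.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InvalidInputError("cannot summarize an empty sample")
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise InvalidInputError("quantile probabilities must lie in [0, 1]")
    return np.quantile(arr, p, method="linear")


def propagate(
    root: ObjectiveNode,
    samples: AttributeSampleSet,
    interval_probs: tuple[float, float] = (0.05, 0.95),
    missing: str = "renormalize",
) -> AssessmentResult:
    """Push every joint draw through the hierarchy and keep per-node samples.

    Equivalent to evaluating the hierarchy once per draw (the vectorised
    evaluation applies every operator draw-wise, preserving the joint
    structure across attributes); summaries are computed from the stored
    samples, never aggregated directly.
    """
    node_values = evaluate_hierarchy(root, samples.draws, missing=missing)
    n = samples.n_draws
    out = {
        node_id: np.broadcast_to(np.asarray(v, dtype=float), (n,)).copy()
        for node_id, v in node_values.items()
    }
    return AssessmentResult(samples.cell, out, interval_probs)


def grab_sample(series: pd.Series, schedule: Sequence) -> pd.Series:
    """Extract attribute levels at scheduled dates from a dated series.

    Mimics the routine monitoring procedure: instead of using the full
    (modelled) time series, levels are read off at the grab-sampling dates
    only. Every scheduled date must exist in the series index.
    """
    if len(schedule) == 0:
        raise InvalidInputError("grab-sample schedule is empty")
    idx = pd.Index(schedule)
    missing = idx.difference(series.index)
    if len(missing) > 0:
        raise InvalidInputError(
            f"grab-sample date(s) outside the series range: {list(missing[:5])}"
        )
    return series.loc[idx]


def grab_statistic(levels: Sequence[float], percentile: float = 90.0) -> float:
    """Attribute statistic entering the value function from grab samples.

    Defaults to the 90th percentile of the sampled concentrations — a
    high-end summary in line with precautionary monitoring practice;
    configurable via ``percentile``.
    """
    arr = np.asarray(levels, dtype=float)
    if arr.size == 0:
        raise InvalidInputError("no grab-sample levels supplied")
    if not 0.0 <= percentile <= 100.0:
        raise InvalidInputError(f"percentile must lie in [0, 100], got {percentile}")
    return float(np.percentile(arr, percentile, method="linear"))
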