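"""Ranking, dominance analysis and cost-effectiveness trade-offs.

The decision layer never collapses cost and water quality into one number:
alternatives are ranked by median overall value per scenario, screened for
Pareto dominance across objectives, and laid out in cost-vs-value trade-off
tables (and plots) that leave the final weighing to the decision makers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "AlternativeOutcome",
    "rank_alternatives",
    "dominated_alternatives",
    "tradeoff_table",
    "plot_tradeoff",
]


@dataclass(frozen=True)
class AlternativeOutcome:
    """Overall value summary and relative cost for one alternative in one cell."""

    alternative_id: str
    scenario_id: str
    climate_id: str
    value_median: float
    value_q05: float
    value_q95: float
    cost_min: float
    cost_best: float
    cost_max: float

    def __post_init__(self) -> None:
        v = (self.value_q05, self.value_median, self.value_q95)
        if not all(0.0 <= x <= 1.0 for x in v) or not (v[0] <= v[1] <= v[2]):
            raise InvalidInputError(
                f"{self.alternative_id!r}: value summaries must be ordered in [0, 1], got {v}"
            )
        c = (self.cost_min, self.cost_best, self.cost_max)
        if not (c[0] <= c[1] <= c[2]):
            raise InvalidInputError(
                f"{self.alternative_id!r}: cost bounds must be ordered, got {c}"
            )


def rank_alternatives(outcomes: Sequence[AlternativeOutcome]) -> dict[str, int]:
    """Rank alternatives within one scenario cell by median overall value.

    Rank 1 is the highest median. Exact ties share a rank and the following
    rank(s) are skipped (competition ranking: 1, 2, 2, 4).
    """
    ids = [o.alternative_id for o in outcomes]
    if len(set(ids)) != len(ids):
        raise InvalidInputError(f"duplicate alternative ids in ranking input: {ids}")
    medians = {o.alternative_id: o.value_median for o in outcomes}
    ranks: dict[str, int] = {}
    for alt, med in medians.items():
        ranks[alt] = 1 + sum(other > med for other in medians.values())
    return ranks


def dominated_alternatives(
    objectives: Mapping[str, Sequence[float]],
    higher_is_better: Sequence[bool],
) -> set[str]:
    """Identify alternatives dominated in the Pareto sense.

    ``objectives`` maps each alternative id to its vector of objective
    medians; ``higher_is_better`` declares the orientation of each position
    (a value objective: True; a cost: False). Alternative A is dominated iff
    some B is at least as good in every oriented objective and strictly
    better in at least one.
    """
    orient = np.where(np.asarray(higher_is_better, dtype=bool), 1.0, -1.0)
    m = orient.shape[0]
    vecs = {}
    for alt, vec in objectives.items():
        arr = np.asarray(vec, dtype=float)
        if arr.shape != (m,):
            raise InvalidInputError(
                f"alternative {alt!r}: expected {m} objectives, got shape {arr.shape}"
            )
        vecs[alt] = arr * orient  # after orientation, higher is always better
    dominated: set[str] = set()
    for a, va in vecs.items():
        for b, vb in vecs.items():
            if a != b and np.all(vb >= va) and np.any(vb > va):
                dominated.add(a)
                break
    return dominated


def dominated_alternatives_conservative(
    outcomes: Sequence[AlternativeOutcome],
) -> set[str]:
    """Interval-separated dominance on (value, cost), stricter than the default.

    A is dominated only if some B's value interval lies entirely above A's
    (q05 of B > q95 of A) while B's cost interval lies entirely below A's
    (max of B < min of A). This uncertainty-aware screening goes beyond the
    median-based analysis and rarely declares anything dominated.
    """
    dominated: set[str] = set()
    for a in outcomes:
        for b in outcomes:
            if b.alternative_id == a.alternative_id:
                continue
            if b.value_q05 > a.value_q95 and b.cost_max < a.cost_min:
                dominated.add(a.alternative_id)
                break
    return dominated


def tradeoff_table(outcomes: Sequence[AlternativeOutcome]) -> pd.DataFrame:
    """One record per (alternative, scenario, climate) with cost and value summaries."""
    if not outcomes:
        raise InvalidInputError("no outcomes supplied")
    return pd.DataFrame(
        [
            {
                "alternative": o.alternative_id,
                "scenario": o.scenario_id,
                "climate": o.climate_id,
                "value_median": o.value_median,
                "value_q05": o.value_q05,
                "value_q95": o.value_q95,
                "cost_best_pct": o.cost_best,
                "cost_min_pct": o.cost_min,
                "cost_max_pct": o.cost_max,
            }
            for o in outcomes
        ]
    )


def pooled_envelope(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse scenarios/climates to a per-alternative min/max envelope of medians."""
    g = table.groupby("alternative")
    return pd.DataFrame(
        {
            "value_median_min": g["value_median"].min(),
            "value_median_max": g["value_median"].max(),
            "cost_best_min": g["cost_best_pct"].min(),
            "cost_best_max": g["cost_best_pct"].max(),
        }
    ).reset_index()


def plot_tradeoff(table: pd.DataFrame, ax=None):
    """Cost-vs-value scatter with interval bars, one point per record.

    X axis: relative cost (best estimate, bar spanning min-max); Y axis:
    median overall value (bar spanning the reported quantile interval).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for _, row in table.iterrows():
        ax.errorbar(
            row["cost_best_pct"],
            row["value_median"],
            xerr=[[row["cost_best_pct"] - row["cost_min_pct"]],
                  [row["cost_max_pct"] - row["cost_best_pct"]]],
            yerr=[[row["value_median"] - row["value_q05"]],
                  [row["value_q95"] - row["value_median"]]],
            fmt="o",
            capsize=2,
            label=f"{row['alternative']}/{row['scenario']}",
        )
    ax.set_xlabel("relative cost [% of mean taxable income per inhabitant]")
    ax.set_ylabel("overall water-quality value [-]")
    ax.set_ylim(0, 1)
    return ax
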