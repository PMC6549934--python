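"""Cost estimates and socio-economic scenario projection.

Absolute annual costs of a management alternative mean little without the
economic context they fall into; the assessment therefore expresses them per
inhabitant and relative to the mean taxable income expected under each
socio-economic scenario at the planning horizon. Cost uncertainty is carried
as (min, best, max) interval bounds, the min and max playing the role of
confidence-interval bounds around the best estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .errors import InvalidConfigError, InvalidInputError

__all__ = [
    "CostEstimate",
    "SocioEconomicScenario",
    "DEFAULT_SCENARIOS",
    "project_scenario",
    "relative_cost",
]


@dataclass(frozen=True)
class CostEstimate:
    """Annual cost of one alternative with interval bounds (currency/year)."""

    alternative_id: str
    annual_cost_min: float
    annual_cost_best: float
    annual_cost_max: float

    def __post_init__(self) -> None:
        c = (self.annual_cost_min, self.annual_cost_best, self.annual_cost_max)
        if any(x < 0 for x in c):
            raise InvalidConfigError(
                f"alternative {self.alternative_id!r}: costs must be >= 0, got {c}"
            )
        if not (c[0] <= c[1] <= c[2]):
            raise InvalidConfigError(
                f"alternative {self.alternative_id!r}: cost bounds must satisfy "
                f"min <= best <= max, got {c}"
            )


@dataclass(frozen=True)
class SocioEconomicScenario:
    """Socio-economic scenario for the planning horizon.

    ``income_growth_pct_per_year`` compounds annually; population and urban
    area changes are signed percentages relative to today (so +730 means a
    factor of 8.3, -20 a factor of 0.8, 0 no change).
    """

    name: str
    income_growth_pct_per_year: float
    population_change_pct: float
    urban_area_change_pct: float

    def __post_init__(self) -> None:
        if self.population_change_pct <= -100.0:
            raise InvalidConfigError(
                f"scenario {self.name!r}: population change {self.population_change_pct}% "
                "leaves no inhabitants"
            )


#: The four shipped scenarios for the 2050 horizon (changes relative to today).
DEFAULT_SCENARIOS: tuple[SocioEconomicScenario, ...] = (
    SocioEconomicScenario("status_quo", 0.4, 0.0, 0.0),
    SocioEconomicScenario("moderate_growth", 2.0, 20.0, 5.0),
    SocioEconomicScenario("exploding_growth", 4.0, 730.0, 300.0),
    SocioEconomicScenario("decline", -1.5, -20.0, 0.0),
)


class ProjectedState(NamedTuple):
    population: float
    income: float


def project_scenario(
    base_population: float,
    base_income: float,
    scenario: SocioEconomicScenario,
    years: int,
) -> ProjectedState:
    """Project population and mean taxable income to the horizon.

    Income compounds geometrically at the scenario's annual rate over
    ``years``; the population change applies as a single factor (the
    scenarios state the horizon-year population directly, not a growth
    path).
    """
    if base_population <= 0 or base_income <= 0:
        raise InvalidInputError(
            f"base population and income must be > 0, got "
            f"({base_population}, {base_income})"
        )
    if years < 0:
        raise InvalidInputError(f"years must be >= 0, got {years}")
    population = base_population * (1.0 + scenario.population_change_pct / 100.0)
    if population <= 0:
        raise InvalidConfigError(
            f"scenario {scenario.name!r}: projected population is not positive"
        )
    income = base_income * (1.0 + scenario.income_growth_pct_per_year / 100.0) ** years
    return ProjectedState(population, income)


class RelativeCost(NamedTuple):
    """Cost bounds as % of mean taxable income per inhabitant."""

    min: float
    best: float
    max: float


def relative_cost(
    cost: CostEstimate, population: float, income: float
) -> RelativeCost:
    """Express annual cost bounds as % of mean taxable income per inhabitant.

    Each bound is ``100 * annual_cost / (population * income)``; the
    min <= best <= max ordering is preserved because the scaling is a
    positive constant.
    """
    if population <= 0 or income <= 0:
        raise InvalidInputError(
            f"population and income must be > 0, got ({population}, {income})"
        )
    scale = 100.0 / (population * income)
    return RelativeCost(
        cost.annual_cost_min * scale,
        cost.annual_cost_best * scale,
        cost.annual_cost_max * scale,
    )
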