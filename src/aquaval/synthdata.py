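"""Synthetic catchment generator.

The real assessment consumes Monte Carlo output of a calibrated catchment
water-quality model. This module stands in for that model with a transparent
statistical emulation: each leaf attribute gets a baseline median level and
a multiplicative (log-normal) spread representing prediction uncertainty;
management alternatives scale source terms with reduction factors in [0, 1];
socio-economic scenarios and climate apply load multipliers. Draws for
different alternatives under the same (scenario, climate) share the same
underlying random realisations — the emulated model is "re-run" on the same
inputs with modified sources — so alternative comparisons are paired, as
they are in the real modelling chain.

The shipped default fixture is a self-consistent toy catchment: ten
alternatives (current practice, eight single measures, and their
combination), four socio-economic scenarios, two climates and the seven
leaf attributes of the default hierarchy. All concentration levels, class
boundaries and standards in the fixture are illustrative, not regulatory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .costs import DEFAULT_SCENARIOS
from .errors import InvalidConfigError
from .hierarchy import AggregationSpec, ObjectiveNode
from .pesticides import MODES_OF_ACTION, Substance, make_rq_value_function
from .uncertainty import AttributeSampleSet, Cell
from .valfun import ValueFunction, make_value_function

__all__ = [
    "SyntheticCatchmentConfig",
    "generate_samples",
    "make_default_fixture",
    "DefaultFixture",
]


@dataclass
class SyntheticCatchmentConfig:
    """Parameters of the emulated catchment.

    ``baseline_medians`` — median level per attribute under current practice,
    present climate, baseline scenario. ``spreads`` — geometric standard
    deviation (>= 1) of the multiplicative prediction noise per attribute; 1
    means no uncertainty. ``reductions`` — per alternative, attribute ->
    source-reduction factor in [0, 1] (attributes not listed are unaffected,
    factor 1). ``scenario_multipliers`` / ``climate_multipliers`` — load
    multipliers > 0 per scenario and climate (missing attributes default
    to 1).
    """

    site: str
    baseline_medians: dict[str, float]
    spreads: dict[str, float]
    reductions: dict[str, dict[str, float]]
    scenario_multipliers: dict[str, dict[str, float]]
    climate_multipliers: dict[str, float]
    n_draws: int = 1000
    seed: int | None = None

    def validate(self) -> None:
        for attr, m in self.baseline_medians.items():
            if not m >= 0:
                raise InvalidConfigError(f"baseline median for {attr!r} must be >= 0")
        for attr, s in self.spreads.items():
            if not s >= 1:
                raise InvalidConfigError(
                    f"spread (geometric s.d.) for {attr!r} must be >= 1, got {s}"
                )
        for alt, red in self.reductions.items():
            for attr, f in red.items():
                if not 0.0 <= f <= 1.0:
                    raise InvalidConfigError(
                        f"reduction factor {alt!r}/{attr!r} must lie in [0, 1], got {f}"
                    )
        for scen, mult in self.scenario_multipliers.items():
            for attr, f in mult.items():
                if not f > 0:
                    raise InvalidConfigError(
                        f"scenario multiplier {scen!r}/{attr!r} must be > 0, got {f}"
                    )
        for clim, f in self.climate_multipliers.items():
            if not f > 0:
                raise InvalidConfigError(
                    f"climate multiplier {clim!r} must be > 0, got {f}"
                )
        if self.n_draws < 1:
            raise InvalidConfigError(f"n_draws must be >= 1, got {self.n_draws}")

    @property
    def attributes(self) -> list[str]:
        return sorted(self.baseline_medians)


def generate_samples(
    config: SyntheticCatchmentConfig, seed: int | None = None
) -> dict[Cell, AttributeSampleSet]:
    """Draw joint attribute samples for every (alternative, scenario, climate).

    Levels are log-normal: ``median * exp(ln(spread) * Z)`` with Z standard
    normal, so the stated median is the distribution's median exactly and a
    spread of 1 collapses to the deterministic product
    ``baseline * reduction * scenario multiplier * climate multiplier``.
    The standard-normal matrix Z is drawn once per (scenario, climate) and
    shared across alternatives (paired comparisons). Identical seeds give
    identical output.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    if seed is None:
        raise InvalidConfigError("a seed is required for reproducible generation")
    attrs = config.attributes
    scenarios = sorted(config.scenario_multipliers)
    climates = sorted(config.climate_multipliers)
    alternatives = sorted(config.reductions)

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(scenarios) * len(climates))

    out: dict[Cell, AttributeSampleSet] = {}
    k = 0
    for scen in scenarios:
        for clim in climates:
            rng = np.random.default_rng(child_seeds[k])
            k += 1
            z = rng.standard_normal((len(attrs), config.n_draws))
            for alt in alternatives:
                red = config.reductions[alt]
                smult = config.scenario_multipliers[scen]
                draws = {}
                for i, attr in enumerate(attrs):
                    median = (
                        config.baseline_medians[attr]
                        * red.get(attr, 1.0)
                        * smult.get(attr, 1.0)
                        * config.climate_multipliers[clim]
                    )
                    sigma = np.log(config.spreads.get(attr, 1.0))
                    draws[attr] = median * np.exp(sigma * z[i])
                cell = Cell(config.site, alt, scen, clim)
                out[cell] = AttributeSampleSet(cell, draws)
    return out


# --------------------------------------------------------------------------
# Default fixture
# --------------------------------------------------------------------------

#: Leaf attribute ids of the default hierarchy: three nutrients and one
#: chronic-type risk quotient per pesticide mode of action.
NUTRIENT_ATTRIBUTES = ("NH4", "PO4", "NO3")
RQ_ATTRIBUTES = tuple(f"rq_{moa}" for moa in MODES_OF_ACTION)

_SINGLE_MEASURES = (
    "BanBioc", "StoreVol", "PermPav", "RetRain", "WWTP", "OrgFarm", "BufZone",
)


def default_value_functions() -> dict[str, ValueFunction]:
    """Value functions for the seven default leaf attributes.

    Nutrient class boundaries are illustrative stand-ins for a national
    stream-assessment scheme, not regulatory numbers; the risk-quotient
    translation anchors RQ 1 at value 0.6.
    """
    vfs = {
        "NH4": make_value_function("NH4", (0.1, 0.3, 0.6, 1.2), 3.0, unit="mg/L"),
        "PO4": make_value_function("PO4", (0.02, 0.04, 0.08, 0.16), 0.4, unit="mg/L"),
        "NO3": make_value_function("NO3", (1.5, 5.6, 8.4, 11.2), 25.0, unit="mg/L"),
    }
    for attr in RQ_ATTRIBUTES:
        vfs[attr] = make_rq_value_function(attr)
    return vfs


def default_hierarchy(
    aggregation: AggregationSpec | None = None,
) -> ObjectiveNode:
    """The default objectives hierarchy.

    Overall water quality splits into low nutrients (NH4, PO4, NO3) and no
    pesticide pollution (one sub-objective per mode of action). Internal
    nodes default to additive-minimum aggregation with alpha = 0.5 and equal
    sibling weights.
    """
    if aggregation is None:
        aggregation = AggregationSpec("additive_minimum", alpha=0.5)
    vfs = default_value_functions()
    nutrient_leaves = [
        ObjectiveNode(id=f"low_{a}", label=f"Low {a}", value_function=vfs[a])
        for a in NUTRIENT_ATTRIBUTES
    ]
    pesticide_leaves = [
        ObjectiveNode(
            id=f"no_{moa}",
            label=f"No {moa.replace('_', ' ')}",
            value_function=vfs[f"rq_{moa}"],
        )
        for moa in MODES_OF_ACTION
    ]
    root = ObjectiveNode(
        id="water_quality",
        label="Good water quality",
        children=[
            ObjectiveNode(
                id="nutrients",
                label="Low nutrient concentrations",
                children=nutrient_leaves,
                weights=[1 / 3] * 3,
                aggregation=aggregation,
            ),
            ObjectiveNode(
                id="pesticides",
                label="No pollution by pesticides",
                children=pesticide_leaves,
                weights=[1 / 4] * 4,
                aggregation=aggregation,
            ),
        ],
        weights=[0.5, 0.5],
        aggregation=aggregation,
    )
    root.validate()
    return root


def default_catchment_config(n_draws: int = 1000, seed: int | None = None) -> SyntheticCatchmentConfig:
    """The toy catchment: baselines, uncertainty spreads, measures, scenarios.

    Under current practice the nutrients sit in the moderate band and the
    pesticide groups around or above their standards, with wide (skewed)
    pesticide prediction uncertainty. Reduction factors encode which sources
    each measure addresses; "All" combines the seven single measures as the
    element-wise minimum of their factors (measures on the same source do
    not double-count).
    """
    baselines = {
        "NH4": 0.35, "PO4": 0.05, "NO3": 6.5,
        "rq_photosynthesis_inhibition": 5.0,
        "rq_auxin_activity": 3.5,
        "rq_vlcfa_synthesis_inhibition": 2.0,
        "rq_acetylcholinesterase_inhibition": 6.0,
    }
    spreads = {
        "NH4": 1.2, "PO4": 1.2, "NO3": 1.15,
        "rq_photosynthesis_inhibition": 2.0,
        "rq_auxin_activity": 2.5,
        "rq_vlcfa_synthesis_inhibition": 2.0,
        "rq_acetylcholinesterase_inhibition": 2.5,
    }
    def rqs(f: float) -> dict[str, float]:
        return {a: f for a in RQ_ATTRIBUTES}

    reductions: dict[str, dict[str, float]] = {
        "CurrPrac": {},
        "BanBioc": {
            "rq_photosynthesis_inhibition": 0.9,
            "rq_vlcfa_synthesis_inhibition": 0.85,
        },
        "StoreVol": {"NH4": 0.85, "PO4": 0.9, **rqs(0.9)},
        "PermPav": {"NH4": 0.9, "PO4": 0.95, **rqs(0.95)},
        "RetRain": {"NH4": 0.9, "PO4": 0.9, **rqs(0.95)},
        "WWTP": {"NH4": 0.5, "PO4": 0.6, **rqs(0.6)},
        "OrgFarm": {"NO3": 0.8, **rqs(0.15)},
        "NatPark": {"NO3": 0.7, "PO4": 0.85, **rqs(0.18)},
        "BufZone": {"PO4": 0.75, "NO3": 0.85, **rqs(0.9)},
    }
    all_attrs = sorted(baselines)
    reductions["All"] = {
        attr: min(reductions[m].get(attr, 1.0) for m in _SINGLE_MEASURES)
        for attr in all_attrs
        if min(reductions[m].get(attr, 1.0) for m in _SINGLE_MEASURES) < 1.0
    }

    urban = {"NH4", "PO4"}
    scenario_multipliers = {
        "status_quo": {},
        "moderate_growth": {**{a: 1.05 for a in urban}},
        "exploding_growth": {
            **{a: 1.15 for a in urban},
            "NO3": 0.9,
            **rqs(1.05),
        },
        "decline": {**{a: 0.95 for a in urban}},
    }
    climate_multipliers = {"present": 1.0, "future": 1.05}

    return SyntheticCatchmentConfig(
        site="outlet",
        baseline_medians=baselines,
        spreads=spreads,
        reductions=reductions,
        scenario_multipliers=scenario_multipliers,
        climate_multipliers=climate_multipliers,
        n_draws=n_draws,
        seed=seed,
    )


def default_substances() -> list[Substance]:
    """Illustrative substance table (EQS values are placeholders, non-regulatory)."""
    return [
        Substance("atrazine_like", "photosynthesis_inhibition", 0.02, 0.2),
        Substance("diuron_like", "photosynthesis_inhibition", 0.07, 0.25),
        Substance("mcpa_like", "auxin_activity", 0.66, 2.0),
        Substance("metolachlor_like", "vlcfa_synthesis_inhibition", 0.28, 1.2),
        Substance("chlorpyrifos_like", "acetylcholinesterase_inhibition", 0.00046, 0.0044),
    ]


def default_cost_table() -> pd.DataFrame:
    """Illustrative annual cost estimates per alternative (currency/year)."""
    rows = [
        ("CurrPrac", 0.0, 0.0, 0.0),
        ("BanBioc", 0.8e6, 1.5e6, 2.8e6),
        ("StoreVol", 0.6e6, 1.0e6, 1.8e6),
        ("PermPav", 0.5e6, 0.9e6, 1.6e6),
        ("RetRain", 0.3e6, 0.6e6, 1.1e6),
        ("WWTP", 0.9e6, 1.4e6, 2.2e6),
        ("OrgFarm", 1.2e6, 2.2e6, 3.8e6),
        ("NatPark", 2.5e6, 4.5e6, 7.5e6),
        ("BufZone", 0.4e6, 0.7e6, 1.3e6),
    ]
    rows.append(
        (
            "All",
            sum(r[1] for r in rows if r[0] in _SINGLE_MEASURES),
            sum(r[2] for r in rows if r[0] in _SINGLE_MEASURES),
            sum(r[3] for r in rows if r[0] in _SINGLE_MEASURES),
        )
    )
    return pd.DataFrame(
        rows,
        columns=["alternative", "annual_cost_min", "annual_cost_best", "annual_cost_max"],
    ).assign(currency="CHF")


def default_scenario_table() -> pd.DataFrame:
    """The four socio-economic scenarios as a table (changes relative to today)."""
    return pd.DataFrame(
        [
            (s.name, s.income_growth_pct_per_year, s.population_change_pct, s.urban_area_change_pct)
            for s in DEFAULT_SCENARIOS
        ],
        columns=[
            "scenario",
            "income_growth_pct_per_year",
            "population_change_pct",
            "urban_area_change_pct",
        ],
    )


@dataclass
class DefaultFixture:
    """All pieces of the shipped toy catchment, ready to run end to end."""

    hierarchy: ObjectiveNode
    value_functions: dict[str, ValueFunction]
    substances: list[Substance]
    cost_table: pd.DataFrame
    scenario_table: pd.DataFrame
    catchment: SyntheticCatchmentConfig
    base_population: float = 24000.0
    base_income: float = 50000.0  # illustrative mean taxable income, CHF/year
    horizon_years: int = 35      # 2015 -> 2050


def make_default_fixture(n_draws: int = 1000, seed: int | None = None) -> DefaultFixture:
    """Assemble the self-consistent default fixture."""
    return DefaultFixture(
        hierarchy=default_hierarchy(),
        value_functions=default_value_functions(),
        substances=default_substances(),
        cost_table=default_cost_table(),
        scenario_table=default_scenario_table(),
        catchment=default_catchment_config(n_draws=n_draws, seed=seed),
    )
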