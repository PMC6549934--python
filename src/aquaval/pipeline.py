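"""End-to-end assessment runs: configs in, result tables out.

A run is described by a :class:`~aquaval.configio.RunManifest` pointing at a
config directory with fixed file names:

* ``value_functions.yaml`` — value-function definitions
* ``hierarchy.yaml``       — objectives hierarchy
* ``eqs.csv``              — substance EQS table
* ``costs.csv``            — annual cost estimates per alternative
* ``scenarios.csv``        — socio-economic scenarios
* ``catchment.yaml``       — synthetic catchment config (+ economy block)

Outputs (all CSV, deterministic given the seed): ``assessment.csv`` with
per-node medians, interval bounds and quality classes; ``outcomes.csv``
joining overall value and relative cost per cell; ``ranking.csv``;
``tradeoff.csv``; ``report.csv`` (the colour-coded class table); and
``manifest.json`` recording the run so it can be reproduced exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__ as _version
from .configio import (
    RunManifest,
    read_catchment_config,
    read_cost_table,
    read_hierarchy,
    read_scenario_table,
    read_value_functions,
)
from .costs import project_scenario, relative_cost
from .decision import AlternativeOutcome, rank_alternatives, tradeoff_table
from .errors import InvalidConfigError
from .hierarchy import AggregationSpec, ObjectiveNode
from .synthdata import generate_samples
from .uncertainty import propagate

__all__ = ["CONFIG_FILES", "run_assessment", "write_fixture_configs"]

CONFIG_FILES = {
    "value_functions": "value_functions.yaml",
    "hierarchy": "hierarchy.yaml",
    "eqs": "eqs.csv",
    "costs": "costs.csv",
    "scenarios": "scenarios.csv",
    "catchment": "catchment.yaml",
}


def _override_aggregation(root: ObjectiveNode, override: Mapping) -> None:
    spec = AggregationSpec(
        method=override.get("method", "additive_minimum"),
        alpha=float(override.get("alpha", 0.5)),
        delta=float(override.get("delta", 0.1)),
    )
    for node in root.iter_nodes():
        if not node.is_leaf:
            node.aggregation = spec


def run_assessment(manifest: RunManifest) -> dict[str, pd.DataFrame]:
    """Execute one full assessment run and write all output tables.

    Returns the output tables keyed by name (``assessment``, ``outcomes``,
    ``ranking``, ``tradeoff``, ``report``). Identical manifests with equal
    seeds produce byte-identical CSV outputs (the manifest's timestamp is
    metadata, not an input).
    """
    cfg_dir = Path(manifest.config_dir)
    out_dir = Path(manifest.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    vfs = read_value_functions(cfg_dir / CONFIG_FILES["value_functions"])
    root = read_hierarchy(cfg_dir / CONFIG_FILES["hierarchy"], vfs)
    costs = {c.alternative_id: c for c in read_cost_table(cfg_dir / CONFIG_FILES["costs"])}
    scenarios = {s.name: s for s in read_scenario_table(cfg_dir / CONFIG_FILES["scenarios"])}
    catchment, economy = read_catchment_config(cfg_dir / CONFIG_FILES["catchment"])

    if manifest.aggregation_override:
        _override_aggregation(root, manifest.aggregation_override)
    if manifest.n_draws:
        catchment.n_draws = manifest.n_draws

    for key in ("base_population", "base_income"):
        if key not in economy:
            raise InvalidConfigError(
                f"{cfg_dir / CONFIG_FILES['catchment']}: economy block must define {key!r}"
            )
    base_pop = float(economy["base_population"])
    base_income = float(economy["base_income"])
    horizon = int(economy.get("horizon_years", 35))

    samples = generate_samples(catchment, seed=manifest.seed)

    results = {}
    for cell, sample_set in samples.items():
        results[cell] = propagate(
            root, sample_set,
            interval_probs=manifest.interval_probs,
            missing=manifest.missing_policy,
        )

    assessment = pd.concat(
        [res.to_frame() for res in results.values()], ignore_index=True
    ).sort_values(["scenario", "climate", "alternative", "node"], kind="stable")
    assessment = assessment.reset_index(drop=True)

    outcomes = []
    for cell, res in sorted(results.items()):
        scen = scenarios.get(cell.scenario)
        if scen is None:
            raise InvalidConfigError(
                f"scenario {cell.scenario!r} in catchment config has no entry in "
                f"{CONFIG_FILES['scenarios']}"
            )
        cost = costs.get(cell.alternative)
        if cost is None:
            raise InvalidConfigError(
                f"alternative {cell.alternative!r} has no entry in {CONFIG_FILES['costs']}"
            )
        pop, income = project_scenario(base_pop, base_income, scen, horizon)
        rc = relative_cost(cost, pop, income)
        s = res.summary(root.id)
        outcomes.append(
            AlternativeOutcome(
                cell.alternative, cell.scenario, cell.climate,
                s.median, s.q05, s.q95, rc.min, rc.best, rc.max,
            )
        )
    tradeoff = tradeoff_table(outcomes).sort_values(
        ["scenario", "climate", "alternative"], kind="stable"
    ).reset_index(drop=True)

    ranking_rows = []
    for (scen, clim), grp in tradeoff.groupby(["scenario", "climate"], sort=True):
        cell_outcomes = [o for o in outcomes if o.scenario_id == scen and o.climate_id == clim]
        ranks = rank_alternatives(cell_outcomes)
        for o in cell_outcomes:
            ranking_rows.append((scen, clim, o.alternative_id, o.value_median, ranks[o.alternative_id]))
    ranking = pd.DataFrame(
        ranking_rows, columns=["scenario", "climate", "alternative", "value_median", "rank"]
    ).sort_values(["scenario", "climate", "rank", "alternative"], kind="stable").reset_index(drop=True)

    report = assessment[
        ["site", "alternative", "scenario", "climate", "node", "median", "q05", "q95", "class", "color"]
    ].copy()

    tables = {
        "assessment": assessment,
        "outcomes": tradeoff,
        "ranking": ranking,
        "tradeoff": tradeoff,
        "report": report,
    }
    for name in ("assessment", "outcomes", "ranking", "tradeoff", "report"):
        tables[name].to_csv(out_dir / f"{name}.csv", index=False)

    manifest.tool_version = _version
    if not manifest.timestamp:
        manifest.timestamp = RunManifest.now()
    manifest.to_json(out_dir / "manifest.json")
    return tables


def write_fixture_configs(
    config_dir: str | Path, n_draws: int = 1000, seed: int | None = None
) -> Path:
    """Write the default toy-catchment fixture as config files.

    The written files are the format documentation by example: they are
    exactly what :func:`run_assessment` reads back.
    """
    from .configio import (
        write_catchment_config,
        write_cost_table,
        write_eqs_table,
        write_hierarchy,
        write_scenario_table,
        write_value_functions,
    )
    from .synthdata import make_default_fixture

    cfg_dir = Path(config_dir)
    cfg_dir.mkdir(parents=True, exist_ok=True)
    fix = make_default_fixture(n_draws=n_draws, seed=seed)
    write_value_functions(fix.value_functions, cfg_dir / CONFIG_FILES["value_functions"])
    write_hierarchy(fix.hierarchy, cfg_dir / CONFIG_FILES["hierarchy"])
    write_eqs_table(fix.substances, cfg_dir / CONFIG_FILES["eqs"])
    write_cost_table(fix.cost_table, cfg_dir / CONFIG_FILES["costs"])
    write_scenario_table(fix.scenario_table, cfg_dir / CONFIG_FILES["scenarios"])
    write_catchment_config(
        fix.catchment,
        cfg_dir / CONFIG_FILES["catchment"],
        economy={
            "base_population": fix.base_population,
            "base_income": fix.base_income,
            "horizon_years": fix.horizon_years,
        },
    )
    return cfg_dir
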