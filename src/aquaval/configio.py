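"""Readers, writers and validation for all config and table formats.

Configs (value functions, hierarchy, catchment) are YAML or JSON — both are
parsed by the YAML loader, since JSON is a YAML subset. Tables (EQS, costs,
scenarios, attribute samples, results) are plain CSV with a header row,
UTF-8, "." decimal separator. Every reader validates and raises with the
offending file and field named; :func:`validate_configs` collects all
violations into a report instead of stopping at the first.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .costs import CostEstimate, SocioEconomicScenario
from .errors import AquavalError, InvalidConfigError, InvalidInputError
from .hierarchy import AggregationSpec, ObjectiveNode
from .pesticides import Substance
from .synthdata import SyntheticCatchmentConfig
from .uncertainty import AttributeSampleSet, Cell
from .valfun import ValueFunction, make_value_function

__all__ = [
    "read_value_functions",
    "write_value_functions",
    "read_hierarchy",
    "write_hierarchy",
    "read_eqs_table",
    "write_eqs_table",
    "read_cost_table",
    "write_cost_table",
    "read_scenario_table",
    "write_scenario_table",
    "read_catchment_config",
    "write_catchment_config",
    "read_attribute_samples",
    "write_attribute_samples",
    "validate_configs",
    "RunManifest",
]


def _load_structured(path: Path) -> Any:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _dump_structured(obj: Any, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False, allow_unicode=True)


# ---------------------------------------------------------------- value functions

def read_value_functions(path: str | Path) -> dict[str, ValueFunction]:
    """Read value-function definitions from a YAML/JSON config.

    Each entry carries ``attribute``, ``unit``, and either the standard
    four ``class_boundary_levels`` plus ``worst_case_level``, or explicit
    ``breakpoints`` as [level, value] pairs.
    """
    path = Path(path)
    data = _load_structured(path)
    if not isinstance(data, list):
        raise InvalidConfigError(f"{path}: expected a list of value-function entries")
    out: dict[str, ValueFunction] = {}
    for i, entry in enumerate(data):
        where = f"{path}: entry {i}"
        if not isinstance(entry, Mapping) or "attribute" not in entry:
            raise InvalidConfigError(f"{where}: missing field 'attribute'")
        attr = entry["attribute"]
        unit = entry.get("unit", "")
        if "breakpoints" in entry:
            pts = entry["breakpoints"]
            vf = ValueFunction(
                attr, unit,
                tuple(float(p[0]) for p in pts),
                tuple(float(p[1]) for p in pts),
            )
        elif "class_boundary_levels" in entry and "worst_case_level" in entry:
            vf = make_value_function(
                attr, entry["class_boundary_levels"], entry["worst_case_level"], unit
            )
        else:
            raise InvalidConfigError(
                f"{where} ({attr!r}): need either 'breakpoints' or "
                "'class_boundary_levels' + 'worst_case_level'"
            )
        if attr in out:
            raise InvalidConfigError(f"{where}: duplicate attribute {attr!r}")
        out[attr] = vf
    return out


def write_value_functions(vfs: Mapping[str, ValueFunction], path: str | Path) -> None:
    data = [
        {
            "attribute": vf.attribute_id,
            "unit": vf.unit,
            "breakpoints": [[float(l), float(v)] for l, v in zip(vf.levels, vf.values)],
        }
        for vf in vfs.values()
    ]
    _dump_structured(data, Path(path))


# ---------------------------------------------------------------- hierarchy

def _node_from_dict(d: Mapping, vfs: Mapping[str, ValueFunction], path: Path) -> ObjectiveNode:
    if "id" not in d:
        raise InvalidConfigError(f"{path}: node without an 'id' field: {dict(d)}")
    node_id = d["id"]
    children_cfg = d.get("children", [])
    if children_cfg:
        agg_cfg = d.get("aggregation", {})
        spec = AggregationSpec(
            method=agg_cfg.get("method", "additive_minimum"),
            alpha=float(agg_cfg.get("alpha", 0.5)),
            delta=float(agg_cfg.get("delta", 0.1)),
        )
        children = [_node_from_dict(c, vfs, path) for c in children_cfg]
        weights = [float(c.get("weight", 1.0 / len(children_cfg))) for c in children_cfg]
        return ObjectiveNode(
            id=node_id, label=d.get("label", node_id),
            children=children, weights=weights, aggregation=spec,
        )
    attr = d.get("attribute")
    if attr is None:
        raise InvalidConfigError(
            f"{path}: leaf node {node_id!r} has no 'attribute' binding"
        )
    if attr not in vfs:
        raise InvalidConfigError(
            f"{path}: leaf node {node_id!r} binds unknown attribute {attr!r} "
            "(no value function defined for it)"
        )
    return ObjectiveNode(id=node_id, label=d.get("label", node_id), value_function=vfs[attr])


def read_hierarchy(path: str | Path, value_functions: Mapping[str, ValueFunction]) -> ObjectiveNode:
    """Read the objectives hierarchy and bind leaves to their value functions."""
    path = Path(path)
    data = _load_structured(path)
    if not isinstance(data, Mapping):
        raise InvalidConfigError(f"{path}: expected a mapping with the root node")
    root = _node_from_dict(data, value_functions, path)
    try:
        root.validate()
    except AquavalError as exc:
        raise InvalidConfigError(f"{path}: {exc}") from exc
    return root


def _node_to_dict(node: ObjectiveNode, weight: float | None = None) -> dict:
    d: dict[str, Any] = {"id": node.id, "label": node.label}
    if weight is not None:
        d["weight"] = float(weight)
    if node.is_leaf:
        d["attribute"] = node.value_function.attribute_id
    else:
        agg = node.aggregation
        d["aggregation"] = {"method": agg.method, "alpha": agg.alpha, "delta": agg.delta}
        d["children"] = [
            _node_to_dict(c, w) for c, w in zip(node.children, node.weights)
        ]
    return d


def write_hierarchy(root: ObjectiveNode, path: str | Path) -> None:
    _dump_structured(_node_to_dict(root), Path(path))


# ---------------------------------------------------------------- CSV tables

def read_eqs_table(path: str | Path) -> list[Substance]:
    """EQS table CSV: substance, moa, eqs_chronic_ugL, eqs_acute_ugL."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"substance", "moa", "eqs_chronic_ugL", "eqs_acute_ugL"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidConfigError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        try:
            out.append(
                Substance(
                    str(row["substance"]), str(row["moa"]),
                    float(row["eqs_chronic_ugL"]), float(row["eqs_acute_ugL"]),
                )
            )
        except AquavalError as exc:
            raise InvalidConfigError(f"{path}: {exc}") from exc
    return out


def write_eqs_table(substances: Sequence[Substance], path: str | Path) -> None:
    pd.DataFrame(
        [(s.name, s.moa, s.eqs_chronic, s.eqs_acute) for s in substances],
        columns=["substance", "moa", "eqs_chronic_ugL", "eqs_acute_ugL"],
    ).to_csv(path, index=False)


def read_cost_table(path: str | Path) -> list[CostEstimate]:
    """Cost table CSV: alternative, annual_cost_min, annual_cost_best, annual_cost_max."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"alternative", "annual_cost_min", "annual_cost_best", "annual_cost_max"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidConfigError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        try:
            out.append(
                CostEstimate(
                    str(row["alternative"]),
                    float(row["annual_cost_min"]),
                    float(row["annual_cost_best"]),
                    float(row["annual_cost_max"]),
                )
            )
        except AquavalError as exc:
            raise InvalidConfigError(f"{path}: {exc}") from exc
    return out


def write_cost_table(costs: pd.DataFrame, path: str | Path) -> None:
    costs.to_csv(path, index=False)


def read_scenario_table(path: str | Path) -> list[SocioEconomicScenario]:
    """Scenario table CSV with income growth and population/urban-area changes."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {
        "scenario", "income_growth_pct_per_year",
        "population_change_pct", "urban_area_change_pct",
    }
    missing = required - set(df.columns)
    if missing:
        raise InvalidConfigError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        try:
            out.append(
                SocioEconomicScenario(
                    str(row["scenario"]),
                    float(row["income_growth_pct_per_year"]),
                    float(row["population_change_pct"]),
                    float(row["urban_area_change_pct"]),
                )
            )
        except AquavalError as exc:
            raise InvalidConfigError(f"{path}: {exc}") from exc
    return out


def write_scenario_table(scenarios: pd.DataFrame, path: str | Path) -> None:
    scenarios.to_csv(path, index=False)


# ---------------------------------------------------------------- catchment config

def read_catchment_config(path: str | Path) -> tuple[SyntheticCatchmentConfig, dict]:
    """Read the synthetic catchment config; returns (config, economy block).

    The optional ``economy`` block carries base_population, base_income and
    horizon_years for the cost normalisation.
    """
    path = Path(path)
    data = _load_structured(path)
    if not isinstance(data, Mapping):
        raise InvalidConfigError(f"{path}: expected a mapping")
    required = (
        "site", "baseline_medians", "spreads", "reductions",
        "scenario_multipliers", "climate_multipliers",
    )
    for key in required:
        if key not in data:
            raise InvalidConfigError(f"{path}: missing field {key!r}")
    cfg = SyntheticCatchmentConfig(
        site=data["site"],
        baseline_medians={k: float(v) for k, v in data["baseline_medians"].items()},
        spreads={k: float(v) for k, v in data["spreads"].items()},
        reductions={
            a: {k: float(v) for k, v in red.items()}
            for a, red in data["reductions"].items()
        },
        scenario_multipliers={
            s: {k: float(v) for k, v in (m or {}).items()}
            for s, m in data["scenario_multipliers"].items()
        },
        climate_multipliers={k: float(v) for k, v in data["climate_multipliers"].items()},
        n_draws=int(data.get("n_draws", 1000)),
        seed=data.get("seed"),
    )
    try:
        cfg.validate()
    except AquavalError as exc:
        raise InvalidConfigError(f"{path}: {exc}") from exc
    return cfg, dict(data.get("economy", {}))


def write_catchment_config(
    cfg: SyntheticCatchmentConfig, path: str | Path, economy: Mapping | None = None
) -> None:
    data: dict[str, Any] = {
        "site": cfg.site,
        "n_draws": cfg.n_draws,
        "baseline_medians": dict(cfg.baseline_medians),
        "spreads": dict(cfg.spreads),
        "reductions": {a: dict(r) for a, r in cfg.reductions.items()},
        "scenario_multipliers": {s: dict(m) for s, m in cfg.scenario_multipliers.items()},
        "climate_multipliers": dict(cfg.climate_multipliers),
    }
    if cfg.seed is not None:
        data["seed"] = cfg.seed
    if economy:
        data["economy"] = dict(economy)
    _dump_structured(data, Path(path))


# ---------------------------------------------------------------- attribute samples

SAMPLE_COLUMNS = ["site", "alternative", "scenario", "climate", "draw", "attribute", "level"]


def write_attribute_samples(
    samples: Mapping[Cell, AttributeSampleSet], path: str | Path
) -> None:
    """Long-format CSV of all draws for all cells."""
    frames = [ss.to_frame() for ss in samples.values()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_attribute_samples(path: str | Path) -> dict[Cell, AttributeSampleSet]:
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing column(s) {sorted(missing)}")
    out: dict[Cell, AttributeSampleSet] = {}
    for key, grp in df.groupby(["site", "alternative", "scenario", "climate"], sort=True):
        cell = Cell(*map(str, key))
        draws = {}
        for attr, g in grp.groupby("attribute", sort=True):
            draws[str(attr)] = g.sort_values("draw")["level"].to_numpy(dtype=float)
        out[cell] = AttributeSampleSet(cell, draws)
    return out


# ---------------------------------------------------------------- validation report

@dataclass(frozen=True)
class Violation:
    file: str
    field: str
    reason: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.file}: {self.field}: {self.reason}"


def validate_configs(
    value_functions: str | Path | None = None,
    hierarchy: str | Path | None = None,
    eqs: str | Path | None = None,
    costs: str | Path | None = None,
    scenarios: str | Path | None = None,
    catchment: str | Path | None = None,
) -> list[Violation]:
    """Validate any subset of config files; return all violations found.

    An empty list means every supplied file is valid. Errors are collected,
    not raised, so one bad file does not hide problems in another.
    """
    violations: list[Violation] = []
    vfs: dict[str, ValueFunction] = {}

    def _try(path, reader, label):
        if path is None:
            return None
        try:
            return reader(path)
        except FileNotFoundError:
            violations.append(Violation(str(path), label, "file not found"))
        except AquavalError as exc:
            violations.append(Violation(str(path), label, str(exc)))
        except Exception as exc:  # unreadable / unparsable
            violations.append(Violation(str(path), label, f"unreadable: {exc}"))
        return None

    loaded_vfs = _try(value_functions, read_value_functions, "value_functions")
    if loaded_vfs:
        vfs = loaded_vfs
    if hierarchy is not None:
        _try(hierarchy, lambda p: read_hierarchy(p, vfs), "hierarchy")
    _try(eqs, read_eqs_table, "eqs")
    _try(costs, read_cost_table, "costs")
    _try(scenarios, read_scenario_table, "scenarios")
    _try(catchment, read_catchment_config, "catchment")
    return violations


# ---------------------------------------------------------------- run manifest

@dataclass
class RunManifest:
    """Everything needed to reproduce one assessment run exactly."""

    config_dir: str
    output_dir: str
    seed: int
    n_draws: int
    interval_probs: tuple[float, float] = (0.05, 0.95)
    missing_policy: str = "renormalize"
    aggregation_override: dict | None = None
    tool_version: str = ""
    timestamp: str = ""

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["interval_probs"] = list(self.interval_probs)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        d["interval_probs"] = tuple(d["interval_probs"])
        return cls(**d)

    @staticmethod
    def now() -> str:
        return datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")
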