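"""Pesticide mixture risk: mode-of-action groups and risk quotients.

Pesticides acting through the same toxic mode of action (MoA) are assumed to
contribute additively to the same effect (concentration addition). Each
substance's exposure is normalized by its environmental quality standard
(EQS) and summed within the group:

    RQ_group = sum_i c_i / EQS_i

An RQ of 1 means the group sits exactly at the standard; the corresponding
value-scale anchor is 0.6 (the legal threshold). Chronic and acute EQS give
two quotients per group; the leaf value is by default the worse (minimum) of
the two translated values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .errors import InvalidConfigError, InvalidInputError, MissingDataError
from .valfun import ValueFunction, make_value_function

__all__ = [
    "MODES_OF_ACTION",
    "Substance",
    "GroupRisk",
    "risk_quotient",
    "group_risks",
    "make_rq_value_function",
    "rq_to_value",
    "moa_leaf_value",
]

#: The four toxic modes of action the assessment groups pesticides by.
MODES_OF_ACTION = (
    "photosynthesis_inhibition",
    "auxin_activity",
    "vlcfa_synthesis_inhibition",
    "acetylcholinesterase_inhibition",
)

#: Default worst-case risk quotient (value 0 anchor).
DEFAULT_WORST_CASE_RQ = 100.0


@dataclass(frozen=True)
class Substance:
    """A pesticide with its MoA group and quality standards (ug/L)."""

    name: str
    moa: str
    eqs_chronic: float
    eqs_acute: float

    def __post_init__(self) -> None:
        if self.moa not in MODES_OF_ACTION:
            raise InvalidConfigError(
                f"substance {self.name!r}: unknown mode of action {self.moa!r}"
            )
        if not (self.eqs_chronic > 0 and self.eqs_acute > 0):
            raise InvalidConfigError(
                f"substance {self.name!r}: EQS values must be > 0 "
                f"(chronic={self.eqs_chronic}, acute={self.eqs_acute})"
            )
        if self.eqs_acute < self.eqs_chronic:
            warnings.warn(
                f"substance {self.name!r}: acute EQS ({self.eqs_acute}) below chronic "
                f"({self.eqs_chronic}); acute standards are normally less strict",
                stacklevel=2,
            )


@dataclass(frozen=True)
class GroupRisk:
    """Chronic and acute risk quotients for one mode-of-action group."""

    moa: str
    rq_chronic: float
    rq_acute: float


def risk_quotient(
    concentrations: Mapping[str, float], eqs: Mapping[str, float]
) -> float:
    """Concentration-addition risk quotient: sum of c_i / EQS_i.

    Both maps are keyed by substance name and must cover the same substances.
    """
    missing = set(concentrations) - set(eqs)
    if missing:
        raise MissingDataError(
            f"no EQS for substance(s): {sorted(missing)}"
        )
    rq = 0.0
    for name, conc in concentrations.items():
        c = float(conc)
        e = float(eqs[name])
        if not math.isfinite(c) or c < 0:
            raise InvalidInputError(f"substance {name!r}: concentration must be >= 0")
        if e <= 0:
            raise InvalidConfigError(f"substance {name!r}: EQS must be > 0, got {e}")
        rq += c / e
    return rq


def group_risks(
    concentrations: Mapping[str, float], substances: Iterable[Substance]
) -> list[GroupRisk]:
    """Partition measured substances by MoA and compute group quotients.

    Returns one :class:`GroupRisk` per mode of action present among the
    measured substances, in :data:`MODES_OF_ACTION` order.
    """
    table = {s.name: s for s in substances}
    unknown = set(concentrations) - set(table)
    if unknown:
        raise MissingDataError(
            f"measured substance(s) absent from the substance table: {sorted(unknown)}"
        )
    out: list[GroupRisk] = []
    for moa in MODES_OF_ACTION:
        members = {n: c for n, c in concentrations.items() if table[n].moa == moa}
        if not members:
            continue
        rq_c = risk_quotient(members, {n: table[n].eqs_chronic for n in members})
        rq_a = risk_quotient(members, {n: table[n].eqs_acute for n in members})
        out.append(GroupRisk(moa, rq_c, rq_a))
    return out


def make_rq_value_function(
    attribute_id: str = "rq",
    worst_case_rq: float = DEFAULT_WORST_CASE_RQ,
) -> ValueFunction:
    """Value function translating a group risk quotient to the 0-1 scale.

    Anchors: RQ 0 -> 1 (no exposure) and RQ 1 -> 0.6 (exactly at the
    standard, i.e. the legal threshold). The remaining class boundaries are
    log-spaced between RQ 1 and the worst case (default 100), reflecting the
    multiplicative nature of exposure ratios; the value-0.8 boundary sits one
    half log-step below RQ 1.
    """
    if worst_case_rq <= 1.0:
        raise InvalidConfigError(
            f"worst-case risk quotient must exceed 1, got {worst_case_rq}"
        )
    step = math.log(worst_case_rq) / 3.0  # log spacing of the 3 bands above RQ=1
    boundaries = (
        math.exp(-step / 2.0),  # value 0.8
        1.0,                    # value 0.6, the legal threshold
        math.exp(step),         # value 0.4
        math.exp(2.0 * step),   # value 0.2
    )
    return make_value_function(attribute_id, boundaries, worst_case_rq, unit="")


_DEFAULT_RQ_VF = make_rq_value_function()


def rq_to_value(rq, vf: ValueFunction | None = None):
    """Translate a risk quotient (scalar or array) to the 0-1 value scale."""
    if vf is None:
        vf = _DEFAULT_RQ_VF
    arr = np.asarray(rq, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise InvalidInputError("risk quotient must be finite and >= 0")
    return vf(rq)


def moa_leaf_value(
    risk: GroupRisk,
    vf_chronic: ValueFunction | None = None,
    vf_acute: ValueFunction | None = None,
    mode: str = "min",
) -> float:
    """Combine a group's chronic and acute quotients into one leaf value.

    ``mode="min"`` (default): the worse of the two translated values governs.
    ``mode="chronic"``: chronic quotient only.
    """
    v_c = rq_to_value(risk.rq_chronic, vf_chronic)
    if mode == "chronic":
        return float(v_c)
    if mode != "min":
        raise InvalidConfigError(f"unknown chronic/acute combination mode {mode!r}")
    v_a = rq_to_value(risk.rq_acute, vf_acute)
    return float(min(v_c, v_a))
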