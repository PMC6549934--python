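"""Measurable value functions and quality classes.

A measurable value function translates a pollutant attribute level (e.g. an
NH4 concentration in mg/L, or a dimensionless risk quotient) into a value on
a continuous 0-1 scale: 1 means the objective is fully met (unpolluted
water), 0 the worst case to be expected. The continuous scale avoids the
discretisation error of purely categorical class schemes while remaining
translatable into the familiar five colour-coded quality classes
(high/good/moderate/poor/bad). The legal threshold — the concentration at
the good/moderate class boundary — is anchored at value 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidConfigError, InvalidInputError

__all__ = [
    "QualityClass",
    "QUALITY_CLASSES",
    "LEGAL_THRESHOLD_VALUE",
    "ValueFunction",
    "make_value_function",
    "make_binary_value_function",
    "evaluate_value",
    "classify",
]

#: Value on the 0-1 scale corresponding to the legal (good/moderate) threshold.
LEGAL_THRESHOLD_VALUE = 0.6


@dataclass(frozen=True)
class QualityClass:
    """One of the five colour-coded water-quality classes.

    The class covers the half-open value interval ``[lower, upper)`` except
    for *high*, which includes 1.0. A value exactly on a boundary belongs to
    the better class, so 0.6 (the legal threshold) is still *good*.
    """

    label: str
    lower: float
    upper: float
    color: str

    def contains(self, value: float) -> bool:
        if self.label == "bad":
            return self.lower <= value < self.upper
        return self.lower <= value <= self.upper


#: The five classes, best first; intervals partition [0, 1] exactly.
QUALITY_CLASSES: tuple[QualityClass, ...] = (
    QualityClass("high", 0.8, 1.0, "blue"),
    QualityClass("good", 0.6, 0.8, "green"),
    QualityClass("moderate", 0.4, 0.6, "yellow"),
    QualityClass("poor", 0.2, 0.4, "orange"),
    QualityClass("bad", 0.0, 0.2, "red"),
)

#: Class boundaries on the value scale, best-to-worst.
CLASS_BOUNDARY_VALUES: tuple[float, ...] = (0.8, 0.6, 0.4, 0.2)


@dataclass(frozen=True)
class ValueFunction:
    """Piecewise-linear, weakly decreasing map from attribute level to [0, 1].

    Parameters
    ----------
    attribute_id
        Identifier of the bound attribute (e.g. ``"NH4"``).
    unit
        Unit of the attribute levels (``"mg/L"``, ``"ug/L"`` or ``""`` for a
        dimensionless risk quotient).
    levels, values
        Breakpoint coordinates. Levels strictly increase; values start at 1
        (best case), weakly decrease, and end at 0 (worst case). Evaluation
        clamps outside the breakpoint range so results stay in [0, 1].
    """

    attribute_id: str
    unit: str
    levels: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=float)
        va = np.asarray(self.values, dtype=float)
        if lv.size != va.size or lv.size < 2:
            raise InvalidConfigError(
                f"value function {self.attribute_id!r}: need >= 2 matching breakpoints"
            )
        if not np.all(np.isfinite(lv)) or np.any(lv < 0):
            raise InvalidConfigError(
                f"value function {self.attribute_id!r}: levels must be finite and >= 0"
            )
        if np.any(np.diff(lv) <= 0):
            raise InvalidConfigError(
                f"value function {self.attribute_id!r}: breakpoint levels must strictly increase"
            )
        if np.any(va < 0) or np.any(va > 1):
            raise InvalidConfigError(
                f"value function {self.attribute_id!r}: breakpoint values must lie in [0, 1]"
            )
        if va[0] != 1.0 or va[-1] != 0.0:
            raise InvalidConfigError(
                f"value function {self.attribute_id!r}: first breakpoint value must be 1 "
                "(best case) and last 0 (worst case)"
            )
        if np.any(np.diff(va) > 0):
            raise InvalidConfigError(
                f"value function {self.attribute_id!r}: breakpoint values must weakly decrease"
            )

    def __call__(self, level):
        return evaluate_value(self, level)


def make_value_function(
    attribute_id: str,
    class_boundary_levels: Sequence[float],
    worst_case_level: float,
    unit: str = "mg/L",
) -> ValueFunction:
    """Build the standard six-breakpoint value function from class boundaries.

    The four class-boundary concentrations (high/good, good/moderate,
    moderate/poor, poor/bad) are mapped to values 0.8, 0.6, 0.4 and 0.2; a
    level of 0 maps to value 1 (unpolluted) and ``worst_case_level`` to 0.
    This is the piecewise-linear interpolation between class boundaries used
    for the nutrient attributes.
    """
    b = [float(x) for x in class_boundary_levels]
    if len(b) != 4:
        raise InvalidConfigError(
            f"{attribute_id!r}: exactly four class-boundary levels required, got {len(b)}"
        )
    levels = [0.0, *b, float(worst_case_level)]
    if any(x < 0 for x in levels):
        raise InvalidConfigError(f"{attribute_id!r}: attribute levels must be >= 0")
    if any(b2 <= b1 for b1, b2 in zip(levels, levels[1:])):
        raise InvalidConfigError(
            f"{attribute_id!r}: class boundaries must strictly increase and stay "
            f"below the worst case (got {levels})"
        )
    values = (1.0, *CLASS_BOUNDARY_VALUES, 0.0)
    return ValueFunction(attribute_id, unit, tuple(levels), values)


def make_binary_value_function(
    attribute_id: str,
    legal_threshold_level: float,
    worst_case_level: float,
    unit: str = "mg/L",
) -> ValueFunction:
    """Three-anchor value function for attributes with only a pass/fail criterion.

    Anchors: level 0 -> value 1 (best case), the legal threshold -> 0.6, and
    the worst case -> 0.
    """
    t, w = float(legal_threshold_level), float(worst_case_level)
    if not 0.0 < t < w:
        raise InvalidConfigError(
            f"{attribute_id!r}: need 0 < legal threshold < worst case (got {t}, {w})"
        )
    return ValueFunction(attribute_id, unit, (0.0, t, w), (1.0, LEGAL_THRESHOLD_VALUE, 0.0))


def evaluate_value(vf: ValueFunction, level):
    """Evaluate a value function at one level or an array of levels.

    Piecewise-linear interpolation through the breakpoints, clamped to the
    anchor values outside the breakpoint range; weakly decreasing in the
    level. Scalar in, scalar out; array in, array out.
    """
    arr = np.asarray(level, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(
            f"value function {vf.attribute_id!r}: attribute level must be finite"
        )
    if np.any(arr < 0):
        raise InvalidInputError(
            f"value function {vf.attribute_id!r}: attribute level must be >= 0"
        )
    out = np.interp(arr, vf.levels, vf.values)
    if np.isscalar(level) or arr.ndim == 0:
        return float(out)
    return out


def classify(value: float) -> QualityClass:
    """Return the quality class containing ``value``.

    A value exactly on a class boundary belongs to the better class, so the
    legal threshold 0.6 classifies as *good*.
    """
    v = float(value)
    if not np.isfinite(v) or v < 0.0 or v > 1.0:
        raise InvalidInputError(f"value {value!r} outside [0, 1]")
    for qc in QUALITY_CLASSES:
        if v >= qc.lower:
            return qc
    return QUALITY_CLASSES[-1]  # pragma: no cover - v >= 0 always matches "bad"
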