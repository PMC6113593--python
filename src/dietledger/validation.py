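"""Validation of calculated nutrients against chemical reference values.

Calculated nutrient content C = {c_1 .. c_n} for a 100 g dish is compared
with chemical measurements M = {m_1 .. m_x} (e.g. Kjeldahl nitrogen for
protein, acid hydrolysis for fat) using the absolute percentage deviation
per nutrient:

    MAPD_x = |c_x - m_x| / m_x * 100

The deviation is undefined when the measured value is zero (a both-zero
carbohydrate cell renders as an em dash, not 0); a calculated zero against
a positive measurement gives exactly 100. Values display at two decimals
(half-up) while full precision is retained internally. Note the formula
is deliberately asymmetric in (c, m): the measurement is the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ._util import normalize_name, round_half_up
from .errors import EmptyComparisonError
from .food_knowledge import FoodCompositionTable, NutrientVector, RecipeDatabase
from .nutrient_engine import nutrient_content_per_100g

#: Rendered in place of a deviation whose measured baseline is zero.
UNDEFINED = "—"


@dataclass(frozen=True)
class ReferenceMeasurement:
    """Chemically measured nutrient amounts per 100 g of one dish."""

    dish: str
    measured: Mapping[str, float]
    methods: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "dish", normalize_name(self.dish))
        for nutrient, value in self.measured.items():
            if value < 0:
                raise ValueError(f"negative measured amount for {nutrient!r}")


def percentage_deviation(calculated: float, measured: float) -> float | None:
    """|c - m| / m * 100, or None when the measured baseline is zero."""
    if measured == 0:
        return None
    return abs(calculated - measured) / measured * 100.0


@dataclass(frozen=True)
class DeviationRow:
    nutrient: str
    calculated: float
    measured: float
    mapd: float | None  # full precision; None = undefined (measured == 0)

    @property
    def mapd_display(self) -> str:
        if self.mapd is None:
            return UNDEFINED
        return f"{round_half_up(self.mapd, 2):.2f}"


@dataclass(frozen=True)
class DeviationReport:
    """Per-nutrient calculated/measured/deviation rows for one dish."""

    dish: str
    rows: tuple[DeviationRow, ...]

    def __getitem__(self, nutrient: str) -> DeviationRow:
        for row in self.rows:
            if row.nutrient == nutrient:
                return row
        raise KeyError(nutrient)

    def mean_deviation(self) -> float | None:
        """Mean over the defined per-nutrient deviations (None if none)."""
        defined = [r.mapd for r in self.rows if r.mapd is not None]
        if not defined:
            return None
        return sum(defined) / len(defined)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.nutrient, r.calculated, r.measured, r.mapd_display)
                for r in self.rows
            ],
            columns=["nutrient", "calculated", "measured", "mapd_pct"],
        )


def mapd(
    calculated: NutrientVector | Mapping[str, float],
    measured: ReferenceMeasurement,
) -> DeviationReport:
    """Compare a calculated nutrient vector with a reference measurement.

    One row per nutrient present (and defined) on both sides, in the
    calculated vector's order. Raises :class:`EmptyComparisonError` when
    no nutrient is shared.
    """
    rows: list[DeviationRow] = []
    for nutrient in calculated:
        c = calculated[nutrient]
        if c is None or nutrient not in measured.measured:
            continue
        m = float(measured.measured[nutrient])
        rows.append(DeviationRow(nutrient, float(c), m, percentage_deviation(float(c), m)))
    if not rows:
        raise EmptyComparisonError(
            f"no shared nutrients between calculation and reference for {measured.dish!r}"
        )
    return DeviationReport(dish=measured.dish, rows=tuple(rows))


def load_reference_measurements(source: str | Path) -> list[ReferenceMeasurement]:
    """Read reference measurements from a long-format CSV.

    Columns: ``dish, nutrient, measured_per_100g, method`` (method may be
    empty). Rows group by dish in first-appearance order.
    """
    df = pd.read_csv(source, dtype={"dish": str, "nutrient": str, "method": str})
    grouped: dict[str, tuple[dict, dict]] = {}
    for row in df.itertuples(index=False):
        dish = normalize_name(row.dish)
        measured, methods = grouped.setdefault(dish, ({}, {}))
        measured[row.nutrient] = float(row.measured_per_100g)
        method = getattr(row, "method", None)
        if isinstance(method, str) and method.strip():
            methods[row.nutrient] = method.strip()
    return [
        ReferenceMeasurement(dish, measured, methods)
        for dish, (measured, methods) in grouped.items()
    ]


def validate_against_fixture(
    recipes: RecipeDatabase,
    table: FoodCompositionTable,
    references: Iterable[ReferenceMeasurement],
    *,
    calculated: Mapping[str, NutrientVector] | None = None,
    include_auxiliary: bool = False,
) -> list[DeviationReport]:
    """One deviation report per reference dish.

    With ``calculated`` supplied (a dish -> per-100 g vector mapping, the
    printed-pairs replication mode) the vectors are used directly;
    otherwise each dish's per-100 g content is computed from its recipe,
    and an unknown dish raises a lookup error.
    """
    reports: list[DeviationReport] = []
    for ref in references:
        if calculated is not None and ref.dish in calculated:
            vector = calculated[ref.dish]
        else:
            vector = nutrient_content_per_100g(
                recipes[ref.dish], table, include_auxiliary=include_auxiliary
            )
        reports.append(mapd(vector, ref))
    return reports
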