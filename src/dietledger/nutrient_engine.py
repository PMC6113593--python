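"""Dish decomposition and nutrient calculation.

Given a dish of known recipe and a serving weight, the engine scales the
recipe's raw ingredient weights proportionally to the serving, looks up
each ingredient's per-100 g nutrient amounts, and sums the weighted
contributions. Intakes aggregate per consumer, per consumer-day, or per
population-day.

Basis and conventions
---------------------
* Per-100 g values are on a *raw-weight* basis: the recipe's raw weights
  are normalized to 100 g of total counted raw weight. No cooking yield,
  water-loss or nutrient-retention correction is applied.
* Auxiliary (condiment-scale) ingredients are excluded by default and
  opted in with ``include_auxiliary=True``.
* A nutrient absent for any contributing ingredient is absent in the
  result, with a warning note — never silently treated as zero.
* Sums run over ingredients in sorted-name order, so results are
  bit-reproducible regardless of recipe listing order.
"""

from __future__ import annotations

import datetime as dt
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from .errors import DegenerateRecipeError, IngredientLookupError
from .food_knowledge import (
    FoodCompositionTable,
    NutrientVector,
    Recipe,
    RecipeDatabase,
)
from .plate_events import PlateEvent


def decompose_dish(
    recipe: Recipe,
    serving_weight: float,
    *,
    include_auxiliary: bool = False,
) -> list[tuple[str, float]]:
    """Scale a recipe's ingredient weights to one serving.

    Each counted ingredient receives serving weight in proportion to its
    raw recipe weight; the scaled weights sum to ``serving_weight``.
    Ingredients listed twice are merged. Output is sorted by ingredient
    name.
    """
    if not serving_weight > 0:
        raise ValueError(f"serving weight must be positive, got {serving_weight}")
    weights: dict[str, float] = defaultdict(float)
    for ing in recipe.ingredients:
        if ing.auxiliary and not include_auxiliary:
            continue
        weights[ing.name] += ing.weight_g
    total = sum(weights.values())
    if total <= 0:
        raise DegenerateRecipeError(
            f"recipe {recipe.name!r} has zero counted ingredient weight"
        )
    return [
        (name, weights[name] / total * serving_weight) for name in sorted(weights)
    ]


def nutrient_content_per_100g(
    recipe: Recipe,
    table: FoodCompositionTable,
    *,
    include_auxiliary: bool = False,
) -> NutrientVector:
    """Nutrient content of 100 g of the dish (raw-weight basis).

    For nutrient x: c_x = sum over ingredients i of
    (scaled weight_i / 100 g) x (amount of x per 100 g of i).
    Nutrients absent for any contributing ingredient come back absent,
    with one warning per (nutrient, ingredient) pair.
    """
    parts = decompose_dish(recipe, 100.0, include_auxiliary=include_auxiliary)
    for name, _ in parts:
        if name not in table:
            raise IngredientLookupError(name)

    values: dict[str, float | None] = {}
    warnings: list[str] = []
    for nutrient in table.nutrient_names:
        acc: float | None = 0.0
        for name, grams in parts:  # parts already name-sorted
            amount = table[name].nutrients.get(nutrient)
            if amount is None:
                warnings.append(f"{nutrient}: absent for ingredient {name!r}")
                acc = None
            elif acc is not None:
                acc += grams / 100.0 * amount
        values[nutrient] = acc
    return NutrientVector(values, warnings=tuple(warnings))


@dataclass(frozen=True)
class IntakeRecord:
    """Nutrients of one consumed serving (absolute amounts, not per-100 g)."""

    consumer_id: str
    date: dt.date
    dish_name: str
    serving_weight_g: float
    nutrients: NutrientVector


@dataclass(frozen=True)
class IntakeSeries:
    """One consumer's daily aggregated intake over an observation window."""

    consumer_id: str
    entries: tuple[tuple[dt.date, NutrientVector], ...]

    def __post_init__(self) -> None:
        dates = [d for d, _ in self.entries]
        if any(a >= b for a, b in zip(dates, dates[1:])):
            raise ValueError("intake series dates must be strictly increasing")

    def __len__(self) -> int:
        return len(self.entries)

    def dates(self) -> tuple[dt.date, ...]:
        return tuple(d for d, _ in self.entries)

    def total(self) -> NutrientVector:
        return _sum_vectors(v for _, v in self.entries)


def _sum_vectors(vectors: Iterable[NutrientVector]) -> NutrientVector:
    acc: NutrientVector | None = None
    for v in vectors:
        acc = v if acc is None else acc + v
    if acc is None:
        raise ValueError("cannot sum zero nutrient vectors")
    return acc


def intake_for_event(
    event: PlateEvent,
    recipes: RecipeDatabase,
    table: FoodCompositionTable,
    *,
    include_auxiliary: bool = False,
) -> IntakeRecord:
    """Nutrient intake from one plate event: per-100 g content x weight/100."""
    per100 = nutrient_content_per_100g(
        recipes[event.dish_name], table, include_auxiliary=include_auxiliary
    )
    return IntakeRecord(
        consumer_id=event.consumer_id,
        date=event.date,
        dish_name=event.dish_name,
        serving_weight_g=event.serving_weight_g,
        nutrients=per100.scale(event.serving_weight_g / 100.0),
    )


GroupBy = Literal["consumer", "consumer+date", "population+date"]


def aggregate_intake(
    records: Iterable[IntakeRecord],
    by: GroupBy = "consumer+date",
):
    """Group-sum intake records.

    ``consumer``        -> dict consumer_id -> total NutrientVector
    ``consumer+date``   -> dict consumer_id -> IntakeSeries
    ``population+date`` -> list of (date, NutrientVector), date-sorted

    Records are pre-sorted on a stable key so the floating-point sums do
    not depend on input order. Absence propagates: if any summand lacks a
    nutrient, the group total lacks it too.
    """
    recs = sorted(
        records,
        key=lambda r: (r.consumer_id, r.date.isoformat(), r.dish_name, r.serving_weight_g),
    )
    if by == "consumer":
        out: dict[str, NutrientVector] = {}
        for r in recs:
            out[r.consumer_id] = (
                r.nutrients if r.consumer_id not in out else out[r.consumer_id] + r.nutrients
            )
        return out
    if by == "consumer+date":
        grouped: dict[str, dict[dt.date, NutrientVector]] = defaultdict(dict)
        for r in recs:
            days = grouped[r.consumer_id]
            days[r.date] = r.nutrients if r.date not in days else days[r.date] + r.nutrients
        return {
            cid: IntakeSeries(cid, tuple(sorted(days.items())))
            for cid, days in grouped.items()
        }
    if by == "population+date":
        by_date: dict[dt.date, NutrientVector] = {}
        for r in recs:
            by_date[r.date] = (
                r.nutrients if r.date not in by_date else by_date[r.date] + r.nutrients
            )
        return sorted(by_date.items())
    raise ValueError(f"unknown grouping: {by!r}")


def intake_table(
    records: Iterable[IntakeRecord],
    by: GroupBy = "consumer+date",
) -> pd.DataFrame:
    """Aggregated intake as a flat DataFrame (for CSV export)."""
    rows: list[dict] = []
    grouped = aggregate_intake(records, by=by)
    if by == "consumer":
        for cid, vec in sorted(grouped.items()):
            rows.append({"consumer_id": cid, **vec.to_dict()})
    elif by == "consumer+date":
        for cid, series in sorted(grouped.items()):
            for date, vec in series.entries:
                rows.append(
                    {"consumer_id": cid, "date": date.isoformat(), **vec.to_dict()}
                )
    else:
        for date, vec in grouped:
            rows.append({"date": date.isoformat(), **vec.to_dict()})
    return pd.DataFrame(rows)
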