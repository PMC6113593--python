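"""Population- and individual-level dietary reports.

Distribution reports tally unique dishes (or, optionally, raw events) by
dish type, preparation method, or ingredient food group; frequency tables
count how often one consumer chose each dish over a window. Percentages
are displayed at one decimal (half-up); the raw counts are always carried
alongside so the rounding is recoverable.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from ._util import normalize_name, percentage
from .food_knowledge import (
    CATEGORIES,
    DISH_TYPES,
    METHODS,
    FoodCompositionTable,
    RecipeDatabase,
)
from .plate_events import PlateEvent


@dataclass(frozen=True)
class DistributionRow:
    label: str
    count: int
    percentage: float


@dataclass(frozen=True)
class DistributionReport:
    """Labeled counts with display percentages over a stated denominator.

    Rows are ordered by descending count, ties broken alphabetically.
    Counts sum exactly to ``total``; percentages are rounded to one
    decimal so their sum may drift from 100.0 by at most 0.05 per row.
    """

    rows: tuple[DistributionRow, ...]
    total: int
    denominator: str

    def __post_init__(self) -> None:
        if sum(r.count for r in self.rows) != self.total:
            raise ValueError("distribution counts do not sum to the total")

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, int], denominator: str
    ) -> "DistributionReport":
        total = sum(counts.values())
        if total == 0:
            return cls(rows=(), total=0, denominator=denominator)
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        rows = tuple(
            DistributionRow(label, count, percentage(count, total))
            for label, count in ordered
        )
        return cls(rows=rows, total=total, denominator=denominator)

    def __getitem__(self, label: str) -> DistributionRow:
        for row in self.rows:
            if row.label == label:
                return row
        raise KeyError(label)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.label, r.count, r.percentage) for r in self.rows],
            columns=["label", "count", "percentage"],
        )

    def to_dict(self) -> dict:
        return {
            "denominator": self.denominator,
            "total": self.total,
            "rows": [
                {"label": r.label, "count": r.count, "percentage": r.percentage}
                for r in self.rows
            ],
        }


def _dish_pool(dishes: Iterable[str], unique: bool) -> list[str]:
    names = [normalize_name(d) for d in dishes]
    if unique:
        return sorted(set(names))
    return names


def dish_type_distribution(
    dishes: Iterable[str],
    recipes: RecipeDatabase,
    *,
    unique: bool = True,
) -> DistributionReport:
    """Share of staple / cooked / porridge-soup dishes.

    By default the denominator is the number of *unique* dishes; set
    ``unique=False`` for an events-weighted variant. Zero-count types are
    still listed.
    """
    counts = {t: 0 for t in DISH_TYPES}
    for dish in _dish_pool(dishes, unique):
        counts[recipes[dish].dish_type] += 1
    return DistributionReport.from_counts(counts, denominator="unique dishes" if unique else "events")


def preparation_method_distribution(
    dishes: Iterable[str],
    recipes: RecipeDatabase,
    *,
    restrict_to: str | None = "cooked",
    unique: bool = True,
) -> DistributionReport:
    """Share of preparation methods, by default among cooked dishes only.

    Pass ``restrict_to=None`` (or ``"all"``) to tally every dish type.
    """
    pool = _dish_pool(dishes, unique)
    if restrict_to not in (None, "all"):
        pool = [d for d in pool if recipes[d].dish_type == restrict_to]
    if not pool:
        return DistributionReport.from_counts({}, denominator="unique dishes")
    counts = {m: 0 for m in METHODS}
    for dish in pool:
        counts[recipes[dish].method] += 1
    scope = restrict_to if restrict_to not in (None, "all") else "all"
    return DistributionReport.from_counts(
        counts, denominator=f"unique {scope} dishes" if unique else f"{scope} events"
    )


def ingredient_category_distribution(
    dishes: Iterable[str],
    recipes: RecipeDatabase,
    table: FoodCompositionTable,
    *,
    include_auxiliary: bool = False,
) -> DistributionReport:
    """Food-group shares among the distinct ingredient kinds of a dish set.

    An ingredient appearing in many dishes counts once; the denominator is
    the number of distinct ingredient kinds across the union of the
    dishes' counted ingredients.
    """
    kinds: set[str] = set()
    for dish in _dish_pool(dishes, unique=True):
        for ing in recipes[dish].ingredients:
            if ing.auxiliary and not include_auxiliary:
                continue
            kinds.add(ing.name)
    if not kinds:
        return DistributionReport.from_counts({}, denominator="distinct ingredient kinds")
    counts = {c: 0 for c in CATEGORIES}
    for name in sorted(kinds):
        counts[table[name].category] += 1
    return DistributionReport.from_counts(counts, denominator="distinct ingredient kinds")


@dataclass(frozen=True)
class FrequencyTable:
    """How often one consumer chose each dish within a date window."""

    consumer_id: str
    start: dt.date
    end: dt.date
    rows: tuple[tuple[str, int], ...]

    def __getitem__(self, dish: str) -> int:
        key = normalize_name(dish)
        for name, count in self.rows:
            if name == key:
                return count
        return 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["dish_name", "times_chosen"])


def food_frequency(
    events: Iterable[PlateEvent],
    consumer: str,
    window: tuple[dt.date, dt.date],
) -> FrequencyTable:
    """Count one consumer's dish choices within ``[start, end]`` inclusive.

    Rows come back in descending count order, ties alphabetical. An
    unknown consumer yields an empty table.
    """
    start, end = window
    counts: dict[str, int] = {}
    for e in events:
        if e.consumer_id == consumer and start <= e.date <= end:
            counts[e.dish_name] = counts.get(e.dish_name, 0) + 1
    rows = tuple(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    return FrequencyTable(consumer_id=consumer, start=start, end=end, rows=rows)
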