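"""Plate-event ingestion and the four-stage record selection procedure.

A *plate event* is the atomic dietary record: one consumer taking one
RFID-tagged plate of one dish at one meal. The chip on the plate carries
dish name, price and serving weight; the checkout reader joins those with
the consumer ID and meal time.

Before analysis, records pass a four-stage selection filter:

1. ``lunchtime-only``      — the record's meal slot is the one analyzed;
2. ``on-rfid-plate``       — the plate type is a valid RFID plate (1-3);
3. ``recipe-known``        — the dish resolves in the recipe database;
4. ``ingredients-covered`` — every counted recipe ingredient resolves in
   the composition table.

Filtering is total and order-preserving; every stage only removes records.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

from ._util import normalize_name
from .errors import SchemaError
from .food_knowledge import (
    FoodCompositionTable,
    RecipeDatabase,
    validate_recipe_coverage,
)

MEAL_SLOTS: tuple[str, ...] = ("breakfast", "lunch", "supper")

#: Plate types: 1 carries staple foods, 2 cooked dishes, 3 soups.
PLATE_TYPES: tuple[int, ...] = (1, 2, 3)

EVENT_COLUMNS: tuple[str, ...] = (
    "consumer_id",
    "dish_name",
    "plate_type",
    "serving_weight_g",
    "price",
    "meal_slot",
    "date",
)

#: Half-open clock-time windows for classifying timestamped records.
DEFAULT_MEAL_WINDOWS: dict[str, tuple[dt.time, dt.time]] = {
    "breakfast": (dt.time(6, 0), dt.time(10, 0)),
    "lunch": (dt.time(11, 0), dt.time(14, 0)),
    "supper": (dt.time(17, 0), dt.time(21, 0)),
}

FILTER_STAGES: tuple[str, ...] = (
    "lunchtime-only",
    "on-rfid-plate",
    "recipe-known",
    "ingredients-covered",
)


@dataclass(frozen=True)
class PlateEvent:
    """One consumption record read from an RFID plate at checkout.

    The dataclass itself is a faithful record and does not enforce field
    invariants: :func:`parse_events` validates file input, and the
    selection filters are responsible for screening in-memory streams
    (an event with an invalid plate type is exactly what filter stage 2
    exists to remove).
    """

    consumer_id: str
    dish_name: str
    plate_type: int
    serving_weight_g: float
    price: float
    meal_slot: str
    date: dt.date

    def __post_init__(self) -> None:
        object.__setattr__(self, "dish_name", normalize_name(self.dish_name))


@dataclass(frozen=True)
class RejectedEvent:
    """An input row that failed validation, with its file line and reason."""

    line: int
    reason: str
    raw: str


class ParseResult(NamedTuple):
    events: list[PlateEvent]
    rejects: list[RejectedEvent]


def meal_slot_from_time(
    t: dt.time,
    windows: dict[str, tuple[dt.time, dt.time]] = DEFAULT_MEAL_WINDOWS,
) -> str | None:
    """Classify a clock time into a meal slot, or None outside all windows."""
    for slot, (start, end) in windows.items():
        if start <= t < end:
            return slot
    return None


def _validate_row(row: dict[str, str]) -> tuple[PlateEvent | None, str | None]:
    consumer = row["consumer_id"].strip()
    if not consumer:
        return None, "consumer_id"
    dish = row["dish_name"].strip()
    if not dish:
        return None, "dish_name"
    try:
        plate = int(row["plate_type"])
    except ValueError:
        return None, "plate_type"
    if plate not in PLATE_TYPES:
        return None, "plate_type"
    try:
        weight = float(row["serving_weight_g"])
    except ValueError:
        return None, "serving_weight"
    if not weight > 0:
        return None, "serving_weight"
    try:
        price = float(row["price"])
    except ValueError:
        return None, "price"
    if price < 0:
        return None, "price"
    slot = row["meal_slot"].strip().casefold()
    if slot not in MEAL_SLOTS:
        return None, "meal_slot"
    try:
        date = dt.date.fromisoformat(row["date"].strip())
    except ValueError:
        return None, "date"
    return (
        PlateEvent(consumer, dish, plate, weight, price, slot, date),
        None,
    )


def parse_events(source: str | Path) -> ParseResult:
    """Read plate events from a CSV file.

    Returns valid events in input order plus a rejects report carrying the
    file line and field responsible for each invalid row — rows are never
    silently dropped. If more than half of the rows are rejected the file
    is presumed schema-mismatched and a :class:`SchemaError` is raised.
    """
    path = Path(source)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"events file missing required column: {col!r}")

    events: list[PlateEvent] = []
    rejects: list[RejectedEvent] = []
    for idx, row in enumerate(df.to_dict(orient="records")):
        line = idx + 2
        event, reason = _validate_row(row)
        if event is None:
            rejects.append(RejectedEvent(line, reason or "unknown", ",".join(row.values())))
        else:
            events.append(event)

    total = len(events) + len(rejects)
    if total and len(rejects) > total / 2:
        raise SchemaError(
            f"{len(rejects)}/{total} rows rejected; input likely has a mismatched schema"
        )
    return ParseResult(events, rejects)


def write_events_csv(events: Iterable[PlateEvent], target: str | Path) -> None:
    """Write plate events to CSV in the canonical column order."""
    df = pd.DataFrame(
        [
            {
                "consumer_id": e.consumer_id,
                "dish_name": e.dish_name,
                "plate_type": e.plate_type,
                "serving_weight_g": e.serving_weight_g,
                "price": e.price,
                "meal_slot": e.meal_slot,
                "date": e.date.isoformat(),
            }
            for e in events
        ],
        columns=list(EVENT_COLUMNS),
    )
    df.to_csv(target, index=False, encoding="utf-8")


class FilterStage(NamedTuple):
    name: str
    entering: int
    surviving: int


@dataclass(frozen=True)
class FilterReport:
    """Per-stage record counts for one run of the selection filters."""

    meal: str
    stages: tuple[FilterStage, ...]

    def __post_init__(self) -> None:
        for stage in self.stages:
            if stage.surviving > stage.entering:
                raise ValueError(f"stage {stage.name!r} gained records")
        for a, b in zip(self.stages, self.stages[1:]):
            if a.surviving != b.entering:
                raise ValueError(
                    f"stage chain broken between {a.name!r} and {b.name!r}"
                )

    def to_dict(self) -> dict:
        return {
            "meal": self.meal,
            "stages": [
                {"name": s.name, "entering": s.entering, "surviving": s.surviving}
                for s in self.stages
            ],
        }


def apply_selection_filters(
    events: Iterable[PlateEvent],
    recipes: RecipeDatabase,
    table: FoodCompositionTable,
    meal: str = "lunch",
    *,
    include_auxiliary: bool = False,
) -> tuple[list[PlateEvent], FilterReport]:
    """Apply the four selection stages and report per-stage counts.

    Order is preserved; identical input yields an identical report.
    """
    current = list(events)
    stages: list[FilterStage] = []

    def run(name: str, keep) -> None:
        nonlocal current
        entering = len(current)
        current = [e for e in current if keep(e)]
        stages.append(FilterStage(name, entering, len(current)))

    coverage_ok: dict[str, bool] = {}

    def covered(dish: str) -> bool:
        if dish not in coverage_ok:
            coverage_ok[dish] = not validate_recipe_coverage(
                recipes[dish], table, include_auxiliary=include_auxiliary
            )
        return coverage_ok[dish]

    run(FILTER_STAGES[0], lambda e: e.meal_slot == meal)
    run(FILTER_STAGES[1], lambda e: e.plate_type in PLATE_TYPES)
    run(FILTER_STAGES[2], lambda e: e.dish_name in recipes)
    run(FILTER_STAGES[3], lambda e: covered(e.dish_name))

    return current, FilterReport(meal=meal, stages=tuple(stages))
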