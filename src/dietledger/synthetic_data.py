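"""Seeded synthetic menus, composition tables, and plate-event streams.

Real restaurant event streams of the kind this package processes are not
publicly deposited, so every other module is exercised against generated
data: a menu of recipes over the three dish types, a composition table
fully covering that menu, and a multi-week lunchtime event stream from a
population of consumers, each with their own categorical dish-preference
distribution. Corruptions can be injected at a configured rate, one per
affected event, drawn from a taxonomy that mirrors the four selection
filter stages — so filter tests have exact planted ground truth.

All generators are pure functions of (config, seed): the same seed yields
byte-identical output.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .food_knowledge import (
    CATEGORIES,
    CORE_NUTRIENTS,
    FoodCompositionTable,
    IngredientComposition,
    NutrientVector,
    Recipe,
    RecipeDatabase,
    RecipeIngredient,
    load_recipe_db,
)
from .plate_events import PlateEvent
from .validation import ReferenceMeasurement, load_reference_measurements

#: The full 23-nutrient column set emulating a national food-composition table.
FULL_NUTRIENT_SET: tuple[str, ...] = CORE_NUTRIENTS + (
    "vitamin_a_ug",
    "carotene_ug",
    "vitamin_b1_mg",
    "vitamin_b2_mg",
    "niacin_mg",
    "vitamin_c_mg",
    "vitamin_e_mg",
    "calcium_mg",
    "phosphorus_mg",
    "potassium_mg",
    "sodium_mg",
    "magnesium_mg",
    "iron_mg",
    "zinc_mg",
    "selenium_ug",
    "copper_mg",
    "manganese_mg",
    "cholesterol_mg",
)

CORRUPTION_KINDS: tuple[str, ...] = (
    "meal_slot",
    "plate_type",
    "unknown_dish",
    "missing_ingredient",
)

#: Dish planted (only under corruption) whose recipe names an ingredient
#: deliberately missing from the generated composition table.
UNCOVERED_DISH = "chef special stew"
UNCOVERED_INGREDIENT = "dragon fruit peel"

AUXILIARY_POOL: tuple[str, ...] = ("ginger", "garlic", "scallion")

_CATEGORY_STEMS: dict[str, str] = {
    "vegetables and vegetable products": "vegetable",
    "tubers, starches and their products": "tuber",
    "meat and meat products": "meat",
    "poultry and poultry products": "poultry",
    "fungi and algae": "fungus",
    "fish, shellfish and molluscs": "fish",
    "cereals": "cereal",
    "legumes": "legume",
    "eggs": "egg",
    "fruits": "fruit",
    "other": "misc",
}

# Relative pool sizes across food groups, loosely matching the makeup of a
# Chinese canteen's ingredient inventory (vegetables dominate).
_CATEGORY_WEIGHTS: dict[str, float] = {
    "vegetables and vegetable products": 0.22,
    "tubers, starches and their products": 0.10,
    "meat and meat products": 0.13,
    "poultry and poultry products": 0.10,
    "fungi and algae": 0.10,
    "fish, shellfish and molluscs": 0.11,
    "cereals": 0.07,
    "legumes": 0.06,
    "eggs": 0.03,
    "fruits": 0.05,
    "other": 0.03,
}

# Macronutrient sampling ranges (g per 100 g edible portion) per group.
_MACRO_PROFILES: dict[str, tuple[tuple[float, float], ...]] = {
    # (protein, fat, carbohydrate, fiber)
    "vegetables and vegetable products": ((0.5, 3.0), (0.1, 1.0), (2.0, 8.0), (0.5, 3.0)),
    "tubers, starches and their products": ((1.0, 3.0), (0.1, 1.0), (15.0, 25.0), (0.5, 2.0)),
    "meat and meat products": ((15.0, 25.0), (5.0, 35.0), (0.0, 2.0), (0.0, 0.0)),
    "poultry and poultry products": ((15.0, 22.0), (5.0, 20.0), (0.0, 2.0), (0.0, 0.0)),
    "fungi and algae": ((1.5, 4.0), (0.1, 1.0), (2.0, 7.0), (1.0, 4.0)),
    "fish, shellfish and molluscs": ((15.0, 22.0), (1.0, 10.0), (0.0, 2.0), (0.0, 0.0)),
    "cereals": ((7.0, 13.0), (1.0, 4.0), (60.0, 78.0), (1.0, 5.0)),
    "legumes": ((18.0, 36.0), (1.0, 18.0), (20.0, 60.0), (4.0, 12.0)),
    "eggs": ((11.0, 14.0), (8.0, 12.0), (1.0, 3.0), (0.0, 0.0)),
    "fruits": ((0.3, 1.5), (0.1, 0.5), (8.0, 20.0), (1.0, 4.0)),
    "other": ((0.0, 10.0), (0.0, 40.0), (0.0, 60.0), (0.0, 3.0)),
}

# Method mix for cooked dishes; stir-frying dominates in this cuisine.
_COOKED_METHODS = ("stir-fry", "steam", "boil", "roast", "deep-fry", "braise", "raw", "other")
_COOKED_METHOD_P = (0.45, 0.12, 0.10, 0.08, 0.10, 0.10, 0.02, 0.03)

#: Serving-weight range in grams per plate type (1 staple, 2 cooked, 3 soup).
DEFAULT_SERVING_RANGES: dict[int, tuple[float, float]] = {
    1: (100.0, 250.0),
    2: (150.0, 300.0),
    3: (200.0, 400.0),
}

_PRICE_PER_100G = {1: 1.0, 2: 2.5, 3: 1.2}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated restaurant deployment.

    Defaults emulate a canteen observed over lunchtimes starting
    2016-01-05: 50 consumers over 30 days with a 50-dish menu — the same
    code paths as the full deployment at a scale suited to routine runs.
    """

    n_consumers: int = 50
    start_date: dt.date = dt.date(2016, 1, 5)
    n_days: int = 30
    working_days_only: bool = False
    meal_slots: tuple[str, ...] = ("lunch",)
    menu_size: Mapping[str, int] = field(
        default_factory=lambda: {"staple": 8, "cooked": 38, "porridge_soup": 4}
    )
    n_ingredients: int = 80
    plates_per_meal: int = 1
    serving_ranges: Mapping[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SERVING_RANGES)
    )
    #: Optional pinned preference weights: consumer id -> {dish: weight}.
    preference_weights: Mapping[str, Mapping[str, float]] | None = None
    #: Probability that a non-core nutrient cell is absent (not measured).
    missing_nutrient_rate: float = 0.03
    corruption_rate: float = 0.0
    corruption_kinds: tuple[str, ...] = CORRUPTION_KINDS
    seed: int = 0


@dataclass(frozen=True)
class Corruption:
    """Ledger entry: which event was corrupted and how."""

    index: int
    kind: str


@dataclass(frozen=True)
class SimulatedEvents:
    events: list[PlateEvent]
    corruptions: tuple[Corruption, ...]

    def corrupted_indices(self) -> set[int]:
        return {c.index for c in self.corruptions}


def working_days(start: dt.date, n: int) -> list[dt.date]:
    """The first `n` Monday-Friday dates on or after `start`."""
    days: list[dt.date] = []
    day = start
    while len(days) < n:
        if day.weekday() < 5:
            days.append(day)
        day += dt.timedelta(days=1)
    return days


def _simulation_days(config: SimulationConfig) -> list[dt.date]:
    if config.working_days_only:
        return working_days(config.start_date, config.n_days)
    return [config.start_date + dt.timedelta(days=i) for i in range(config.n_days)]


def _ingredient_pool(config: SimulationConfig, rng: np.random.Generator) -> list[IngredientComposition]:
    # Deterministic per-category allocation: proportional, at least 2 each.
    n = max(config.n_ingredients, 2 * len(CATEGORIES))
    counts = {c: max(2, int(n * w)) for c, w in _CATEGORY_WEIGHTS.items()}
    while sum(counts.values()) > n:
        biggest = max(CATEGORIES, key=lambda c: counts[c])
        counts[biggest] -= 1
    while sum(counts.values()) < n:
        counts["vegetables and vegetable products"] += 1

    entries: list[IngredientComposition] = []
    for category in CATEGORIES:
        (p_rng, f_rng, c_rng, fib_rng) = _MACRO_PROFILES[category]
        stem = _CATEGORY_STEMS[category]
        for i in range(counts[category]):
            protein = rng.uniform(*p_rng)
            fat = rng.uniform(*f_rng)
            carb = rng.uniform(*c_rng)
            fiber = rng.uniform(*fib_rng)
            values: dict[str, float | None] = {
                "energy_kcal": 4.0 * protein + 9.0 * fat + 4.0 * carb,
                "protein_g": protein,
                "fat_g": fat,
                "carbohydrate_g": carb,
                "fiber_g": fiber,
            }
            for nutrient in FULL_NUTRIENT_SET[len(CORE_NUTRIENTS):]:
                if rng.random() < config.missing_nutrient_rate:
                    values[nutrient] = None
                else:
                    values[nutrient] = float(rng.uniform(0.0, 50.0))
            entries.append(
                IngredientComposition(f"{stem} {i + 1:04d}", category, NutrientVector(values))
            )
    # Fixed condiment-scale ingredients used as auxiliaries in recipes.
    for name in AUXILIARY_POOL:
        values = {
            "energy_kcal": rng.uniform(20.0, 130.0),
            "protein_g": rng.uniform(0.5, 4.0),
            "fat_g": rng.uniform(0.1, 1.0),
            "carbohydrate_g": rng.uniform(2.0, 25.0),
            "fiber_g": rng.uniform(0.5, 3.0),
        }
        for nutrient in FULL_NUTRIENT_SET[len(CORE_NUTRIENTS):]:
            values[nutrient] = float(rng.uniform(0.0, 50.0))
        entries.append(
            IngredientComposition(name, "vegetables and vegetable products", NutrientVector(values))
        )
    return entries


def _pick(rng: np.random.Generator, pool: Sequence[str], size: int) -> list[str]:
    idx = rng.choice(len(pool), size=min(size, len(pool)), replace=False)
    return [pool[int(i)] for i in sorted(idx)]


def generate_food_knowledge(
    config: SimulationConfig,
) -> tuple[RecipeDatabase, FoodCompositionTable]:
    """Generate a menu and a composition table that fully covers it.

    Every menu recipe's counted and auxiliary ingredients resolve in the
    table. When corruption with kind ``missing_ingredient`` is enabled,
    one extra off-menu dish is planted whose recipe names an ingredient
    deliberately absent from the table.
    """
    rng = np.random.default_rng((int(config.seed), 0))
    pool = _ingredient_pool(config, rng)
    table = FoodCompositionTable(
        pool,
        nutrient_names=FULL_NUTRIENT_SET,
        source_name="synthetic food composition table",
        source_version="1",
    )
    by_cat: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    for entry in pool:
        if entry.name not in AUXILIARY_POOL:
            by_cat[entry.category].append(entry.name)

    staple_pool = by_cat["cereals"] + by_cat["tubers, starches and their products"]
    main_pool = (
        by_cat["meat and meat products"]
        + by_cat["poultry and poultry products"]
        + by_cat["fish, shellfish and molluscs"]
        + by_cat["vegetables and vegetable products"]
        + by_cat["fungi and algae"]
        + by_cat["legumes"]
        + by_cat["eggs"]
    )
    soup_pool = (
        by_cat["cereals"]
        + by_cat["vegetables and vegetable products"]
        + by_cat["eggs"]
        + by_cat["fungi and algae"]
    )

    recipes: list[Recipe] = []
    for i in range(int(config.menu_size.get("staple", 0))):
        name = staple_pool[int(rng.integers(len(staple_pool)))]
        recipes.append(
            Recipe(
                name=f"staple dish {i + 1:03d}",
                dish_type="staple",
                method=("steam", "boil")[int(rng.integers(2))],
                ingredients=(RecipeIngredient(name, float(rng.uniform(100, 250))),),
            )
        )
    for i in range(int(config.menu_size.get("cooked", 0))):
        k = int(rng.integers(2, 5))
        mains = tuple(
            RecipeIngredient(n, float(rng.uniform(60, 300)))
            for n in _pick(rng, main_pool, k)
        )
        n_aux = int(rng.integers(1, 3))
        aux = tuple(
            RecipeIngredient(n, float(rng.uniform(3, 12)), auxiliary=True)
            for n in _pick(rng, AUXILIARY_POOL, n_aux)
        )
        recipes.append(
            Recipe(
                name=f"cooked dish {i + 1:03d}",
                dish_type="cooked",
                method=str(rng.choice(_COOKED_METHODS, p=_COOKED_METHOD_P)),
                ingredients=mains + aux,
            )
        )
    for i in range(int(config.menu_size.get("porridge_soup", 0))):
        k = int(rng.integers(1, 4))
        mains = tuple(
            RecipeIngredient(n, float(rng.uniform(30, 150)))
            for n in _pick(rng, soup_pool, k)
        )
        recipes.append(
            Recipe(
                name=f"soup {i + 1:03d}",
                dish_type="porridge_soup",
                method="boil",
                ingredients=mains,
            )
        )

    if config.corruption_rate > 0 and "missing_ingredient" in config.corruption_kinds:
        recipes.append(
            Recipe(
                name=UNCOVERED_DISH,
                dish_type="cooked",
                method="braise",
                ingredients=(RecipeIngredient(UNCOVERED_INGREDIENT, 100.0),),
            )
        )

    db = RecipeDatabase(recipes, source_name="synthetic menu", source_version="1")
    return db, table


def menu_dishes(recipes: RecipeDatabase) -> list[str]:
    """Orderable menu: every dish except the planted uncovered one."""
    return [n for n in recipes.names() if n != UNCOVERED_DISH]


def _preferences(
    config: SimulationConfig,
    consumer: str,
    menu: list[str],
    rng: np.random.Generator,
) -> np.ndarray:
    if config.preference_weights and consumer in config.preference_weights:
        pinned = config.preference_weights[consumer]
        w = np.array([float(pinned.get(d, 0.0)) for d in menu])
        if w.sum() <= 0:
            raise ValueError(f"pinned preferences for {consumer!r} sum to zero")
        return w / w.sum()
    return rng.dirichlet(np.ones(len(menu)))


def generate_events(
    config: SimulationConfig, recipes: RecipeDatabase
) -> SimulatedEvents:
    """Simulate the plate-event stream and its corruption ledger.

    Per consumer, day, and meal slot, each of ``plates_per_meal`` dishes
    is drawn from that consumer's categorical preference over the menu;
    serving weight is uniform over the plate-type range. Each event is
    then independently corrupted with probability ``corruption_rate``
    (one corruption kind per event, chosen uniformly), and every
    corruption is ledgered. Uncorrupted events all pass the four
    selection filters for the simulated (lunch-only) meal.
    """
    rng = np.random.default_rng((int(config.seed), 1))
    menu = sorted(menu_dishes(recipes))
    days = _simulation_days(config)
    consumers = [f"c{i + 1:04d}" for i in range(config.n_consumers)]

    events: list[PlateEvent] = []
    for consumer in consumers:
        prefs = _preferences(config, consumer, menu, rng)
        for day in days:
            for slot in config.meal_slots:
                for _ in range(config.plates_per_meal):
                    dish = menu[int(rng.choice(len(menu), p=prefs))]
                    plate = recipes[dish].plate_type
                    lo, hi = config.serving_ranges[plate]
                    weight = float(rng.uniform(lo, hi))
                    price = round(weight / 100.0 * _PRICE_PER_100G[plate], 2)
                    events.append(
                        PlateEvent(consumer, dish, plate, weight, price, slot, day)
                    )

    corruptions: list[Corruption] = []
    if config.corruption_rate > 0:
        hit = rng.random(len(events)) < config.corruption_rate
        for idx in np.flatnonzero(hit):
            idx = int(idx)
            kind = str(rng.choice(config.corruption_kinds))
            e = events[idx]
            if kind == "meal_slot":
                e = dataclasses.replace(e, meal_slot="breakfast")
            elif kind == "plate_type":
                e = dataclasses.replace(e, plate_type=5)
            elif kind == "unknown_dish":
                e = dataclasses.replace(e, dish_name=f"unlisted dish {idx}")
            elif kind == "missing_ingredient":
                e = dataclasses.replace(e, dish_name=UNCOVERED_DISH, plate_type=2)
            else:
                raise ValueError(f"unknown corruption kind: {kind!r}")
            events[idx] = e
            corruptions.append(Corruption(idx, kind))

    return SimulatedEvents(events=events, corruptions=tuple(corruptions))


@dataclass(frozen=True)
class IndividualScenario:
    """A single consumer observed over 20 working days at lunch.

    On a planted subset of days the consumer takes rice together with
    egg-drop soup (plus one cooked dish); on the remaining days, steamed
    buns and a cooked dish. The planted count is ground truth for
    food-frequency recovery.
    """

    recipes: RecipeDatabase
    table: FoodCompositionTable
    events: list[PlateEvent]
    consumer_id: str
    window: tuple[dt.date, dt.date]
    planted_rice_soup_days: int


def _fixed_individual_knowledge() -> tuple[RecipeDatabase, FoodCompositionTable]:
    # Hand-set per-100 g values in the range of common food-composition
    # entries for these foods; core five nutrients only.
    comp = {
        "polished rice": ("cereals", (346, 7.9, 0.9, 77.2, 0.6)),
        "wheat flour": ("cereals", (354, 11.2, 1.5, 73.6, 2.1)),
        "egg": ("eggs", (144, 13.3, 8.8, 2.8, 0.0)),
        "tomato": ("vegetables and vegetable products", (20, 0.9, 0.2, 4.0, 0.5)),
        "cabbage": ("vegetables and vegetable products", (24, 1.5, 0.2, 4.6, 1.0)),
        "pork": ("meat and meat products", (395, 13.2, 37.0, 2.4, 0.0)),
        "string beans": ("vegetables and vegetable products", (31, 2.0, 0.4, 6.1, 2.1)),
        "rapeseed oil": ("other", (899, 0.0, 99.9, 0.0, 0.0)),
        "scallion": ("vegetables and vegetable products", (33, 1.7, 0.3, 6.5, 1.3)),
    }
    entries = [
        IngredientComposition(
            name,
            category,
            NutrientVector(dict(zip(CORE_NUTRIENTS, values))),
        )
        for name, (category, values) in comp.items()
    ]
    table = FoodCompositionTable(
        entries,
        nutrient_names=CORE_NUTRIENTS,
        source_name="synthetic individual-scenario composition table",
    )
    recipes = RecipeDatabase(
        [
            Recipe("rice", "staple", "steam", (RecipeIngredient("polished rice", 150),)),
            Recipe("steamed buns", "staple", "steam", (RecipeIngredient("wheat flour", 120),)),
            Recipe(
                "egg drop soup",
                "porridge_soup",
                "boil",
                (RecipeIngredient("egg", 50), RecipeIngredient("tomato", 80)),
            ),
            Recipe(
                "cooked tomato with eggs",
                "cooked",
                "stir-fry",
                (
                    RecipeIngredient("tomato", 200),
                    RecipeIngredient("egg", 150),
                    RecipeIngredient("scallion", 5, auxiliary=True),
                ),
            ),
            Recipe(
                "stir-fried cabbage",
                "cooked",
                "stir-fry",
                (
                    RecipeIngredient("cabbage", 250),
                    RecipeIngredient("rapeseed oil", 10),
                    RecipeIngredient("garlic", 5, auxiliary=True),
                ),
            ),
            Recipe(
                "braised pork",
                "cooked",
                "braise",
                (
                    RecipeIngredient("pork", 300),
                    RecipeIngredient("scallion", 10, auxiliary=True),
                ),
            ),
        ],
        source_name="synthetic individual-scenario menu",
    )
    return recipes, table


def generate_individual_scenario(
    seed: int = 0, planted_days: int = 15, n_days: int = 20
) -> IndividualScenario:
    """20 working days of one consumer's lunches with a planted habit.

    ``planted_days`` of the ``n_days`` (chosen by the seeded generator)
    include rice + egg-drop soup; every day has at least two plates, so
    the daily intake series covers the full window.
    """
    if planted_days > n_days:
        raise ValueError("planted_days cannot exceed n_days")
    rng = np.random.default_rng((int(seed), 2))
    recipes, table = _fixed_individual_knowledge()
    days = working_days(dt.date(2016, 1, 5), n_days)
    rice_days = set(
        int(i) for i in rng.choice(n_days, size=planted_days, replace=False)
    )
    cooked = ["braised pork", "cooked tomato with eggs", "stir-fried cabbage"]
    consumer = "c0001"

    events: list[PlateEvent] = []

    def take(dish: str, day: dt.date) -> None:
        plate = recipes[dish].plate_type
        lo, hi = DEFAULT_SERVING_RANGES[plate]
        weight = float(rng.uniform(lo, hi))
        price = round(weight / 100.0 * _PRICE_PER_100G[plate], 2)
        events.append(PlateEvent(consumer, dish, plate, weight, price, "lunch", day))

    for i, day in enumerate(days):
        dish = cooked[int(rng.integers(len(cooked)))]
        if i in rice_days:
            take("rice", day)
            take("egg drop soup", day)
            take(dish, day)
        else:
            take("steamed buns", day)
            take(dish, day)

    return IndividualScenario(
        recipes=recipes,
        table=table,
        events=events,
        consumer_id=consumer,
        window=(days[0], days[-1]),
        planted_rice_soup_days=planted_days,
    )


def _data_path(name: str):
    return resources.files("dietledger").joinpath("data", name)


def make_reference_fixture() -> tuple[dict[str, NutrientVector], list[ReferenceMeasurement]]:
    """The three reference dishes' printed calculated/measured value pairs.

    Returns the calculated per-100 g vectors (energy, protein, fat,
    carbohydrate) keyed by dish name, and the matching chemical reference
    measurements, exactly as published.
    """
    with resources.as_file(_data_path("reference_dishes_calculated.csv")) as path:
        df = pd.read_csv(path)
    calculated: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        calculated.setdefault(row.dish, {})[row.nutrient] = float(row.calculated_per_100g)
    vectors = {dish: NutrientVector(values) for dish, values in calculated.items()}
    with resources.as_file(_data_path("reference_dishes_measured.csv")) as path:
        references = load_reference_measurements(path)
    return vectors, references


def load_reference_dish_recipes() -> RecipeDatabase:
    """Recipes for the three reference dishes.

    Ingredient lists and preparation methods follow the published dish
    descriptions; the raw weights are synthetic stand-ins (the originals
    are not public), so these recipes support structural tests, not
    reproduction of the printed calculated values.
    """
    with resources.as_file(_data_path("reference_dish_recipes_synthetic.json")) as path:
        return load_recipe_db(path)
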