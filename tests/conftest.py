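import datetime as dt

import pytest

from dietledger.food_knowledge import (
    CORE_NUTRIENTS,
    FoodCompositionTable,
    IngredientComposition,
    NutrientVector,
    Recipe,
    RecipeDatabase,
    RecipeIngredient,
)
from dietledger.plate_events import PlateEvent


def make_table(entries, nutrient_names=CORE_NUTRIENTS):
    """Build a composition table from {name: (category, {nutrient: amount})}."""
    return FoodCompositionTable(
        [
            IngredientComposition(name, category, NutrientVector(values))
            for name, (category, values) in entries.items()
        ],
        nutrient_names=nutrient_names,
        source_name="test table",
    )


def core(energy, protein, fat, carb, fiber):
    return dict(zip(CORE_NUTRIENTS, (energy, protein, fat, carb, fiber)))


@pytest.fixture
def small_table():
    return make_table(
        {
            "rice": ("cereals", core(346, 7.9, 0.9, 77.2, 0.6)),
            "tomato": ("vegetables and vegetable products", core(20, 0.9, 0.2, 4.0, 0.5)),
            "cabbage": ("vegetables and vegetable products", core(24, 1.5, 0.2, 4.6, 1.0)),
            "egg": ("eggs", core(144, 13.3, 8.8, 2.8, 0.0)),
            "pork": ("meat and meat products", core(395, 13.2, 37.0, 2.4, 0.0)),
            "garlic": ("vegetables and vegetable products", core(128, 4.5, 0.2, 27.6, 1.1)),
            # fiber deliberately not measured for mushroom
            "mushroom": ("fungi and algae", {**core(26, 2.7, 0.1, 4.1, 2.1), "fiber_g": None}),
        }
    )


@pytest.fixture
def small_recipes():
    return RecipeDatabase(
        [
            Recipe("rice", "staple", "steam", (RecipeIngredient("rice", 150),)),
            Recipe(
                "cooked tomato with eggs",
                "cooked",
                "stir-fry",
                (
                    RecipeIngredient("tomato", 200),
                    RecipeIngredient("egg", 150),
                    RecipeIngredient("garlic", 5, auxiliary=True),
                ),
            ),
            Recipe(
                "braised pork",
                "cooked",
                "braise",
                (
                    RecipeIngredient("pork", 300),
                    RecipeIngredient("garlic", 10, auxiliary=True),
                ),
            ),
            Recipe(
                "mushroom soup",
                "porridge_soup",
                "boil",
                (RecipeIngredient("mushroom", 80), RecipeIngredient("egg", 40)),
            ),
            # ingredient absent from the composition table
            Recipe(
                "dragon delight",
                "cooked",
                "stir-fry",
                (RecipeIngredient("dragon fruit peel", 100),),
            ),
        ],
        source_name="test recipes",
    )


def make_event(
    dish="rice",
    consumer="c0001",
    plate_type=1,
    weight=150.0,
    price=1.5,
    slot="lunch",
    date=dt.date(2016, 1, 5),
):
    return PlateEvent(consumer, dish, plate_type, weight, price, slot, date)
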