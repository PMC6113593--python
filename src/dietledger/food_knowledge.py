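"""Recipe database and food-composition table.

Two knowledge sources together turn a named dish into nutrient amounts:
the recipe database breaks a dish down into raw ingredients with weights,
and the food-composition table breaks each ingredient down into nutrient
amounts per 100 g edible portion (the schema emulates the China Food
Composition Database: up to 23 nutrients for ~1400 ingredients).

Conventions
-----------
* Composition values are per 100 g *edible portion* of the raw ingredient.
* A missing nutrient cell is an explicit *absent* value (``None``), never
  coerced to zero: "not measured" and "zero content" are different facts.
* Name matching is exact after :func:`~dietledger._util.normalize_name`;
  there is no fuzzy matching.
"""

from __future__ import annotations

import json
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._util import normalize_name
from .errors import (
    DuplicateKeyError,
    RecipeValidationError,
    SchemaError,
    VocabularyError,
)

#: Closed food-group vocabulary for composition-table entries.
CATEGORIES: tuple[str, ...] = (
    "vegetables and vegetable products",
    "tubers, starches and their products",
    "meat and meat products",
    "poultry and poultry products",
    "fungi and algae",
    "fish, shellfish and molluscs",
    "cereals",
    "legumes",
    "eggs",
    "fruits",
    "other",
)

#: The three dish types of a Chinese meal.
DISH_TYPES: tuple[str, ...] = ("staple", "cooked", "porridge_soup")

#: Controlled preparation-method vocabulary.
METHODS: tuple[str, ...] = (
    "stir-fry",
    "steam",
    "boil",
    "roast",
    "deep-fry",
    "braise",
    "raw",
    "other",
)

#: Core nutrient columns every composition table must provide.
CORE_NUTRIENTS: tuple[str, ...] = (
    "energy_kcal",
    "protein_g",
    "fat_g",
    "carbohydrate_g",
    "fiber_g",
)

# Common free-text spellings accepted on input and mapped onto the
# controlled vocabularies. Alias resolution is an exact table lookup,
# not fuzzy matching.
DISH_TYPE_ALIASES: dict[str, str] = {
    "staple": "staple",
    "staple food": "staple",
    "cooked": "cooked",
    "cooked food": "cooked",
    "cooked dish": "cooked",
    "porridge_soup": "porridge_soup",
    "porridge and soup": "porridge_soup",
    "porridge": "porridge_soup",
    "soup": "porridge_soup",
}

METHOD_ALIASES: dict[str, str] = {
    "stir-fry": "stir-fry",
    "stir fry": "stir-fry",
    "stir frying": "stir-fry",
    "stir-frying": "stir-fry",
    "steam": "steam",
    "steaming": "steam",
    "steamed": "steam",
    "boil": "boil",
    "boiling": "boil",
    "boiled": "boil",
    "roast": "roast",
    "roasting": "roast",
    "roasted": "roast",
    "deep-fry": "deep-fry",
    "deep fry": "deep-fry",
    "deep frying": "deep-fry",
    "deep-frying": "deep-fry",
    "braise": "braise",
    "braising": "braise",
    "braised": "braise",
    "raw": "raw",
    "other": "other",
}


def resolve_dish_type(token: str) -> str:
    key = normalize_name(token)
    try:
        return DISH_TYPE_ALIASES[key]
    except KeyError:
        raise VocabularyError(f"unknown dish type: {token!r}") from None


def resolve_method(token: str) -> str:
    key = normalize_name(token)
    try:
        return METHOD_ALIASES[key]
    except KeyError:
        raise VocabularyError(f"unknown preparation method: {token!r}") from None


class NutrientVector(Mapping):
    """Ordered mapping from nutrient name to amount per reference basis.

    Values are non-negative floats or ``None`` for *absent* (not measured).
    Absence propagates through arithmetic: a sum involving an absent value
    is absent, and scaling preserves absence. The optional ``warnings``
    attachment carries human-readable notes about absent contributions; it
    does not participate in equality.
    """

    __slots__ = ("_values", "warnings")

    def __init__(self, values: Mapping | None = None, warnings: tuple[str, ...] = ()):
        out: dict[str, float | None] = {}
        for name, v in dict(values or {}).items():
            if v is not None and not (isinstance(v, float) and v != v):  # NaN -> absent
                v = float(v)
                if v < 0:
                    raise ValueError(f"negative nutrient amount for {name!r}: {v}")
            else:
                v = None
            out[str(name)] = v
        self._values = out
        self.warnings = tuple(warnings)

    def __getitem__(self, key: str) -> float | None:
        return self._values[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __repr__(self) -> str:
        inner = ", ".join(f"{k}={v}" for k, v in self._values.items())
        return f"NutrientVector({inner})"

    def __eq__(self, other: object) -> bool:
        if isinstance(other, NutrientVector):
            return self._values == other._values
        if isinstance(other, Mapping):
            return self._values == dict(other)
        return NotImplemented

    def __hash__(self) -> int:  # Mapping sets __hash__ = None
        return hash(tuple(self._values.items()))

    @property
    def absent(self) -> tuple[str, ...]:
        """Names of nutrients marked absent (not measured)."""
        return tuple(k for k, v in self._values.items() if v is None)

    def scale(self, factor: float) -> "NutrientVector":
        """Multiply every defined amount by ``factor`` (absent stays absent)."""
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return NutrientVector(
            {k: (None if v is None else v * factor) for k, v in self._values.items()},
            warnings=self.warnings,
        )

    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        if not isinstance(other, Mapping):
            return NotImplemented
        keys = list(self._values) + [k for k in other if k not in self._values]
        out: dict[str, float | None] = {}
        notes: list[str] = list(self.warnings) + list(getattr(other, "warnings", ()))
        for k in keys:
            a = self._values.get(k)
            b = other.get(k) if k in other else None
            if a is None or b is None:
                out[k] = None
                if (k in self._values) != (k in other):
                    notes.append(f"{k}: absent on one side of a sum")
            else:
                out[k] = a + b
        return NutrientVector(out, warnings=tuple(notes))

    def to_dict(self) -> dict[str, float | None]:
        return dict(self._values)


@dataclass(frozen=True)
class IngredientComposition:
    """One composition-table row: an ingredient and its per-100 g nutrients."""

    name: str
    category: str
    nutrients: NutrientVector

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise VocabularyError(f"unknown food category: {self.category!r}")


@dataclass(frozen=True)
class RejectedRow:
    """A composition-table row excluded during loading, with its reason."""

    line: int
    key: str
    reason: str


class FoodCompositionTable:
    """Composition entries keyed by normalized ingredient name."""

    def __init__(
        self,
        entries: list[IngredientComposition] | None = None,
        *,
        nutrient_names: tuple[str, ...] = CORE_NUTRIENTS,
        source_name: str = "unknown",
        source_version: str = "0",
        rejected_rows: tuple[RejectedRow, ...] = (),
    ):
        self._entries: dict[str, IngredientComposition] = {}
        self.nutrient_names = tuple(nutrient_names)
        self.source_name = source_name
        self.source_version = source_version
        self.rejected_rows = tuple(rejected_rows)
        for entry in entries or []:
            self.add(entry)

    def add(self, entry: IngredientComposition) -> None:
        key = normalize_name(entry.name)
        if key in self._entries:
            raise DuplicateKeyError(f"duplicate ingredient: {key!r}")
        self._entries[key] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, name: str) -> bool:
        return normalize_name(name) in self._entries

    def __getitem__(self, name: str) -> IngredientComposition:
        key = normalize_name(name)
        try:
            return self._entries[key]
        except KeyError:
            from .errors import IngredientLookupError

            raise IngredientLookupError(key) from None

    lookup = __getitem__

    def ingredients(self) -> Iterator[IngredientComposition]:
        return iter(self._entries.values())

    def names(self) -> tuple[str, ...]:
        return tuple(self._entries)


@dataclass(frozen=True)
class RecipeIngredient:
    """One recipe component: raw weight in grams, optionally auxiliary.

    Auxiliary marks condiment-scale components (ginger, garlic, scallion)
    that the nutrient engine ignores by default. The flag is author-supplied,
    never inferred from the weight.
    """

    name: str
    weight_g: float
    auxiliary: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", normalize_name(self.name))
        if not self.weight_g > 0:
            raise RecipeValidationError(
                f"ingredient {self.name!r} must have positive weight, got {self.weight_g}"
            )


@dataclass(frozen=True)
class Recipe:
    """A dish: type, preparation method, and raw-weight ingredient list."""

    name: str
    dish_type: str
    method: str
    ingredients: tuple[RecipeIngredient, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", normalize_name(self.name))
        object.__setattr__(self, "ingredients", tuple(self.ingredients))
        if self.dish_type not in DISH_TYPES:
            raise VocabularyError(f"unknown dish type: {self.dish_type!r}")
        if self.method not in METHODS:
            raise VocabularyError(f"unknown preparation method: {self.method!r}")
        main = [i for i in self.ingredients if not i.auxiliary]
        if not main or sum(i.weight_g for i in main) <= 0:
            raise RecipeValidationError(
                f"recipe {self.name!r} needs at least one non-auxiliary ingredient "
                "with positive weight"
            )

    @property
    def plate_type(self) -> int:
        """Plate carrying this dish type: 1 staple, 2 cooked, 3 soup."""
        return DISH_TYPES.index(self.dish_type) + 1

    def main_ingredients(self) -> tuple[RecipeIngredient, ...]:
        return tuple(i for i in self.ingredients if not i.auxiliary)


class RecipeDatabase:
    """Recipes keyed by normalized dish name."""

    def __init__(
        self,
        recipes: list[Recipe] | None = None,
        *,
        source_name: str = "unknown",
        source_version: str = "0",
    ):
        self._recipes: dict[str, Recipe] = {}
        self.source_name = source_name
        self.source_version = source_version
        for recipe in recipes or []:
            self.add(recipe)

    def add(self, recipe: Recipe) -> None:
        if recipe.name in self._recipes:
            raise DuplicateKeyError(f"duplicate dish: {recipe.name!r}")
        self._recipes[recipe.name] = recipe

    def __len__(self) -> int:
        return len(self._recipes)

    def __contains__(self, dish: str) -> bool:
        return normalize_name(dish) in self._recipes

    def __getitem__(self, dish: str) -> Recipe:
        key = normalize_name(dish)
        try:
            return self._recipes[key]
        except KeyError:
            from .errors import DishLookupError

            raise DishLookupError(key) from None

    lookup = __getitem__

    def recipes(self) -> Iterator[Recipe]:
        return iter(self._recipes.values())

    def names(self) -> tuple[str, ...]:
        return tuple(self._recipes)


# ---------------------------------------------------------------------------
# Loading and writing


def _separator_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def load_composition_table(source: str | Path) -> FoodCompositionTable:
    """Load a composition table from a delimited text file.

    CSV or TSV (chosen by extension), UTF-8, header required. Required
    columns: ``ingredient``, ``category``, and the five core nutrient
    columns; any further columns are treated as additional nutrients.
    Empty nutrient cells parse to absent. Rows with a negative nutrient
    value or an unknown category are excluded and recorded on
    ``rejected_rows``; duplicate ingredient names are a hard error.
    """
    path = Path(source)
    df = pd.read_csv(path, sep=_separator_for(path), encoding="utf-8")
    for col in ("ingredient", "category", *CORE_NUTRIENTS):
        if col not in df.columns:
            raise SchemaError(f"composition table missing required column: {col!r}")
    nutrient_cols = [c for c in df.columns if c not in ("ingredient", "category")]

    entries: list[IngredientComposition] = []
    seen: set[str] = set()
    rejected: list[RejectedRow] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # 1-based file line, after the header
        name = normalize_name(getattr(row, "ingredient"))
        if name in seen:
            raise DuplicateKeyError(f"duplicate ingredient: {name!r}")
        seen.add(name)
        category = normalize_name(getattr(row, "category"))
        if category not in CATEGORIES:
            rejected.append(RejectedRow(line, name, "category"))
            continue
        values: dict[str, float | None] = {}
        negative = False
        for col in nutrient_cols:
            v = getattr(row, col)
            if pd.isna(v):
                values[col] = None
            else:
                v = float(v)
                if v < 0:
                    negative = True
                    break
                values[col] = v
        if negative:
            rejected.append(RejectedRow(line, name, "negative nutrient value"))
            continue
        entries.append(IngredientComposition(name, category, NutrientVector(values)))

    return FoodCompositionTable(
        entries,
        nutrient_names=tuple(nutrient_cols),
        source_name=path.name,
        rejected_rows=tuple(rejected),
    )


def write_composition_table(table: FoodCompositionTable, target: str | Path) -> None:
    """Write a composition table back to delimited text (round-trip exact)."""
    path = Path(target)
    rows = []
    for entry in table.ingredients():
        row: dict[str, object] = {"ingredient": entry.name, "category": entry.category}
        for col in table.nutrient_names:
            v = entry.nutrients.get(col)
            row[col] = "" if v is None else repr(v)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["ingredient", "category", *table.nutrient_names])
    df.to_csv(path, sep=_separator_for(path), index=False, encoding="utf-8")


def _recipe_from_mapping(raw: Mapping) -> Recipe:
    for key in ("dish", "dish_type", "ingredients"):
        if key not in raw:
            raise SchemaError(f"recipe record missing field {key!r}")
    ingredients = tuple(
        RecipeIngredient(
            name=item["name"],
            weight_g=float(item["weight_g"]),
            auxiliary=bool(item.get("auxiliary", False)),
        )
        for item in raw["ingredients"]
    )
    return Recipe(
        name=raw["dish"],
        dish_type=resolve_dish_type(raw["dish_type"]),
        method=resolve_method(raw.get("method", "other")),
        ingredients=ingredients,
    )


def load_recipe_db(source: str | Path) -> RecipeDatabase:
    """Load a recipe database from a JSON or YAML document.

    The document is either a mapping with a ``recipes`` list (and optional
    ``schema_version`` / ``source`` metadata) or a bare list of recipe
    records. See ``docs/formats.md`` for the schema.
    """
    path = Path(source)
    doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    if isinstance(doc, Mapping):
        records = doc.get("recipes")
        if records is None:
            raise SchemaError("recipe document has no 'recipes' list")
        source_name = str(doc.get("source", path.name))
        source_version = str(doc.get("schema_version", "1"))
    elif isinstance(doc, list):
        records, source_name, source_version = doc, path.name, "1"
    else:
        raise SchemaError("recipe document must be a mapping or a list")

    db = RecipeDatabase(source_name=source_name, source_version=source_version)
    for raw in records:
        db.add(_recipe_from_mapping(raw))
    return db


def write_recipe_db(db: RecipeDatabase, target: str | Path) -> None:
    """Serialize a recipe database as JSON (round-trips through load)."""
    doc = {
        "schema_version": 1,
        "source": db.source_name,
        "recipes": [
            {
                "dish": r.name,
                "dish_type": r.dish_type,
                "method": r.method,
                "ingredients": [
                    {"name": i.name, "weight_g": i.weight_g, "auxiliary": i.auxiliary}
                    for i in r.ingredients
                ],
            }
            for r in db.recipes()
        ],
    }
    Path(target).write_text(json.dumps(doc, indent=2), encoding="utf-8")


def validate_recipe_coverage(
    recipe: Recipe,
    table: FoodCompositionTable,
    *,
    include_auxiliary: bool = False,
) -> list[str]:
    """Names of recipe ingredients that do not resolve in the table.

    Returns an empty list iff every counted ingredient (non-auxiliary, or
    all of them when ``include_auxiliary``) has a composition entry.
    """
    missing: list[str] = []
    for ing in recipe.ingredients:
        if ing.auxiliary and not include_auxiliary:
            continue
        if ing.name not in table and ing.name not in missing:
            missing.append(ing.name)
    return missing
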