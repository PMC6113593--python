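import datetime as dt

import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from conftest import core, make_event, make_table
from dietledger.food_knowledge import Recipe, RecipeIngredient
from dietledger.errors import IngredientLookupError
from dietledger.nutrient_engine import (
    aggregate_intake,
    decompose_dish,
    intake_for_event,
    nutrient_content_per_100g,
)
from dietledger.synthetic_data import generate_individual_scenario
from oracles import brute_force_per_100g


def recipe_of(weights, aux=None):
    """Recipe from {name: weight} plus optional auxiliary {name: weight}."""
    ingredients = tuple(RecipeIngredient(n, w) for n, w in weights.items())
    if aux:
        ingredients += tuple(RecipeIngredient(n, w, auxiliary=True) for n, w in aux.items())
    return Recipe("test dish", "cooked", "stir-fry", ingredients)


class TestDecomposeDish:
    def test_single_ingredient_takes_whole_serving(self):
        recipe = Recipe("rice", "staple", "steam", (RecipeIngredient("rice", 150),))
        assert decompose_dish(recipe, 100.0) == [("rice", 100.0)]

    def test_two_ingredients_split_proportionally(self):
        recipe = recipe_of({"a": 300, "b": 100})
        assert decompose_dish(recipe, 200.0) == [("a", 150.0), ("b", 50.0)]

    def test_auxiliary_excluded_from_the_total_by_default(self):
        recipe = Recipe(
            "test dish",
            "cooked",
            "stir-fry",
            (
                RecipeIngredient("a", 250),
                RecipeIngredient("b", 150),
                RecipeIngredient("c", 100),
                RecipeIngredient("d", 10, auxiliary=True),
            ),
        )
        # counted total 500 -> shares 50/30/20 of a 100 g serving
        assert decompose_dish(recipe, 100.0) == [("a", 50.0), ("b", 30.0), ("c", 20.0)]
        with_aux = dict(decompose_dish(recipe, 100.0, include_auxiliary=True))
        assert with_aux["d"] == pytest.approx(10 / 510 * 100)
        assert sum(with_aux.values()) == pytest.approx(100.0, rel=1e-9)

    def test_duplicate_ingredient_lines_merge(self):
        recipe = Recipe(
            "test dish",
            "cooked",
            "boil",
            (RecipeIngredient("a", 100), RecipeIngredient("a", 100), RecipeIngredient("b", 200)),
        )
        assert decompose_dish(recipe, 100.0) == [("a", 50.0), ("b", 50.0)]

    def test_non_positive_serving_rejected(self):
        recipe = recipe_of({"a": 100})
        with pytest.raises(ValueError):
            decompose_dish(recipe, 0)

    @given(
        weights=st.lists(
            st.floats(min_value=0.5, max_value=500, allow_nan=False), min_size=1, max_size=8
        ),
        serving=st.floats(min_value=1, max_value=1000, allow_nan=False),
    )
    @settings(max_examples=150, deadline=None)
    def test_mass_conservation(self, weights, serving):
        recipe = recipe_of({f"ing {i}": w for i, w in enumerate(weights)})
        parts = decompose_dish(recipe, serving)
        assert sum(w for _, w in parts) == pytest.approx(serving, rel=1e-9)


class TestPer100g:
    def test_single_ingredient_dish_equals_the_ingredient(self, small_recipes, small_table):
        vector = nutrient_content_per_100g(small_recipes["rice"], small_table)
        assert vector == small_table["rice"].nutrients

    def test_fifty_fifty_blend_is_the_midpoint(self):
        table = make_table(
            {
                "a": ("other", core(100, 10, 2, 5, 1)),
                "b": ("other", core(300, 20, 8, 15, 3)),
            }
        )
        recipe = recipe_of({"a": 200, "b": 200})
        vector = nutrient_content_per_100g(recipe, table)
        assert vector["energy_kcal"] == pytest.approx(200.0, rel=1e-12)
        assert vector["protein_g"] == pytest.approx(15.0, rel=1e-12)

    def test_uncovered_ingredient_names_the_culprit(self, small_recipes, small_table):
        with pytest.raises(IngredientLookupError, match="dragon fruit peel"):
            nutrient_content_per_100g(small_recipes["dragon delight"], small_table)

    def test_absent_nutrient_propagates_with_warning(self, small_recipes, small_table):
        # mushroom has no measured fiber -> the soup's fiber is absent
        vector = nutrient_content_per_100g(small_recipes["mushroom soup"], small_table)
        assert vector["fiber_g"] is None
        assert any("fiber_g" in w and "mushroom" in w for w in vector.warnings)
        assert vector["energy_kcal"] is not None

    def test_matches_brute_force_oracle(self, small_recipes, small_table):
        comp = {
            name: small_table[name].nutrients.to_dict() for name in small_table.names()
        }
        for recipe in small_recipes.recipes():
            if recipe.name == "dragon delight":
                continue
            expected = brute_force_per_100g(
                [(i.name, i.weight_g, i.auxiliary) for i in recipe.ingredients], comp
            )
            vector = nutrient_content_per_100g(recipe, small_table)
            for nutrient, value in expected.items():
                if value is None:
                    assert vector[nutrient] is None
                else:
                    assert vector[nutrient] == pytest.approx(value, rel=1e-9)


class TestIntake:
    def test_serving_of_100g_equals_per_100g(self, small_recipes, small_table):
        event = make_event("rice", weight=100.0)
        record = intake_for_event(event, small_recipes, small_table)
        assert record.nutrients == nutrient_content_per_100g(
            small_recipes["rice"], small_table
        )

    def test_double_serving_doubles_every_nutrient(self, small_recipes, small_table):
        r100 = intake_for_event(make_event("rice", weight=100.0), small_recipes, small_table)
        r200 = intake_for_event(make_event("rice", weight=200.0), small_recipes, small_table)
        for nutrient, value in r100.nutrients.items():
            assert r200.nutrients[nutrient] == pytest.approx(2 * value, rel=1e-12)

    @given(k=st.floats(min_value=0.1, max_value=10, allow_nan=False))
    @settings(
        max_examples=50,
        deadline=None,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    def test_linearity_in_serving_weight(self, k, small_recipes, small_table):
        base = intake_for_event(
            make_event("braised pork", plate_type=2, weight=150.0),
            small_recipes,
            small_table,
        )
        scaled = intake_for_event(
            make_event("braised pork", plate_type=2, weight=150.0 * k),
            small_recipes,
            small_table,
        )
        for nutrient, value in base.nutrients.items():
            assert scaled.nutrients[nutrient] == pytest.approx(k * value, rel=1e-9)


class TestAggregation:
    def _records(self, small_recipes, small_table):
        events = [
            make_event("rice", date=dt.date(2016, 1, 5)),
            make_event("braised pork", plate_type=2, date=dt.date(2016, 1, 5)),
            make_event("rice", date=dt.date(2016, 1, 6)),
            make_event("mushroom soup", consumer="c0002", plate_type=3, date=dt.date(2016, 1, 5)),
        ]
        return [intake_for_event(e, small_recipes, small_table) for e in events]

    def test_single_record_round_trips(self, small_recipes, small_table):
        record = intake_for_event(make_event("rice"), small_recipes, small_table)
        series = aggregate_intake([record])["c0001"]
        assert len(series) == 1
        assert series.entries[0] == (record.date, record.nutrients)

    def test_same_day_records_sum_componentwise(self, small_recipes, small_table):
        records = self._records(small_recipes, small_table)[:2]
        series = aggregate_intake(records)["c0001"]
        assert len(series) == 1
        _, vector = series.entries[0]
        for nutrient in vector:
            assert vector[nutrient] == pytest.approx(
                records[0].nutrients[nutrient] + records[1].nutrients[nutrient], rel=1e-12
            )

    def test_partition_invariance(self, small_recipes, small_table):
        records = self._records(small_recipes, small_table)
        whole = aggregate_intake(records, by="consumer")
        part = aggregate_intake(records[:2], by="consumer")
        rest = aggregate_intake(records[2:], by="consumer")
        merged = {}
        for chunk in (part, rest):
            for cid, vec in chunk.items():
                merged[cid] = vec if cid not in merged else merged[cid] + vec
        assert set(merged) == set(whole)
        for cid in whole:
            for nutrient, value in whole[cid].items():
                assert merged[cid][nutrient] == pytest.approx(value, rel=1e-9)

    def test_input_order_does_not_change_sums(self, small_recipes, small_table):
        records = self._records(small_recipes, small_table)
        forward = aggregate_intake(records, by="population+date")
        backward = aggregate_intake(records[::-1], by="population+date")
        assert forward == backward

    def test_twenty_day_individual_series(self, small_recipes, small_table):
        scenario = generate_individual_scenario(seed=3)
        records = [
            intake_for_event(e, scenario.recipes, scenario.table) for e in scenario.events
        ]
        series = aggregate_intake(records)[scenario.consumer_id]
        assert len(series) == 20
        assert series.dates() == tuple(sorted(series.dates()))
        comp = {
            name: scenario.table[name].nutrients.to_dict()
            for name in scenario.table.names()
        }
        # oracle: sum of per-event brute-force energies over the window
        expected_energy = 0.0
        for e in scenario.events:
            recipe = scenario.recipes[e.dish_name]
            per100 = brute_force_per_100g(
                [(i.name, i.weight_g, i.auxiliary) for i in recipe.ingredients], comp
            )
            expected_energy += per100["energy_kcal"] * e.serving_weight_g / 100.0
        assert series.total()["energy_kcal"] == pytest.approx(expected_energy, rel=1e-9)
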