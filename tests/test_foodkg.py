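"""Knowledge-graph construction, deduplication, inference, and rule parsing."""

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mealcombo.foodkg import (
    AmbiguousStatementError,
    Dish,
    GraphError,
    Ingredient,
    IngredientCategory,
    InferenceError,
    KnowledgeGraph,
    Nutrient,
    RELATION_TYPES,
    StandardizationError,
    build_graph,
    dedup_dishes,
    infer_dish_nutrients,
    infer_disease_dish,
    parse_disease_rules,
    standardize_sodium,
)

from conftest import toy_tables


def make_dish(dish_id, ingredients, category="vegan", name=None):
    return Dish(
        id=dish_id,
        name=name or dish_id,
        dish_category=category,
        composition={i: 100.0 for i in ingredients},
    )


class TestBuildGraph:
    def test_toy_edge_census(self, toy_kg):
        """1 dish x 2 ingredients, 2 nutrients, 1 rule: counts check out by hand."""
        by_rel = {}
        for e in toy_kg.edges:
            by_rel[e.relation] = by_rel.get(e.relation, 0) + 1
        assert by_rel["consist_of"] == 2
        assert by_rel["belong_to"] == 2
        # 4 ingredient-level contain + 2 inferred dish-level contain
        assert by_rel["contain"] == 6
        # explicit disease->ingredient plus inferred disease->dish
        assert by_rel["discourage"] == 2
        assert set(by_rel) <= RELATION_TYPES
        assert len(toy_kg.dishes) == 1
        assert len(toy_kg.ingredients) == 2
        assert len(toy_kg.nutrients) == 2

    def test_empty_disease_table_yields_no_rule_edges(self):
        recipes, composition, _rules, guidelines = toy_tables()
        kg = build_graph(recipes, composition, pd.DataFrame(), guidelines,
                         standardize=False)
        relations = {e.relation for e in kg.edges}
        assert not relations & {"discourage", "restrict", "recommend"}

    def test_unresolved_ingredient_names_dish_and_ingredient(self):
        recipes, composition, rules, guidelines = toy_tables()
        recipes.loc[0, "ingredient_id"] = "unicorn"
        with pytest.raises(GraphError, match=r"d1.*unicorn"):
            build_graph(recipes, composition, rules, guidelines, standardize=False)

    def test_negative_gram_rejected(self):
        recipes, composition, rules, guidelines = toy_tables()
        recipes.loc[0, "grams"] = -1.0
        with pytest.raises(GraphError, match="negative"):
            build_graph(recipes, composition, rules, guidelines, standardize=False)

    def test_no_dangling_edges_and_known_relations(self, small_kg):
        small_kg.validate()  # checks endpoints resolve and relation types
        assert {e.relation for e in small_kg.edges} <= RELATION_TYPES


class TestDedup:
    def test_exact_duplicates_collapse(self):
        a = make_dish("a", ["x", "y"])
        b = make_dish("b", ["x", "y"], name="a")  # same name, same ingredients
        assert len(dedup_dishes([a, b])) == 1

    def test_jaccard_merge_and_keep(self):
        # 9 shared of sizes 9 and 10 -> 9/10 = 0.90 >= 0.85: merged
        big = make_dish("big", [f"i{k}" for k in range(10)])
        sub = make_dish("sub", [f"i{k}" for k in range(9)])
        assert len(dedup_dishes([big, sub])) == 1
        # 6 shared of sizes 7 and 7 -> 6/8 = 0.75 < 0.85: both kept
        left = make_dish("left", [f"i{k}" for k in range(7)])
        right = make_dish("right", [f"i{k}" for k in range(1, 8)])
        assert len(dedup_dishes([left, right])) == 2

    def test_threshold_is_inclusive(self):
        # sizes 17 and 20 sharing 17: Jaccard 17/20 = 0.85 exactly -> merged
        a = make_dish("a", [f"i{k}" for k in range(17)])
        b = make_dish("b", [f"i{k}" for k in range(20)])
        assert len(dedup_dishes([a, b], threshold=0.85)) == 1

    def test_most_frequent_variant_kept(self):
        v1 = make_dish("v1", ["x", "y"], name="soup one")
        v2 = make_dish("v2", ["x", "y"], name="soup two")
        v3 = make_dish("v3", ["x", "y"], name="soup one")  # same combo as v1/v2
        # all three share identical ingredient sets; combination frequency 3
        # -> one kept, lexicographically smallest id on the tie
        kept = dedup_dishes([v2, v1, v3])
        assert [d.id for d in kept] == ["v1"]

    @given(
        st.lists(
            st.frozensets(st.sampled_from("abcdefg"), min_size=1, max_size=4),
            min_size=0,
            max_size=8,
        )
    )
    def test_idempotent_and_never_grows(self, ingredient_sets):
        dishes = [
            make_dish(f"d{i}", sorted(s)) for i, s in enumerate(ingredient_sets)
        ]
        once = dedup_dishes(dishes)
        twice = dedup_dishes(once)
        assert len(once) <= len(dishes)
        assert [d.id for d in twice] == [d.id for d in once]


class TestNutrientInference:
    def test_identity_scaling(self):
        kg = KnowledgeGraph(
            ingredients={"apple": Ingredient("apple", "apple", "fruit",
                                            {"vitamin_c": 10.0})},
            categories={"fruit": IngredientCategory("fruit", "fruit")},
            nutrients={"vitamin_c": Nutrient("vitamin_c", "vitamin c", "mg")},
        )
        dish = Dish("d", "apple plate", "vegan", composition={"apple": 100.0})
        assert infer_dish_nutrients(dish, kg) == {"vitamin_c": 10.0}

    def test_weighted_sum(self, toy_kg):
        # 150 g at 2.0 mg/100 g + 50 g at 1.0 mg/100 g = 3.5 mg iron
        totals = toy_kg.dish_nutrients("d1")
        assert totals["iron"] == pytest.approx(3.5)

    @pytest.mark.parametrize("alpha", [0.5, 2.0])
    def test_linear_in_composition(self, toy_kg, alpha):
        dish = toy_kg.dishes["d1"]
        scaled = Dish("s", dish.name, dish.dish_category,
                      composition={k: alpha * v for k, v in dish.composition.items()})
        base = infer_dish_nutrients(dish, toy_kg)
        assert infer_dish_nutrients(scaled, toy_kg) == {
            k: alpha * v for k, v in base.items()
        }

    def test_missing_ingredient_named(self, toy_kg):
        dish = Dish("d", "mystery", "vegan", composition={"unicorn": 50.0})
        with pytest.raises(InferenceError, match="unicorn"):
            infer_dish_nutrients(dish, toy_kg)


class TestDiseaseDishInference:
    def test_empty_discourage_set(self, toy_kg):
        rule = toy_kg.diseases["gout"]
        empty = type(rule)(id="x", name="x")
        toy_kg.diseases["x"] = empty
        assert infer_disease_dish(empty, toy_kg) == set()

    def test_matches_exhaustive_enumeration(self, small_kg):
        """Rule-based inference equals a brute-force scan of all pairs."""
        for disease in small_kg.diseases.values():
            got = infer_disease_dish(disease, small_kg)
            expected = set()
            for dish_id, dish in small_kg.dishes.items():
                for ing_id in dish.composition:
                    ing = small_kg.ingredients[ing_id]
                    if ing_id in disease.discourage or ing.category_id in disease.discourage:
                        expected.add(dish_id)
            assert got == expected

    def test_category_discouragement_inherited(self, toy_kg):
        rule = toy_kg.diseases["gout"]
        by_category = type(rule)(id="g2", name="g2", discourage={"meat"})
        toy_kg.diseases["g2"] = by_category
        assert infer_disease_dish(by_category, toy_kg) == {"d1"}


class TestSodiumStandard:
    @staticmethod
    def _kg_with_salt():
        return KnowledgeGraph(
            ingredients={
                "stew": Ingredient("stew", "stew", "meat", {"sodium": 52.631578947}),
                "salt": Ingredient("salt", "salt", "seasonings", {"sodium": 39000.0}),
            },
            categories={
                "meat": IngredientCategory("meat", "meat"),
                "seasonings": IngredientCategory("seasonings", "seasonings",
                                                 is_seasoning=True),
            },
            nutrients={"sodium": Nutrient("sodium", "sodium", "mg")},
        )

    def test_in_band_unchanged(self):
        kg = self._kg_with_salt()
        dish = Dish("d", "stew", "soup", composition={"stew": 395.0, "salt": 9.1})
        # fraction ~ (0.208 + 3.549) / 404.1 = 0.0093
        out = standardize_sodium(dish, kg)
        assert out is dish

    def test_high_sodium_rescaled_to_upper_bound(self):
        kg = self._kg_with_salt()
        # 400 g dish carrying 8 g sodium (fraction 0.020): 380 g stew
        # contributes 0.2 g, 20 g salt contributes 7.8 g
        dish = Dish("d", "stew", "soup", composition={"stew": 380.0, "salt": 20.0})
        out = standardize_sodium(dish, kg)
        # closed-form oracle: k = (t*M_f - Na_f) / (Na_s - t*M_s), t = 0.010
        k = (0.010 * 380.0 - 0.2) / (7.8 - 0.010 * 20.0)
        assert out.composition["salt"] == pytest.approx(20.0 * k)
        assert out.composition["stew"] == 380.0
        sodium_g = (out.composition["stew"] * 52.631578947
                    + out.composition["salt"] * 39000.0) / 100.0 / 1000.0
        assert sodium_g / out.portion_mass_g == pytest.approx(0.010)
        assert sodium_g == pytest.approx(3.8947, abs=1e-3)

    def test_zero_portion_mass_rejected(self):
        kg = self._kg_with_salt()
        dish = Dish("d", "air", "soup", composition={"stew": 0.0})
        with pytest.raises(StandardizationError):
            standardize_sodium(dish, kg)

    @given(
        stew_g=st.floats(50, 600),
        salt_g=st.floats(0.2, 30),
        base_na=st.floats(0, 300),
    )
    def test_output_fraction_always_in_band(self, stew_g, salt_g, base_na):
        kg = self._kg_with_salt()
        kg.ingredients["stew"].nutrient_per_100g["sodium"] = base_na
        dish = Dish("d", "stew", "soup", composition={"stew": stew_g, "salt": salt_g})
        try:
            out = standardize_sodium(dish, kg)
        except StandardizationError:
            return  # non-seasoning sodium alone above the band: legitimately refused
        sodium_g = sum(
            out.composition[i] * kg.ingredients[i].nutrient_per_100g["sodium"]
            for i in out.composition
        ) / 100.0 / 1000.0
        fraction = sodium_g / out.portion_mass_g
        assert 0.008 - 1e-12 <= fraction <= 0.010 + 1e-12


class TestRuleParsing:
    RESOLVER = {
        "organ meats": ("ingredient", "organ_meats_00"),
        "cholesterol": ("nutrient", "cholesterol"),
        "fish": ("category", "fish"),
    }

    def test_avoid_maps_to_discourage(self):
        statements = pd.DataFrame(
            [{"disease_id": "gout", "text": "patients with gout should avoid organ meats"}]
        )
        parsed = parse_disease_rules(statements, resolver=self.RESOLVER)
        assert parsed.unmatched == []
        (rule,) = parsed.rules
        assert rule.discourage == {"organ_meats_00"}

    def test_restriction_with_amount_capture(self):
        statements = pd.DataFrame(
            [{"disease_id": "dyslipidemia", "text": "cholesterol <200 mg/day"}]
        )
        (rule,) = parse_disease_rules(statements, resolver=self.RESOLVER).rules
        (bound,) = rule.restrict
        assert bound.amount == 200.0
        assert bound.unit == "mg"
        assert bound.bound_type == "max"

    def test_empty_table(self):
        parsed = parse_disease_rules(pd.DataFrame(columns=["disease_id", "text"]))
        assert parsed.rules == [] and parsed.unmatched == []

    def test_unmatched_reported_not_dropped(self):
        statements = pd.DataFrame(
            [{"disease_id": "gout", "text": "beer is inadvisable sometimes"}]
        )
        parsed = parse_disease_rules(statements)
        assert parsed.rules == []
        assert parsed.unmatched == [("gout", "beer is inadvisable sometimes")]

    def test_ambiguous_statement_raises(self):
        statements = pd.DataFrame(
            [{"disease_id": "gout",
              "text": "avoid shellfish and increase intake of vegetables"}]
        )
        with pytest.raises(AmbiguousStatementError):
            parse_disease_rules(statements)


def test_graph_json_roundtrip(small_kg, tmp_path):
    path = tmp_path / "kg.json"
    small_kg.to_json(path)
    back = KnowledgeGraph.from_json(path)
    assert back.to_dict() == small_kg.to_dict()


def test_networkx_export_counts(small_kg):
    g = small_kg.to_networkx()
    assert g.number_of_nodes() == len(small_kg.nodes_frame())
    assert g.number_of_edges() == len(small_kg.edges)
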