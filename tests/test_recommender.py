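"""Candidate filtering, preference ranking, combo assembly, constraints, pipeline."""

import math

import pandas as pd
import pytest

from mealcombo.foodkg import build_graph
from mealcombo.profiles import UserProfile
from mealcombo.recommender import (
    DEFAULT_TEMPLATES,
    EnergyBudget,
    adequacy_rank,
    check_constraints,
    cold_boot_rank,
    cosine_rank,
    enumerate_combos,
    filter_by_disease,
    recommend,
)
import oracles


def mini_kg(dish_rows, rule_rows=(), densities=None):
    """Small controlled world; dish_rows = (id, category, {ingredient: grams})."""
    densities = densities or {
        "chicken": {"energy": 150.0, "fat": 8.0, "cholesterol": 90.0},
        "cabbage": {"energy": 25.0, "fat": 0.2, "cholesterol": 0.0},
        "rice": {"energy": 130.0, "fat": 0.4, "cholesterol": 0.0},
        "tofu": {"energy": 90.0, "fat": 5.0, "cholesterol": 0.0},
    }
    categories = {"chicken": "meat", "cabbage": "vegetable", "rice": "cereal",
                  "tofu": "soy"}
    recipes = []
    for dish_id, category, comp in dish_rows:
        for ing, grams in comp.items():
            recipes.append(
                {"dish_id": dish_id, "name": dish_id, "category": category,
                 "flavor": "light", "cooking_method": "steamed", "price_level": 1,
                 "ingredient_id": ing, "grams": grams}
            )
    composition = []
    for ing, nutrient_map in densities.items():
        for nid, amount in nutrient_map.items():
            composition.append(
                {"ingredient_id": ing, "name": ing,
                 "category_id": categories.get(ing, "misc"), "nutrient_id": nid,
                 "amount_per_100g": amount, "unit": "kcal" if nid == "energy" else "mg"}
            )
    guidelines = pd.DataFrame(
        [
            {"nutrient_id": "energy", "name": "energy", "unit": "kcal",
             "low": 1200.0, "high": 1600.0},
            {"nutrient_id": "fat", "name": "fat", "unit": "g", "low": 20.0, "high": 60.0},
            {"nutrient_id": "cholesterol", "name": "cholesterol", "unit": "mg",
             "low": float("nan"), "high": float("nan")},
        ]
    )
    rules = pd.DataFrame(
        list(rule_rows),
        columns=["disease_id", "disease_name", "relation", "target_type",
                 "target_id", "bound_type", "amount", "unit", "source_text"],
    )
    return build_graph(pd.DataFrame(recipes), pd.DataFrame(composition), rules,
                       guidelines, standardize=False, dedup=False)


def make_user(uid="u", diseases=(), history=(), weight=60.0):
    return UserProfile(
        id=uid, sex="female", age_years=70, weight_kg=weight, bmi=24.0,
        income_band="middle", diseases=set(diseases), activity_level="light",
        preferences={"flavor": "light"},
        history=[(d, tuple(c)) for d, c in history],
    )


FIVE_DISHES = [
    ("a1", "animal-derived", {"chicken": 100.0}),
    ("a2", "animal-derived", {"chicken": 120.0}),
    ("v1", "vegan", {"cabbage": 200.0}),
    ("s1", "staple", {"rice": 150.0}),
    ("p1", "soup", {"cabbage": 80.0}),
]


class TestDiseaseFilter:
    def test_no_diseases_keeps_everything(self):
        kg = mini_kg(FIVE_DISHES)
        assert filter_by_disease(make_user(), kg) == set(kg.dishes)

    def test_discouraged_ingredient_removes_its_dishes(self):
        rule = {"disease_id": "gout", "disease_name": "gout",
                "relation": "discourage", "target_type": "ingredient",
                "target_id": "chicken", "bound_type": "", "amount": float("nan"),
                "unit": "", "source_text": ""}
        kg = mini_kg(FIVE_DISHES, [rule])
        # chicken appears in a1, a2: the other 3 dishes survive
        assert filter_by_disease(make_user(diseases=["gout"]), kg) == {"v1", "s1", "p1"}


class TestCosineRank:
    def test_hand_computed_scores(self):
        kg = mini_kg(
            [
                ("A", "vegan", {"cabbage": 100.0}),
                ("B", "vegan", {"tofu": 100.0}),
                ("C", "vegan", {"cabbage": 100.0, "tofu": 100.0}),
            ]
        )
        user = make_user(history=[(1, ("A",)), (2, ("A",)), (3, ("A",)),
                                  (4, ("A",)), (5, ("A",))])
        ranked = cosine_rank(user, {"A", "B", "C"}, kg)
        assert [d for d, _ in ranked] == ["A", "C", "B"]
        scores = dict(ranked)
        assert scores["A"] == pytest.approx(1.0)
        assert scores["C"] == pytest.approx(1 / math.sqrt(2))
        assert scores["B"] == pytest.approx(0.0)

    def test_candidate_identical_to_frequent_dish_tops(self):
        kg = mini_kg(FIVE_DISHES)
        user = make_user(history=[(d, ("a1",)) for d in range(5)])
        ranked = cosine_rank(user, set(kg.dishes), kg)
        assert ranked[0][0] in {"a1", "a2"}  # same single-ingredient direction
        assert ranked[0][1] == pytest.approx(1.0)

    def test_cold_boot_delegates_to_reference(self):
        kg = mini_kg(FIVE_DISHES)
        reference = make_user("ref", history=[(d, ("v1",)) for d in range(6)])
        newcomer = make_user("new")
        assert cold_boot_rank(newcomer, [reference], set(kg.dishes), kg) == cosine_rank(
            reference, set(kg.dishes), kg
        )

    def test_cold_boot_follows_most_similar_of_two(self):
        kg = mini_kg(FIVE_DISHES)
        like_me = make_user("twin", history=[(d, ("v1",)) for d in range(6)])
        unlike = make_user(
            "other", history=[(d, ("a1",)) for d in range(6)], diseases=["gout"],
        )
        unlike.sex = "male"
        unlike.age_years = 62
        unlike.preferences = {"flavor": "spicy"}
        newcomer = make_user("new")
        assert cold_boot_rank(newcomer, [unlike, like_me], set(kg.dishes), kg) == (
            cosine_rank(like_me, set(kg.dishes), kg)
        )


class TestEnumerate:
    def test_empty_pool(self, small_kg):
        assert enumerate_combos([], DEFAULT_TEMPLATES, 10, small_kg) == []

    def test_hand_counted_stock(self):
        """2 animal + 1 vegan + 1 staple + 1 soup admits exactly 4 combos."""
        kg = mini_kg(FIVE_DISHES)
        ranked = [(d, 0.0) for d in sorted(kg.dishes)]
        combos = enumerate_combos(ranked, DEFAULT_TEMPLATES, None, kg)
        by_template = {}
        for c in combos:
            by_template.setdefault(c.template.name, []).append(c)
        assert len(by_template.get("high-4a", [])) == 2
        assert "high-4b" not in by_template
        assert len(by_template.get("intermediate-high-3a", [])) == 2
        assert len(combos) == 4

    def test_low_tier_template_shape(self):
        low = next(t for t in DEFAULT_TEMPLATES if t.price_tier == "low")
        assert low.slots == (frozenset({"vegan"}), frozenset({"complete"}))
        assert low.dish_count == 2

    def test_cap_limits_per_template(self):
        kg = mini_kg(FIVE_DISHES)
        ranked = [(d, 0.0) for d in sorted(kg.dishes)]
        combos = enumerate_combos(ranked, DEFAULT_TEMPLATES, 1, kg)
        names = [c.template.name for c in combos]
        assert len(names) == len(set(names))


class TestConstraints:
    def test_clean_combo_passes(self):
        kg = mini_kg(FIVE_DISHES)
        ranked = [(d, 0.0) for d in sorted(kg.dishes)]
        combo = enumerate_combos(ranked, DEFAULT_TEMPLATES, None, kg)[0]
        # a1 + v1 + s1 + p1: energy 150 + 50 + 195 + 20 = 415 kcal
        report = check_constraints(combo, make_user(weight=50.0), kg, EnergyBudget())
        assert report.passed and report.violations == []

    def test_diabetic_energy_window(self):
        """60 kg diabetic: lunch window 360-525 kcal, a 600 kcal combo fails."""
        kg = mini_kg(
            [
                ("a1", "animal-derived", {"chicken": 200.0}),  # 300 kcal
                ("v1", "vegan", {"cabbage": 200.0}),           # 50
                ("s1", "staple", {"rice": 150.0}),             # 195
                ("p1", "soup", {"cabbage": 220.0}),            # 55
            ]
        )
        ranked = [(d, 0.0) for d in sorted(kg.dishes)]
        combo = enumerate_combos(ranked, DEFAULT_TEMPLATES, None, kg)[0]
        user = make_user(diseases=["diabetes"], weight=60.0)
        report = check_constraints(combo, user, kg, EnergyBudget())
        assert not report.passed
        assert any(v.startswith("energy") for v in report.violations)

    def test_cholesterol_bound_scaled_to_lunch(self):
        """200 mg/day at a 40% lunch share caps the combo at 80 mg."""
        rule = {"disease_id": "dyslipidemia", "disease_name": "dyslipidemia",
                "relation": "restrict", "target_type": "nutrient",
                "target_id": "cholesterol", "bound_type": "max", "amount": 200.0,
                "unit": "mg", "source_text": "cholesterol <200 mg/day"}
        kg = mini_kg(FIVE_DISHES, [rule])
        ranked = [(d, 0.0) for d in sorted(kg.dishes)]
        combo = next(
            c for c in enumerate_combos(ranked, DEFAULT_TEMPLATES, None, kg)
            if "a1" in c.dish_ids
        )  # 100 g chicken = 90 mg cholesterol > 80
        user = make_user(diseases=["dyslipidemia"], weight=50.0)
        report = check_constraints(combo, user, kg, EnergyBudget())
        assert any(v.startswith("restrict: cholesterol") for v in report.violations)

    def test_discouraged_dish_flagged(self):
        rule = {"disease_id": "gout", "disease_name": "gout",
                "relation": "discourage", "target_type": "ingredient",
                "target_id": "chicken", "bound_type": "", "amount": float("nan"),
                "unit": "", "source_text": ""}
        kg = mini_kg(FIVE_DISHES, [rule])
        ranked = [(d, 0.0) for d in sorted(kg.dishes)]
        combo = next(
            c for c in enumerate_combos(ranked, DEFAULT_TEMPLATES, None, kg)
            if "a1" in c.dish_ids
        )
        report = check_constraints(combo, make_user(diseases=["gout"]), kg)
        assert any(v.startswith("discouraged") for v in report.violations)


class TestAdequacyRank:
    def test_orders_by_criteria_count(self, small_kg):
        ranked = [(d, 0.0) for d in sorted(small_kg.dishes)]
        combos = enumerate_combos(ranked, DEFAULT_TEMPLATES, 20, small_kg)
        ordered = adequacy_rank(combos, small_kg, EnergyBudget())
        counts = [c.adequacy_count for c in ordered]
        assert counts == sorted(counts, reverse=True)
        # every count equals the hand-summed oracle
        for combo in ordered:
            assert combo.adequacy_count == oracles.adequacy(combo.dish_ids, small_kg)

    def test_stable_tie_break(self, small_kg):
        ranked = [(d, 0.0) for d in sorted(small_kg.dishes)]
        combos = enumerate_combos(ranked, DEFAULT_TEMPLATES, 20, small_kg)
        once = adequacy_rank(list(combos), small_kg)
        twice = adequacy_rank(list(reversed(combos)), small_kg)
        assert [c.dish_ids for c in once] == [c.dish_ids for c in twice]


class TestRecommendPipeline:
    def test_single_feasible_combo_with_warning(self):
        kg = mini_kg(
            [
                ("v1", "vegan", {"cabbage": 200.0, "tofu": 100.0}),  # 140 kcal
                ("c1", "complete", {"rice": 200.0, "cabbage": 100.0}),  # 285
            ]
        )
        user = make_user(weight=50.0, history=[(d, ("v1",)) for d in range(5)])
        result = recommend(user, kg, n_options=5)
        assert len(result.combos) == 1
        assert result.combos[0].dish_ids == ("v1", "c1")
        assert result.warnings

    def test_matches_bruteforce_oracle(self, small_kg, small_cohort):
        pool = [u for u in small_cohort if u.history_length() >= 5]
        for user in small_cohort[:6]:
            if not pool and user.history_length() < 5:
                continue
            got = recommend(user, small_kg, pool, n_options=5, per_template_cap=None)
            expected = oracles.brute_force_recommend(user, small_kg, pool, n_options=5)
            assert [(c.dish_ids, c.adequacy_count) for c in got.combos] == expected

    def test_safety_no_discouraged_dish_ever(self, small_kg, small_cohort):
        pool = [u for u in small_cohort if u.history_length() >= 5]
        for user in small_cohort:
            result = recommend(user, small_kg, pool)
            banned = oracles.banned_dishes(user, small_kg)
            for combo in result.combos:
                assert not banned & set(combo.dish_ids)
                assert oracles.matches_some_template(combo.dish_ids, small_kg)

    def test_adding_a_disease_never_enlarges_feasible_set(self, small_kg, small_cohort):
        pool = [u for u in small_cohort if u.history_length() >= 5]
        user = next(u for u in small_cohort if u.history_length() >= 5)
        base = recommend(user, small_kg, pool, n_options=10**6, per_template_cap=None)
        base_set = {frozenset(c.dish_ids) for c in base.combos}
        overrides = set(EnergyBudget().disease_overrides)
        plain = [d for d in sorted(small_kg.diseases) if d not in overrides]
        for disease_id in plain[:3]:
            sick = make_user(
                "sick", diseases=set(user.diseases) | {disease_id},
                history=user.history, weight=user.weight_kg,
            )
            narrowed = recommend(sick, small_kg, pool, n_options=10**6,
                                 per_template_cap=None)
            assert {frozenset(c.dish_ids) for c in narrowed.combos} <= base_set

    def test_deterministic(self, small_kg, small_cohort):
        pool = [u for u in small_cohort if u.history_length() >= 5]
        user = small_cohort[0]
        first = recommend(user, small_kg, pool)
        second = recommend(user, small_kg, pool)
        assert [c.dish_ids for c in first.combos] == [c.dish_ids for c in second.combos]
        assert [c.adequacy_count for c in first.combos] == [
            c.adequacy_count for c in second.combos
        ]
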