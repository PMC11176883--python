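import hypothesis
import pandas as pd
import pytest

from mealcombo.foodkg import KnowledgeGraph, build_graph
from mealcombo.syndata import WorldSpec, generate_cohort, generate_food_database

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")


def toy_tables():
    """A hand-checkable two-ingredient world used across unit tests."""
    recipes = pd.DataFrame(
        [
            # braised pork over rice: 150 g pork + 50 g rice
            {"dish_id": "d1", "name": "braised pork rice", "category": "complete",
             "flavor": "salty", "cooking_method": "braised", "price_level": 2,
             "ingredient_id": "pork", "grams": 150.0},
            {"dish_id": "d1", "name": "braised pork rice", "category": "complete",
             "flavor": "salty", "cooking_method": "braised", "price_level": 2,
             "ingredient_id": "rice", "grams": 50.0},
        ]
    )
    composition = pd.DataFrame(
        [
            {"ingredient_id": "pork", "name": "pork", "category_id": "meat",
             "nutrient_id": "iron", "amount_per_100g": 2.0, "unit": "mg"},
            {"ingredient_id": "pork", "name": "pork", "category_id": "meat",
             "nutrient_id": "vitamin_c", "amount_per_100g": 0.0, "unit": "mg"},
            {"ingredient_id": "rice", "name": "rice", "category_id": "cereal",
             "nutrient_id": "iron", "amount_per_100g": 1.0, "unit": "mg"},
            {"ingredient_id": "rice", "name": "rice", "category_id": "cereal",
             "nutrient_id": "vitamin_c", "amount_per_100g": 0.0, "unit": "mg"},
        ]
    )
    disease_rules = pd.DataFrame(
        [
            {"disease_id": "gout", "disease_name": "gout", "relation": "discourage",
             "target_type": "ingredient", "target_id": "pork", "bound_type": "",
             "amount": float("nan"), "unit": "", "source_text": ""},
        ]
    )
    guidelines = pd.DataFrame(
        [
            {"nutrient_id": "iron", "name": "iron", "unit": "mg", "low": 5.0, "high": 20.0},
            {"nutrient_id": "vitamin_c", "name": "vitamin c", "unit": "mg",
             "low": 50.0, "high": 200.0},
        ]
    )
    return recipes, composition, disease_rules, guidelines


@pytest.fixture()
def toy_kg() -> KnowledgeGraph:
    recipes, composition, rules, guidelines = toy_tables()
    return build_graph(recipes, composition, rules, guidelines, standardize=False)


SMALL_SPEC = WorldSpec(
    n_dishes=16, n_ingredients=16, n_categories=8, n_nutrients=8,
    n_diseases=5, cohort_size=10, seed=11,
)


@pytest.fixture(scope="module")
def small_kg() -> KnowledgeGraph:
    return generate_food_database(SMALL_SPEC).build()


@pytest.fixture(scope="module")
def small_cohort(small_kg):
    return generate_cohort(SMALL_SPEC, small_kg)


DEFAULT_SPEC = WorldSpec(seed=1)


@pytest.fixture(scope="session")
def default_kg() -> KnowledgeGraph:
    return generate_food_database(DEFAULT_SPEC).build()


@pytest.fixture(scope="session")
def default_cohort(default_kg):
    return generate_cohort(DEFAULT_SPEC, default_kg)
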