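"""Seeded synthetic food databases and older-adult cohorts.

No recipe database or participant data ships with the package, so every
other module is exercised against generated worlds that reproduce the
structural census of the real system -- 180 dishes, 112 ingredients, 20
ingredient categories, 27 nutrients, 30 geriatric diseases -- and a 96-person
cohort with the reported disease prevalences (hypertension 59%, arthritis
31%, diabetes 24%) and multimorbidity level (~38% with three or more
conditions, induced by a shared latent-frailty factor in a Gaussian copula).

Nutrient densities are drawn from per-food-kind log-uniform priors recorded
in :data:`NUTRIENT_PRIORS`; guideline ranges and restriction bounds are
calibrated against the generated food supply so that a typical combo
satisfies some, but not all, guideline criteria. Everything is deterministic
for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .foodkg import (
    Dish,
    Ingredient,
    IngredientCategory,
    KnowledgeGraph,
    Nutrient,
    StandardizationError,
    build_graph,
    standardize_sodium,
)
from .profiles import UserProfile
from .recommender import DEFAULT_TEMPLATES, ComboTemplate, filter_by_disease, kg_index


class SpecError(ValueError):
    """Raised when a world specification cannot support generation."""


class GenerationError(RuntimeError):
    """Raised when a requested artifact cannot be generated (e.g. no feasible combo)."""


# ---------------------------------------------------------------------------
# world specification
# ---------------------------------------------------------------------------


@dataclass
class WorldSpec:
    n_dishes: int = 180
    n_ingredients: int = 112
    n_categories: int = 20
    n_nutrients: int = 27
    n_diseases: int = 30
    cohort_size: int = 96
    tracked_fraction: float = 0.35
    disease_prevalences: dict[str, float] = field(
        default_factory=lambda: {
            "hypertension": 0.59,
            "arthritis": 0.31,
            "diabetes": 0.24,
        }
    )
    #: shared-frailty loading of the disease copula; drives multimorbidity
    frailty_correlation: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_dishes", "n_ingredients", "n_categories", "n_nutrients",
            "n_diseases", "cohort_size",
        ):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be >= 0")
        for disease, p in self.disease_prevalences.items():
            if not 0 <= p <= 1:
                raise SpecError(f"prevalence of {disease!r} outside [0, 1]")
        if not 0 <= self.tracked_fraction <= 1:
            raise SpecError("tracked_fraction outside [0, 1]")
        if not 0 <= self.frailty_correlation < 1:
            raise SpecError("frailty_correlation outside [0, 1)")


# ---------------------------------------------------------------------------
# canonical vocabularies (ordered so small worlds keep the essential kinds)
# ---------------------------------------------------------------------------

# (id, dds_group, kind); kind selects nutrient priors and dish-building roles
CATEGORY_POOL: tuple[tuple[str, str, str], ...] = (
    ("rice_grains", "cereals_tubers", "cereal"),
    ("dark_vegetables", "vegetables", "vegetable"),
    ("pork", "meat", "meat"),
    ("seasonings", "none", "seasoning"),
    ("plant_oils", "oils_fats", "oil"),
    ("fish", "fish_seafood", "fish"),
    ("eggs", "eggs", "egg"),
    ("soy_products", "legumes_nuts", "legume"),
    ("fruits", "fruits", "fruit"),
    ("dairy", "dairy", "dairy"),
    ("wheat_products", "cereals_tubers", "cereal"),
    ("light_vegetables", "vegetables", "vegetable"),
    ("poultry", "meat", "meat"),
    ("tubers", "cereals_tubers", "cereal"),
    ("beef_lamb", "meat", "meat"),
    ("fungi_algae", "vegetables", "vegetable"),
    ("shellfish", "fish_seafood", "fish"),
    ("nuts_seeds", "legumes_nuts", "nut"),
    ("legumes", "legumes_nuts", "legume"),
    ("organ_meats", "meat", "meat"),
)

# (id, unit); ordered so the structurally required nutrients come first
NUTRIENT_POOL: tuple[tuple[str, str], ...] = (
    ("energy", "kcal"), ("protein", "g"), ("fat", "g"), ("carbohydrate", "g"),
    ("sodium", "mg"), ("fiber", "g"), ("cholesterol", "mg"), ("calcium", "mg"),
    ("iron", "mg"), ("zinc", "mg"), ("potassium", "mg"), ("magnesium", "mg"),
    ("vitamin_c", "mg"), ("vitamin_a", "ug"), ("vitamin_b1", "mg"),
    ("vitamin_b2", "mg"), ("vitamin_b6", "mg"), ("vitamin_b12", "ug"),
    ("vitamin_d", "ug"), ("vitamin_e", "mg"), ("folate", "ug"),
    ("niacin", "mg"), ("selenium", "ug"), ("phosphorus", "mg"),
    ("copper", "mg"), ("manganese", "mg"), ("iodine", "ug"),
)

DISEASE_POOL: tuple[str, ...] = (
    "hypertension", "arthritis", "diabetes", "dyslipidemia",
    "coronary_heart_disease", "stroke", "copd", "asthma", "gout",
    "osteoporosis", "chronic_kidney_disease", "chronic_gastritis",
    "peptic_ulcer", "fatty_liver", "gallstones", "cataract", "glaucoma",
    "hearing_loss", "parkinsons_disease", "dementia", "depression",
    "insomnia", "anemia", "hyperthyroidism", "hypothyroidism",
    "prostate_hyperplasia", "urinary_incontinence", "constipation",
    "diverticulosis", "heart_failure",
)

#: Log-uniform (low, high) nutrient priors per 100 g by food kind. Amounts
#: are in each nutrient's native unit, on an as-served basis (cooked
#: staples, raw-weight vegetables and meats). Nutrients absent for a kind
#: fall back to the "trace" row.
NUTRIENT_PRIORS: dict[str, dict[str, tuple[float, float]]] = {
    "cereal": {"energy": (110, 200), "protein": (2.5, 5), "fat": (0.3, 1.5),
               "carbohydrate": (23, 42), "fiber": (0.8, 3),
               "vitamin_b1": (0.1, 0.4), "niacin": (1.5, 5), "manganese": (0.5, 2),
               "magnesium": (20, 90), "selenium": (5, 25)},
    "vegetable": {"energy": (15, 45), "protein": (1, 3), "fat": (0.1, 0.6),
                  "carbohydrate": (3, 8), "fiber": (1, 3.5), "vitamin_c": (15, 80),
                  "vitamin_a": (50, 500), "folate": (40, 180), "potassium": (150, 450),
                  "vitamin_e": (0.3, 2)},
    "fruit": {"energy": (40, 75), "protein": (0.3, 1), "fat": (0.1, 0.5),
              "carbohydrate": (9, 18), "fiber": (1, 3), "vitamin_c": (20, 90),
              "potassium": (100, 350), "folate": (10, 60)},
    "meat": {"energy": (110, 220), "protein": (14, 22), "fat": (3, 12),
             "carbohydrate": (0.2, 2), "cholesterol": (50, 140), "iron": (1.5, 5),
             "zinc": (2, 6), "vitamin_b12": (0.5, 3), "vitamin_b6": (0.2, 0.6),
             "niacin": (3, 9), "phosphorus": (140, 250), "selenium": (8, 25)},
    "fish": {"energy": (85, 170), "protein": (15, 21), "fat": (2, 9),
             "carbohydrate": (0.2, 2), "cholesterol": (40, 110),
             "vitamin_d": (2, 12), "vitamin_b12": (1, 8), "selenium": (15, 50),
             "iodine": (10, 80), "phosphorus": (150, 280), "zinc": (0.5, 3)},
    "egg": {"energy": (135, 165), "protein": (11, 14), "fat": (8.5, 11.5),
            "carbohydrate": (0.8, 2), "cholesterol": (380, 600),
            "vitamin_a": (150, 350), "vitamin_d": (1, 3), "vitamin_b12": (0.6, 1.5),
            "vitamin_b2": (0.3, 0.6), "selenium": (15, 35), "phosphorus": (150, 230)},
    "dairy": {"energy": (50, 95), "protein": (2.5, 4.2), "fat": (2, 4.5),
              "carbohydrate": (3.5, 6), "calcium": (90, 130),
              "vitamin_b2": (0.12, 0.3), "vitamin_b12": (0.3, 0.7),
              "vitamin_d": (0.5, 1.5), "phosphorus": (70, 110)},
    "legume": {"energy": (80, 210), "protein": (7, 18), "fat": (3, 11),
               "carbohydrate": (3, 12), "fiber": (1.5, 6), "folate": (40, 160),
               "magnesium": (30, 110), "potassium": (120, 500), "iron": (1.5, 5),
               "calcium": (60, 200)},
    "nut": {"energy": (540, 650), "protein": (14, 26), "fat": (44, 62),
            "carbohydrate": (8, 20), "fiber": (4, 10), "vitamin_e": (5, 25),
            "magnesium": (100, 300), "copper": (0.8, 2), "manganese": (1, 4)},
    "oil": {"energy": (860, 900), "fat": (96, 100), "vitamin_e": (15, 60)},
    "seasoning": {"energy": (5, 60), "carbohydrate": (1, 10)},
    "trace": {"sodium": (10, 90), "calcium": (4, 40), "iron": (0.1, 1),
              "zinc": (0.1, 0.8), "potassium": (30, 150), "magnesium": (5, 25),
              "vitamin_c": (0.2, 3), "vitamin_a": (1, 30), "vitamin_b1": (0.01, 0.1),
              "vitamin_b2": (0.01, 0.1), "vitamin_b6": (0.01, 0.12),
              "vitamin_b12": (0.01, 0.2), "vitamin_d": (0.01, 0.3),
              "vitamin_e": (0.05, 0.8), "folate": (2, 25), "niacin": (0.1, 1.5),
              "selenium": (0.5, 5), "phosphorus": (20, 100), "copper": (0.02, 0.25),
              "manganese": (0.03, 0.5), "iodine": (0.3, 8), "cholesterol": (0.1, 2),
              "fiber": (0.05, 0.6), "protein": (0.2, 1.5), "fat": (0.05, 0.8),
              "carbohydrate": (0.2, 3), "energy": (5, 40)},
}

#: Sodium content of the two canonical salty seasonings (mg per 100 g).
SALT_SODIUM_MG = 39000.0
SOY_SAUCE_SODIUM_MG = 6000.0

DISH_CATEGORY_SHARES = {
    "animal-derived": 0.19,
    "vegan": 0.22,
    "omnivorous": 0.19,
    "staple": 0.17,
    "soup": 0.14,
    "complete": 0.09,
}

FLAVORS = ("salty", "light", "sweet", "spicy", "sour")
COOKING_METHODS = ("stir-fried", "steamed", "boiled", "braised", "stewed", "cold-dressed")
STAPLE_PREFS = ("rice", "noodles", "steamed_bread")
OIL_PREFS = ("peanut_oil", "rapeseed_oil", "corn_oil")
INCOME_BANDS = ("low", "middle", "high")
ACTIVITY_LEVELS = ("light", "moderate", "vigorous")


@dataclass
class FoodTables:
    """The four input tables plus the category table, as DataFrames."""

    recipes: pd.DataFrame
    composition: pd.DataFrame
    disease_rules: pd.DataFrame
    guidelines: pd.DataFrame
    categories: pd.DataFrame

    def build(self, **kwargs) -> KnowledgeGraph:
        return build_graph(
            self.recipes,
            self.composition,
            self.disease_rules,
            self.guidelines,
            self.categories,
            **kwargs,
        )


# ---------------------------------------------------------------------------
# food database
# ---------------------------------------------------------------------------


def _loguniform(rng: np.random.Generator, low: float, high: float) -> float:
    return float(np.exp(rng.uniform(np.log(low), np.log(high))))


def _allocate(total: int, shares: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation with every key getting at least one."""
    keys = list(shares)
    raw = {k: total * shares[k] for k in keys}
    counts = {k: max(1, int(raw[k])) for k in keys}
    while sum(counts.values()) > total:
        k = max(counts, key=lambda k: (counts[k], k))
        if counts[k] > 1:
            counts[k] -= 1
        else:
            break
    order = sorted(keys, key=lambda k: (raw[k] - int(raw[k])), reverse=True)
    i = 0
    while sum(counts.values()) < total:
        counts[order[i % len(order)]] += 1
        i += 1
    return counts


def generate_food_database(spec: WorldSpec) -> FoodTables:
    """Generate the recipe, composition, rule, and guideline tables.

    Every dish category needed by the combo templates is represented, every
    ingredient is categorized, each disease carries at least one discourage
    and one restrict relation, and guideline ranges are calibrated around the
    generated food supply. Deterministic for a fixed ``spec.seed``.
    """
    spec.validate()
    if spec.n_dishes == 0:
        empty = pd.DataFrame(
            columns=["dish_id", "name", "category", "flavor", "cooking_method",
                     "price_level", "ingredient_id", "grams"]
        )
        # an empty recipe table is legal; combos are then simply impossible
        return FoodTables(
            recipes=empty,
            composition=pd.DataFrame(
                columns=["ingredient_id", "name", "category_id", "nutrient_id",
                         "amount_per_100g", "unit"]
            ),
            disease_rules=pd.DataFrame(
                columns=["disease_id", "disease_name", "relation", "target_type",
                         "target_id", "bound_type", "amount", "unit", "source_text"]
            ),
            guidelines=pd.DataFrame(columns=["nutrient_id", "name", "unit", "low", "high"]),
            categories=pd.DataFrame(
                columns=["category_id", "name", "dds_group", "is_seasoning"]
            ),
        )
    if spec.n_dishes < len(DISH_CATEGORY_SHARES):
        raise SpecError(
            f"n_dishes={spec.n_dishes} cannot cover the "
            f"{len(DISH_CATEGORY_SHARES)} combo dish categories"
        )
    if spec.n_categories < 5:
        raise SpecError("need at least 5 ingredient categories (incl. seasonings, oils)")
    if spec.n_nutrients < 5:
        raise SpecError("need at least the 5 leading nutrients")
    if spec.n_ingredients < spec.n_categories:
        raise SpecError("need at least one ingredient per category")

    seeds = np.random.SeedSequence([spec.seed, 101]).generate_state(1)
    rng = np.random.default_rng(seeds)

    categories = [
        IngredientCategory(id=cid, name=cid.replace("_", " "), dds_group=group,
                           is_seasoning=(kind == "seasoning"))
        for cid, group, kind in CATEGORY_POOL[: spec.n_categories]
    ]
    kind_of = {cid: kind for cid, _g, kind in CATEGORY_POOL[: spec.n_categories]}
    nutrients = [
        Nutrient(id=nid, name=nid.replace("_", " "), unit=unit)
        for nid, unit in NUTRIENT_POOL[: spec.n_nutrients]
    ]
    nutrient_ids = [n.id for n in nutrients]

    # -- ingredients -------------------------------------------------------
    per_cat = _allocate(
        spec.n_ingredients, {c.id: 1.0 / len(categories) for c in categories}
    )
    ingredients: list[Ingredient] = []
    for category in categories:
        kind = kind_of[category.id]
        priors = NUTRIENT_PRIORS.get(kind, {})
        trace = NUTRIENT_PRIORS["trace"]
        for j in range(per_cat[category.id]):
            ing_id = f"{category.id}_{j:02d}"
            name = ing_id.replace("_", " ")
            density: dict[str, float] = {}
            for nid in nutrient_ids:
                lohi = priors.get(nid) or trace.get(nid)
                if lohi is None:
                    continue
                density[nid] = round(_loguniform(rng, *lohi), 4)
            if kind == "seasoning":
                if j == 0:
                    ing_id, name = f"{category.id}_salt", "salt"
                    density["sodium"] = SALT_SODIUM_MG
                    density["energy"] = 0.0
                elif j == 1:
                    density["sodium"] = SOY_SAUCE_SODIUM_MG
            ingredients.append(
                Ingredient(id=ing_id, name=name, category_id=category.id,
                           nutrient_per_100g=density)
            )
    by_kind: dict[str, list[Ingredient]] = {}
    for ing in ingredients:
        by_kind.setdefault(kind_of[ing.category_id], []).append(ing)
    salt = next(i for i in by_kind.get("seasoning", []) if i.name == "salt")

    # -- dishes ------------------------------------------------------------
    def pick(kinds: tuple[str, ...]) -> Ingredient:
        pool = [i for k in kinds for i in by_kind.get(k, [])]
        if not pool:
            raise SpecError(f"no ingredients of kinds {kinds} available")
        return pool[rng.integers(len(pool))]

    main_protein = ("meat", "fish", "egg", "legume")
    dish_counts = _allocate(spec.n_dishes, DISH_CATEGORY_SHARES)
    dishes: list[Dish] = []
    seen_sets: set[frozenset] = set()
    serial = 0
    for dish_category, count in dish_counts.items():
        for _ in range(count):
            comp: dict[str, float] = {}

            def add(ing: Ingredient, lo: float, hi: float) -> None:
                comp[ing.id] = comp.get(ing.id, 0.0) + round(float(rng.uniform(lo, hi)), 1)

            def build_one() -> None:
                comp.clear()
                if dish_category == "staple":
                    add(pick(("cereal",)), 100, 165)
                    if rng.random() < 0.5:
                        add(pick(("cereal", "legume", "vegetable")), 15, 50)
                elif dish_category == "vegan":
                    add(pick(("vegetable",)), 120, 220)
                    if rng.random() < 0.5:
                        add(pick(("vegetable", "fruit", "legume", "nut")), 20, 60)
                    if rng.random() < 0.7:  # steamed/boiled dishes use no oil
                        add(pick(("oil",)), 2, 5)
                elif dish_category == "animal-derived":
                    add(pick(main_protein[:3]), 70, 125)
                    if rng.random() < 0.5:
                        add(pick(("vegetable",)), 20, 60)
                    if rng.random() < 0.7:
                        add(pick(("oil",)), 2, 5)
                elif dish_category == "omnivorous":
                    add(pick(main_protein), 40, 80)
                    add(pick(("vegetable",)), 80, 150)
                    if rng.random() < 0.7:
                        add(pick(("oil",)), 2, 5)
                elif dish_category == "soup":
                    add(pick(("vegetable", "egg", "fish", "dairy")), 40, 110)
                    if rng.random() < 0.3:
                        add(pick(("vegetable",)), 20, 60)
                elif dish_category == "complete":
                    add(pick(("cereal",)), 90, 140)
                    add(pick(main_protein), 40, 70)
                    add(pick(("vegetable",)), 60, 100)
                    if rng.random() < 0.6:
                        add(pick(("oil",)), 2, 5)
                comp[salt.id] = comp.get(salt.id, 0.0) + round(float(rng.uniform(1.0, 4.0)), 1)

            # distinct ingredient sets keep dishes apart at the 0.85 dedup bar
            for _attempt in range(40):
                build_one()
                if frozenset(comp) not in seen_sets:
                    break
            seen_sets.add(frozenset(comp))
            serial += 1
            dishes.append(
                Dish(
                    id=f"dish_{serial:03d}",
                    name=f"{dish_category} dish {serial}",
                    dish_category=dish_category,
                    flavor=FLAVORS[rng.integers(len(FLAVORS))],
                    cooking_method=COOKING_METHODS[rng.integers(len(COOKING_METHODS))],
                    price_level=int(rng.integers(1, 5)),
                    composition=comp,
                )
            )

    # pre-standardize sodium so the emitted tables already sit in the band
    scratch = KnowledgeGraph(
        ingredients={i.id: i for i in ingredients},
        categories={c.id: c for c in categories},
        nutrients={n.id: n for n in nutrients},
    )
    standardized: list[Dish] = []
    for dish in dishes:
        try:
            standardized.append(standardize_sodium(dish, scratch))
        except StandardizationError:
            standardized.append(dish)
    dishes = standardized

    # -- guideline calibration against the generated food supply -----------
    lunch_fraction = 0.40
    totals = _sample_combo_totals(dishes, scratch, nutrient_ids, rng, n_samples=120)
    guide_rows = []
    for ni, nutrient in enumerate(nutrients):
        column = totals[:, ni]
        low = float(np.percentile(column, 35)) / lunch_fraction
        high = float(np.percentile(column, 85)) / lunch_fraction
        if high <= low:
            high = low * 1.2 + 1e-9
        nutrient.guideline_low = round(low, 3)
        nutrient.guideline_high = round(high, 3)
        guide_rows.append(
            {"nutrient_id": nutrient.id, "name": nutrient.name, "unit": nutrient.unit,
             "low": nutrient.guideline_low, "high": nutrient.guideline_high}
        )

    # -- disease rules -----------------------------------------------------
    disease_names = list(DISEASE_POOL[: spec.n_diseases])
    extra = spec.n_diseases - len(DISEASE_POOL)
    disease_names += [f"condition_{i:02d}" for i in range(max(0, extra))]
    protected_kinds = {"seasoning", "oil", "cereal"}
    discourageable = [
        i for i in ingredients if kind_of[i.category_id] not in protected_kinds
    ]
    nonessential_categories = [
        c.id for c in categories
        if c.id in {"shellfish", "organ_meats", "nuts_seeds", "fungi_algae"}
    ]
    rule_rows = []
    p90 = {
        nid: float(np.percentile(totals[:, ni], 90)) / lunch_fraction
        for ni, nid in enumerate(nutrient_ids)
    }
    restrictable = [n for n in nutrient_ids if n != "energy"]
    for di, disease in enumerate(disease_names):
        used: set[str] = set()
        n_discourage = 1 + int(rng.random() < 0.4)
        for _ in range(n_discourage):
            if disease == "gout" and nonessential_categories and rng.random() < 0.8:
                target, target_type = "shellfish", "category"
                if target not in {c.id for c in categories}:
                    target, target_type = discourageable[rng.integers(len(discourageable))].id, "ingredient"
            elif nonessential_categories and rng.random() < 0.08:
                target = nonessential_categories[rng.integers(len(nonessential_categories))]
                target_type = "category"
            else:
                target = discourageable[rng.integers(len(discourageable))].id
                target_type = "ingredient"
            if target in used:
                continue
            used.add(target)
            rule_rows.append(
                {"disease_id": disease, "disease_name": disease.replace("_", " "),
                 "relation": "discourage", "target_type": target_type,
                 "target_id": target, "bound_type": "", "amount": np.nan, "unit": "",
                 "source_text": f"patients with {disease.replace('_', ' ')} should avoid {target}"}
            )
        n_restrict = 1 + int(rng.random() < 0.35)
        candidates = [n for n in restrictable if n not in used]
        chosen = rng.choice(len(candidates), size=min(n_restrict, len(candidates)),
                            replace=False)
        for ci in np.atleast_1d(chosen):
            nid = candidates[int(ci)]
            used.add(nid)
            amount = round(p90[nid], 3)
            unit = dict(NUTRIENT_POOL).get(nid, "g")
            rule_rows.append(
                {"disease_id": disease, "disease_name": disease.replace("_", " "),
                 "relation": "restrict", "target_type": "nutrient", "target_id": nid,
                 "bound_type": "max", "amount": amount, "unit": unit,
                 "source_text": f"limit {nid.replace('_', ' ')} to less than {amount} {unit}/day"}
            )
        recommendables = [n for n in nutrient_ids if n not in used]
        if recommendables:
            nid = recommendables[int(rng.integers(len(recommendables)))]
            rule_rows.append(
                {"disease_id": disease, "disease_name": disease.replace("_", " "),
                 "relation": "recommend", "target_type": "nutrient", "target_id": nid,
                 "bound_type": "", "amount": np.nan, "unit": "",
                 "source_text": f"increase intake of {nid.replace('_', ' ')}"}
            )

    # -- to tables ---------------------------------------------------------
    recipe_rows = []
    for dish in dishes:
        for ingredient_id, grams in dish.composition.items():
            recipe_rows.append(
                {"dish_id": dish.id, "name": dish.name, "category": dish.dish_category,
                 "flavor": dish.flavor, "cooking_method": dish.cooking_method,
                 "price_level": dish.price_level, "ingredient_id": ingredient_id,
                 "grams": grams}
            )
    comp_rows = []
    for ing in ingredients:
        for nid, amount in ing.nutrient_per_100g.items():
            comp_rows.append(
                {"ingredient_id": ing.id, "name": ing.name,
                 "category_id": ing.category_id, "nutrient_id": nid,
                 "amount_per_100g": amount,
                 "unit": dict(NUTRIENT_POOL).get(nid, "g")}
            )
    cat_rows = [
        {"category_id": c.id, "name": c.name, "dds_group": c.dds_group,
         "is_seasoning": c.is_seasoning}
        for c in categories
    ]
    return FoodTables(
        recipes=pd.DataFrame(recipe_rows),
        composition=pd.DataFrame(comp_rows),
        disease_rules=pd.DataFrame(rule_rows),
        guidelines=pd.DataFrame(guide_rows),
        categories=pd.DataFrame(cat_rows),
    )


def _sample_combo_totals(
    dishes: list[Dish],
    scratch: KnowledgeGraph,
    nutrient_ids: list[str],
    rng: np.random.Generator,
    n_samples: int,
) -> np.ndarray:
    """Lunch nutrient totals of randomly assembled template combos."""
    by_cat: dict[str, list[Dish]] = {}
    for dish in dishes:
        by_cat.setdefault(dish.dish_category, []).append(dish)
    pos = {nid: i for i, nid in enumerate(nutrient_ids)}
    dish_vec: dict[str, np.ndarray] = {}
    for dish in dishes:
        v = np.zeros(len(nutrient_ids))
        for ing_id, grams in dish.composition.items():
            for nid, per100 in scratch.ingredients[ing_id].nutrient_per_100g.items():
                if nid in pos:
                    v[pos[nid]] += per100 * grams / 100.0
        dish_vec[dish.id] = v
    rows = []
    templates = [t for t in DEFAULT_TEMPLATES]
    for _ in range(n_samples):
        template = templates[rng.integers(len(templates))]
        total = np.zeros(len(nutrient_ids))
        chosen: set[str] = set()
        ok = True
        for slot in template.slots:
            pool = [d for c in slot for d in by_cat.get(c, []) if d.id not in chosen]
            if not pool:
                ok = False
                break
            dish = pool[rng.integers(len(pool))]
            chosen.add(dish.id)
            total += dish_vec[dish.id]
        if ok:
            rows.append(total)
    if not rows:
        # degenerate world: fall back to single dishes
        rows = [dish_vec[d.id] for d in dishes]
    return np.vstack(rows)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

AGE_BAND_PROBS = ((60, 64, 0.14), (65, 79, 0.69), (80, 90, 0.17))
BMI_BAND_PROBS = ((17.0, 19.9, 0.02), (20.0, 26.9, 0.70), (27.0, 33.0, 0.28))


def generate_cohort(
    spec: WorldSpec,
    kg: KnowledgeGraph | None = None,
    with_history: bool = True,
) -> list[UserProfile]:
    """Generate ``spec.cohort_size`` older-adult profiles.

    Age, BMI, and sex follow the banded distributions of the study cohort;
    diseases are drawn from a Gaussian copula with a shared latent frailty
    factor so the stated marginal prevalences hold exactly while
    multimorbidity clusters. A ``tracked_fraction`` share of users receives
    at least five history records assembled from disease-safe dishes of the
    generated food database (requires ``kg``; built from ``spec`` if absent).
    """
    spec.validate()
    if spec.cohort_size == 0:
        return []
    if kg is None and with_history:
        kg = generate_food_database(spec).build()

    seeds = np.random.SeedSequence([spec.seed, 202]).generate_state(1)
    rng = np.random.default_rng(seeds)
    n = spec.cohort_size

    disease_names = list(DISEASE_POOL[: spec.n_diseases])
    disease_names += [
        f"condition_{i:02d}" for i in range(max(0, spec.n_diseases - len(DISEASE_POOL)))
    ]
    prevalences = np.empty(len(disease_names))
    for j, name in enumerate(disease_names):
        if name in spec.disease_prevalences:
            prevalences[j] = spec.disease_prevalences[name]
        else:
            prevalences[j] = rng.uniform(0.02, 0.09)

    r = spec.frailty_correlation
    z = rng.standard_normal(n)
    noise = rng.standard_normal((n, len(disease_names)))
    latent = math.sqrt(r) * z[:, None] + math.sqrt(1 - r) * noise
    thresholds = stats.norm.ppf(prevalences)
    present = latent < thresholds

    age_bands = np.array([p for _lo, _hi, p in AGE_BAND_PROBS])
    bmi_bands = np.array([p for _lo, _hi, p in BMI_BAND_PROBS])
    users: list[UserProfile] = []
    for i in range(n):
        sex = "male" if rng.random() < 0.53 else "female"
        lo, hi, _ = AGE_BAND_PROBS[rng.choice(len(AGE_BAND_PROBS), p=age_bands / age_bands.sum())]
        age = int(rng.integers(lo, hi + 1))
        lo, hi, _ = BMI_BAND_PROBS[rng.choice(len(BMI_BAND_PROBS), p=bmi_bands / bmi_bands.sum())]
        bmi = float(rng.uniform(lo, hi))
        height = rng.normal(1.67 if sex == "male" else 1.57, 0.05)
        weight = round(bmi * height * height, 1)
        users.append(
            UserProfile(
                id=f"user_{i:03d}",
                sex=sex,
                age_years=age,
                weight_kg=float(weight),
                bmi=round(bmi, 1),
                income_band=INCOME_BANDS[rng.choice(3, p=[0.3, 0.5, 0.2])],
                diseases={disease_names[j] for j in np.flatnonzero(present[i])},
                activity_level=ACTIVITY_LEVELS[rng.choice(3, p=[0.5, 0.4, 0.1])],
                preferences={
                    "flavor": FLAVORS[rng.integers(len(FLAVORS))],
                    "staple": STAPLE_PREFS[rng.integers(len(STAPLE_PREFS))],
                    "oil": OIL_PREFS[rng.integers(len(OIL_PREFS))],
                    "cooking_method": COOKING_METHODS[rng.integers(len(COOKING_METHODS))],
                },
            )
        )

    if with_history and kg is not None:
        n_tracked = int(round(spec.tracked_fraction * n))
        tracked_idx = rng.choice(n, size=n_tracked, replace=False)
        for i in sorted(tracked_idx):
            n_records = int(rng.integers(5, 16))
            seed = int(rng.integers(0, 2**31 - 1))
            try:
                users[i].history = generate_history(users[i], kg, n_records, seed)
            except GenerationError:
                users[i].history = []
    return users


def generate_history(
    user: UserProfile,
    kg: KnowledgeGraph,
    n_records: int,
    seed: int,
) -> list[tuple[int, tuple[str, ...]]]:
    """``n_records`` day-indexed selections of disease-safe combos.

    Stands in for a canteen tracking log: each record is a uniformly chosen
    template combo over the user's disease-safe dishes, on days ``-n..-1``
    (before the simulated intervention). Deterministic for a fixed seed.
    """
    if n_records == 0:
        return []
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]).generate_state(1))
    safe = sorted(filter_by_disease(user, kg))
    history: list[tuple[int, tuple[str, ...]]] = []
    for k in range(n_records):
        combo = sample_uniform_combo(safe, kg, rng)
        if combo is None:
            raise GenerationError(f"no feasible combo for user {user.id!r}")
        history.append((k - n_records, combo))
    return history


def sample_uniform_combo(
    safe: list[str],
    kg: KnowledgeGraph,
    rng: np.random.Generator,
    templates: tuple[ComboTemplate, ...] = DEFAULT_TEMPLATES,
) -> tuple[str, ...] | None:
    """Uniformly assemble one template combo from disease-safe dishes.

    The autonomous-choice model: a template is drawn uniformly among those
    that can be filled, then each slot is filled uniformly without
    replacement. No constraint check and no adequacy ranking. Returns None
    when no template can be filled.
    """
    index = kg_index(kg)
    by_cat: dict[str, list[str]] = {}
    for dish_id in safe:
        by_cat.setdefault(index.dish_category[index.dish_pos[dish_id]], []).append(dish_id)
    fillable = []
    for template in templates:
        need: dict[frozenset, int] = {}
        for slot in template.slots:
            need[slot] = need.get(slot, 0) + 1
        if all(
            len({d for c in slot for d in by_cat.get(c, [])}) >= count
            for slot, count in need.items()
        ):
            fillable.append(template)
    if not fillable:
        return None
    template = fillable[rng.integers(len(fillable))]
    chosen: list[str] = []
    for slot in template.slots:
        pool = sorted({d for c in slot for d in by_cat.get(c, [])} - set(chosen))
        if not pool:
            return None
        chosen.append(pool[rng.integers(len(pool))])
    return tuple(chosen)
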