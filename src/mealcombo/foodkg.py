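"""Food knowledge graph: entities, relations, and rule-based inference.

The graph holds five entity classes -- dishes, ingredients, ingredient
categories, nutrients, and diseases -- connected by six relation types:

* ``consist_of``  dish -> ingredient, carrying grams per standard portion
* ``contain``     ingredient -> nutrient (amount per 100 g) and, after
  inference, dish -> nutrient (amount per portion)
* ``belong_to``   ingredient -> ingredient category
* ``discourage``  disease -> ingredient | category | dish (hard exclusion)
* ``restrict``    disease -> nutrient | ingredient | category, carrying a
  quantitative per-day bound
* ``recommend``   disease -> ingredient | category | nutrient (soft boost)

Two first-order inference rules close the graph: nutrient containment is
propagated from ingredients to dishes through the composition, and
discouragement is propagated from ingredients (or their categories) to the
dishes that use them.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

RELATION_TYPES = frozenset(
    {"consist_of", "contain", "belong_to", "discourage", "restrict", "recommend"}
)

DISH_CATEGORIES = (
    "animal-derived",
    "vegan",
    "omnivorous",
    "staple",
    "soup",
    "complete",
)

#: Conversion factors from declared nutrient units to grams (for mass
#: fractions such as the sodium standard). Energy units are not mass-like
#: and deliberately absent.
_UNIT_TO_G = {"g": 1.0, "mg": 1e-3, "ug": 1e-6, "µg": 1e-6, "mcg": 1e-6}


class GraphError(ValueError):
    """Raised when graph construction or validation fails."""


class InferenceError(GraphError):
    """Raised when an inference rule cannot be applied."""


class StandardizationError(GraphError):
    """Raised when a dish cannot be brought into the sodium band."""


class AmbiguousStatementError(GraphError):
    """Raised when a rule statement matches patterns of two relation types."""


# ---------------------------------------------------------------------------
# entity types
# ---------------------------------------------------------------------------


@dataclass
class Ingredient:
    id: str
    name: str
    category_id: str
    nutrient_per_100g: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for nutrient_id, amount in self.nutrient_per_100g.items():
            if amount < 0:
                raise GraphError(
                    f"ingredient {self.id!r}: negative amount for {nutrient_id!r}"
                )


@dataclass
class IngredientCategory:
    id: str
    name: str
    dds_group: str = "none"
    is_seasoning: bool = False


@dataclass
class Nutrient:
    id: str
    name: str
    unit: str
    guideline_low: float | None = None
    guideline_high: float | None = None

    def validate(self) -> None:
        if (
            self.guideline_low is not None
            and self.guideline_high is not None
            and self.guideline_low > self.guideline_high
        ):
            raise GraphError(f"nutrient {self.id!r}: guideline_low > guideline_high")


@dataclass
class Dish:
    id: str
    name: str
    dish_category: str
    flavor: str = ""
    cooking_method: str = ""
    price_level: int = 1
    composition: dict[str, float] = field(default_factory=dict)

    @property
    def portion_mass_g(self) -> float:
        return float(sum(self.composition.values()))

    def validate(self) -> None:
        if self.dish_category not in DISH_CATEGORIES:
            raise GraphError(
                f"dish {self.id!r}: unknown category {self.dish_category!r}"
            )
        if not self.composition:
            raise GraphError(f"dish {self.id!r}: empty composition")
        for ingredient_id, grams in self.composition.items():
            if grams < 0:
                raise GraphError(
                    f"dish {self.id!r}: negative grams for {ingredient_id!r}"
                )


@dataclass(frozen=True)
class RestrictBound:
    """A quantitative per-day bound a disease places on a target.

    ``amount`` is per day in the target's native unit (the nutrient's declared
    unit, or grams for ingredient/category targets).
    """

    target_id: str
    target_type: str  # "ingredient" | "category" | "nutrient"
    bound_type: str  # "max" | "min" | "range"
    amount: float
    unit: str
    amount_high: float | None = None  # only for bound_type == "range"


@dataclass
class DiseaseRule:
    id: str
    name: str
    discourage: set[str] = field(default_factory=set)
    restrict: list[RestrictBound] = field(default_factory=list)
    recommend: set[str] = field(default_factory=set)

    def validate(self) -> None:
        restricted = {b.target_id for b in self.restrict}
        for a, b, what in (
            (self.discourage, restricted, "discourage/restrict"),
            (self.discourage, self.recommend, "discourage/recommend"),
            (restricted, self.recommend, "restrict/recommend"),
        ):
            overlap = a & b
            if overlap:
                raise GraphError(
                    f"disease {self.id!r}: {what} overlap on {sorted(overlap)}"
                )


@dataclass(frozen=True)
class Edge:
    head: str
    relation: str
    tail: str
    amount: float | None = None
    bound_type: str | None = None
    unit: str | None = None


# ---------------------------------------------------------------------------
# the graph
# ---------------------------------------------------------------------------


@dataclass
class KnowledgeGraph:
    ingredients: dict[str, Ingredient] = field(default_factory=dict)
    categories: dict[str, IngredientCategory] = field(default_factory=dict)
    nutrients: dict[str, Nutrient] = field(default_factory=dict)
    dishes: dict[str, Dish] = field(default_factory=dict)
    diseases: dict[str, DiseaseRule] = field(default_factory=dict)
    edges: list[Edge] = field(default_factory=list)

    # caches filled by finalize(); not serialized
    _dish_nutrients: dict[str, dict[str, float]] = field(
        default_factory=dict, repr=False
    )
    _discouraged: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    # -- entity helpers ----------------------------------------------------

    def entity_type(self, entity_id: str) -> str | None:
        for type_name, table in (
            ("dish", self.dishes),
            ("ingredient", self.ingredients),
            ("category", self.categories),
            ("nutrient", self.nutrients),
            ("disease", self.diseases),
        ):
            if entity_id in table:
                return type_name
        return None

    def nutrient_ids(self) -> list[str]:
        return sorted(self.nutrients)

    def dish_ids(self) -> list[str]:
        return sorted(self.dishes)

    def dish_nutrients(self, dish_id: str) -> dict[str, float]:
        """Per-portion nutrient totals for a dish (cached after finalize)."""
        if dish_id not in self._dish_nutrients:
            self._dish_nutrients[dish_id] = infer_dish_nutrients(
                self.dishes[dish_id], self
            )
        return self._dish_nutrients[dish_id]

    def discouraged_dishes(self, disease_id: str) -> frozenset[str]:
        if disease_id not in self._discouraged:
            self._discouraged[disease_id] = frozenset(
                infer_disease_dish(self.diseases[disease_id], self, emit_edges=False)
            )
        return self._discouraged[disease_id]

    def dish_category_grams(self, dish_id: str) -> dict[str, float]:
        """Grams of each ingredient category in one portion of a dish."""
        out: dict[str, float] = {}
        for ingredient_id, grams in self.dishes[dish_id].composition.items():
            cat = self.ingredients[ingredient_id].category_id
            out[cat] = out.get(cat, 0.0) + grams
        return out

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        for ingredient in self.ingredients.values():
            ingredient.validate()
            if ingredient.category_id not in self.categories:
                raise GraphError(
                    f"ingredient {ingredient.id!r}: unresolved category "
                    f"{ingredient.category_id!r}"
                )
        for nutrient in self.nutrients.values():
            nutrient.validate()
        for dish in self.dishes.values():
            dish.validate()
            for ingredient_id in dish.composition:
                if ingredient_id not in self.ingredients:
                    raise GraphError(
                        f"dish {dish.id!r}: unresolved ingredient {ingredient_id!r}"
                    )
        for disease in self.diseases.values():
            disease.validate()
        for edge in self.edges:
            if edge.relation not in RELATION_TYPES:
                raise GraphError(f"unknown relation type {edge.relation!r}")
            if self.entity_type(edge.head) is None:
                raise GraphError(f"dangling edge head {edge.head!r}")
            if self.entity_type(edge.tail) is None:
                raise GraphError(f"dangling edge tail {edge.tail!r}")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "ingredients": [vars(i) for i in self.ingredients.values()],
            "categories": [vars(c) for c in self.categories.values()],
            "nutrients": [vars(n) for n in self.nutrients.values()],
            "dishes": [
                {
                    "id": d.id,
                    "name": d.name,
                    "dish_category": d.dish_category,
                    "flavor": d.flavor,
                    "cooking_method": d.cooking_method,
                    "price_level": d.price_level,
                    "composition": d.composition,
                }
                for d in self.dishes.values()
            ],
            "diseases": [
                {
                    "id": r.id,
                    "name": r.name,
                    "discourage": sorted(r.discourage),
                    "restrict": [vars(b) for b in r.restrict],
                    "recommend": sorted(r.recommend),
                }
                for r in self.diseases.values()
            ],
            "edges": [
                {k: v for k, v in vars(e).items() if v is not None}
                for e in self.edges
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, ensure_ascii=False, indent=1)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "KnowledgeGraph":
        kg = cls()
        for row in doc.get("ingredients", []):
            kg.ingredients[row["id"]] = Ingredient(**row)
        for row in doc.get("categories", []):
            kg.categories[row["id"]] = IngredientCategory(**row)
        for row in doc.get("nutrients", []):
            kg.nutrients[row["id"]] = Nutrient(**row)
        for row in doc.get("dishes", []):
            kg.dishes[row["id"]] = Dish(**row)
        for row in doc.get("diseases", []):
            kg.diseases[row["id"]] = DiseaseRule(
                id=row["id"],
                name=row["name"],
                discourage=set(row.get("discourage", [])),
                restrict=[RestrictBound(**b) for b in row.get("restrict", [])],
                recommend=set(row.get("recommend", [])),
            )
        for row in doc.get("edges", []):
            kg.edges.append(Edge(**row))
        kg.validate()
        return kg

    @classmethod
    def from_json(cls, path) -> "KnowledgeGraph":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for table, type_name in (
            (self.dishes, "dish"),
            (self.ingredients, "ingredient"),
            (self.categories, "category"),
            (self.nutrients, "nutrient"),
            (self.diseases, "disease"),
        ):
            for entity_id, entity in table.items():
                g.add_node(entity_id, entity_type=type_name, name=entity.name)
        for e in self.edges:
            g.add_edge(
                e.head,
                e.tail,
                relation=e.relation,
                amount=e.amount,
                bound_type=e.bound_type,
                unit=e.unit,
            )
        return g

    def nodes_frame(self) -> pd.DataFrame:
        rows = []
        for table, type_name in (
            (self.dishes, "dish"),
            (self.ingredients, "ingredient"),
            (self.categories, "category"),
            (self.nutrients, "nutrient"),
            (self.diseases, "disease"),
        ):
            for entity_id, entity in table.items():
                rows.append(
                    {"id": entity_id, "entity_type": type_name, "name": entity.name}
                )
        return pd.DataFrame(rows, columns=["id", "entity_type", "name"])

    def edges_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [vars(e) for e in self.edges],
            columns=["head", "relation", "tail", "amount", "bound_type", "unit"],
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _nutrient_mass_factor(unit: str) -> float | None:
    return _UNIT_TO_G.get(unit.strip().lower())


def jaccard(a: set, b: set) -> float:
    union = a | b
    if not union:
        raise ValueError("Jaccard similarity undefined for two empty sets")
    return len(a & b) / len(union)


def dedup_dishes(dishes: Sequence[Dish], threshold: float = 0.85) -> list[Dish]:
    """Collapse duplicate dishes by name equality or ingredient-set similarity.

    Two dishes are duplicates when their case-folded names are equal or the
    Jaccard similarity of their ingredient-id sets is >= ``threshold``
    (inclusive). Within a duplicate cluster the variant whose exact
    composition occurs most frequently in the input is kept; frequency ties
    fall to the lexicographically smallest dish id.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    dishes = list(dishes)
    for dish in dishes:
        if not dish.composition:
            raise GraphError(f"dish {dish.id!r}: empty ingredient set")

    # union-find over duplicate pairs
    parent = list(range(len(dishes)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    sets = [frozenset(d.composition) for d in dishes]
    names = [d.name.casefold() for d in dishes]
    for i in range(len(dishes)):
        for j in range(i + 1, len(dishes)):
            if names[i] == names[j] or jaccard(set(sets[i]), set(sets[j])) >= threshold:
                union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(len(dishes)):
        clusters.setdefault(find(i), []).append(i)

    # frequency of exact ingredient combinations across the whole input
    combo_freq: dict[frozenset, int] = {}
    for s in sets:
        combo_freq[s] = combo_freq.get(s, 0) + 1

    kept: list[tuple[int, Dish]] = []
    for members in clusters.values():
        best = min(members, key=lambda i: (-combo_freq[sets[i]], dishes[i].id))
        kept.append((members[0], dishes[best]))
    kept.sort(key=lambda pair: pair[0])  # preserve input order of clusters
    return [dish for _, dish in kept]


def infer_dish_nutrients(dish: Dish, kg: KnowledgeGraph) -> dict[str, float]:
    """Propagate nutrient content from ingredients to a dish.

    For each nutrient the per-portion amount is ``sum_i M_i * P_i / 100``
    where ``M_i`` is the ingredient's amount per 100 g and ``P_i`` the grams
    of ingredient ``i`` in the dish's standard portion.
    """
    totals: dict[str, float] = {}
    for ingredient_id, grams in dish.composition.items():
        ingredient = kg.ingredients.get(ingredient_id)
        if ingredient is None:
            raise InferenceError(
                f"dish {dish.id!r}: ingredient {ingredient_id!r} missing from graph"
            )
        for nutrient_id, per_100g in ingredient.nutrient_per_100g.items():
            totals[nutrient_id] = totals.get(nutrient_id, 0.0) + per_100g * grams / 100.0
    return totals


def infer_disease_dish(
    disease: DiseaseRule, kg: KnowledgeGraph, emit_edges: bool = False
) -> set[str]:
    """Dishes a disease discourages, via discouraged ingredients or categories.

    A dish is discouraged when it contains a discouraged ingredient, or an
    ingredient whose category is discouraged (category discouragement is
    inherited by its members). Dish ids appearing directly in the discourage
    set are returned as-is.
    """
    discouraged_ingredients = {
        t for t in disease.discourage if t in kg.ingredients
    }
    discouraged_categories = {t for t in disease.discourage if t in kg.categories}
    direct_dishes = {t for t in disease.discourage if t in kg.dishes}

    result = set(direct_dishes)
    for dish_id, dish in kg.dishes.items():
        for ingredient_id in dish.composition:
            if ingredient_id in discouraged_ingredients:
                result.add(dish_id)
                break
            ingredient = kg.ingredients.get(ingredient_id)
            if ingredient is not None and ingredient.category_id in discouraged_categories:
                result.add(dish_id)
                break
    if emit_edges:
        existing = {
            (e.head, e.tail) for e in kg.edges if e.relation == "discourage"
        }
        for dish_id in sorted(result):
            if (disease.id, dish_id) not in existing:
                kg.edges.append(Edge(disease.id, "discourage", dish_id))
    return result


def standardize_sodium(
    dish: Dish,
    kg: KnowledgeGraph,
    low: float = 0.008,
    high: float = 0.010,
    sodium_id: str = "sodium",
) -> Dish:
    """Bring a dish's sodium mass fraction into ``[low, high]``.

    Sodium outside the band is attributed to seasoning and the grams of the
    dish's seasoning ingredients (category flagged ``is_seasoning``) are
    rescaled so the sodium fraction lands exactly on the nearest bound; all
    other composition entries are untouched. If the dish has no seasoning
    ingredient carrying sodium, the single largest sodium contributor is
    rescaled instead.
    """
    if not 0 <= low <= high:
        raise ValueError("require 0 <= low <= high")
    if dish.portion_mass_g <= 0:
        raise StandardizationError(f"dish {dish.id!r}: zero portion mass")
    nutrient = kg.nutrients.get(sodium_id)
    if nutrient is None:
        raise StandardizationError(f"nutrient {sodium_id!r} not in graph")
    factor = _nutrient_mass_factor(nutrient.unit)
    if factor is None:
        raise StandardizationError(
            f"nutrient {sodium_id!r}: unit {nutrient.unit!r} is not a mass unit"
        )

    def sodium_frac(ingredient_id: str) -> float:
        ing = kg.ingredients.get(ingredient_id)
        if ing is None:
            raise InferenceError(
                f"dish {dish.id!r}: ingredient {ingredient_id!r} missing from graph"
            )
        return ing.nutrient_per_100g.get(sodium_id, 0.0) * factor / 100.0

    contributions = {
        ing_id: grams * sodium_frac(ing_id)
        for ing_id, grams in dish.composition.items()
    }
    total_na = sum(contributions.values())
    total_mass = dish.portion_mass_g
    fraction = total_na / total_mass
    if low <= fraction <= high:
        return dish

    target = high if fraction > high else low
    seasoning = {
        ing_id
        for ing_id in dish.composition
        if kg.categories[kg.ingredients[ing_id].category_id].is_seasoning
        and contributions[ing_id] > 0
    }
    if not seasoning:
        positive = [i for i, c in contributions.items() if c > 0]
        if not positive:
            raise StandardizationError(
                f"dish {dish.id!r}: no sodium to rescale (fraction {fraction:.4f})"
            )
        seasoning = {max(positive, key=lambda i: contributions[i])}

    na_seas = sum(contributions[i] for i in seasoning)
    mass_seas = sum(dish.composition[i] for i in seasoning)
    na_fixed = total_na - na_seas
    mass_fixed = total_mass - mass_seas
    # solve (na_fixed + k*na_seas) / (mass_fixed + k*mass_seas) = target
    denom = na_seas - target * mass_seas
    if denom <= 0:
        raise StandardizationError(
            f"dish {dish.id!r}: seasoning sodium density too low to standardize"
        )
    k = (target * mass_fixed - na_fixed) / denom
    if k < 0:
        raise StandardizationError(
            f"dish {dish.id!r}: non-seasoning sodium alone exceeds the band"
        )
    composition = dict(dish.composition)
    for ing_id in seasoning:
        composition[ing_id] = dish.composition[ing_id] * k
    return replace(dish, composition=composition)


# ---------------------------------------------------------------------------
# rule extraction from guideline statements
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LexiconPattern:
    """One surface pattern mapping statement text to a typed relation.

    The regex must expose a named group ``target``; restrict patterns may
    also expose ``amount`` and ``unit``.
    """

    relation: str  # discourage | restrict | recommend
    pattern: str
    bound_type: str = "max"

    def compiled(self) -> re.Pattern:
        return re.compile(self.pattern, re.IGNORECASE)


DEFAULT_LEXICON: tuple[LexiconPattern, ...] = (
    LexiconPattern("discourage", r"\b(?:should\s+)?avoid\s+(?P<target>[\w \-]+)"),
    LexiconPattern("discourage", r"\bmust\s+not\s+(?:eat|consume)\s+(?P<target>[\w \-]+)"),
    LexiconPattern(
        "restrict",
        r"\b(?:limit|restrict)\s+(?P<target>[\w \-]+?)\s+to\s+(?:less\s+than\s+)?"
        r"(?P<amount>[\d.]+)\s*(?P<unit>[\w/]+?)\s*(?:/|\s+per\s+)day",
    ),
    LexiconPattern(
        "restrict",
        r"(?P<target>[\w \-]+?)\s*<\s*(?P<amount>[\d.]+)\s*(?P<unit>\w+)\s*(?:/|\s+per\s+)day",
    ),
    LexiconPattern(
        "recommend", r"\b(?:recommend(?:ed)?|increase\s+intake\s+of)\s+(?P<target>[\w \-]+)"
    ),
)


@dataclass
class ParsedRules:
    rules: list[DiseaseRule]
    unmatched: list[tuple[str, str]]  # (disease_id, statement)


def parse_disease_rules(
    statements: pd.DataFrame,
    lexicon: Sequence[LexiconPattern] = DEFAULT_LEXICON,
    resolver: Mapping[str, tuple[str, str]] | None = None,
) -> ParsedRules:
    """Extract typed disease rules from guideline-style statements.

    ``statements`` needs columns ``disease_id`` and ``text`` (optionally
    ``disease_name``). ``resolver`` maps a case-folded surface name of a
    target to ``(target_type, target_id)``; without a resolver the captured
    surface form becomes the target id with type ``unresolved``. Statements
    matching no pattern are reported in ``unmatched`` rather than dropped;
    a statement matching patterns of two different relation types raises
    :class:`AmbiguousStatementError`.
    """
    compiled = [(p, p.compiled()) for p in lexicon]
    rules: dict[str, DiseaseRule] = {}
    unmatched: list[tuple[str, str]] = []
    for row in statements.itertuples(index=False):
        disease_id = str(row.disease_id)
        text = str(row.text)
        name = str(getattr(row, "disease_name", disease_id))
        matches: list[tuple[LexiconPattern, re.Match]] = []
        for pattern, regex in compiled:
            m = regex.search(text)
            if m:
                matches.append((pattern, m))
        relations = {p.relation for p, _ in matches}
        if len(relations) > 1:
            raise AmbiguousStatementError(
                f"statement {text!r} matches multiple relation types: "
                + ", ".join(sorted(f"{p.relation}:{p.pattern}" for p, _ in matches))
            )
        if not matches:
            unmatched.append((disease_id, text))
            continue
        pattern, m = matches[0]
        surface = m.group("target").strip().casefold()
        if resolver is not None and surface in resolver:
            _, target_id = resolver[surface]
            target_type = resolver[surface][0]
        else:
            target_id, target_type = surface, "unresolved"
        rule = rules.setdefault(disease_id, DiseaseRule(id=disease_id, name=name))
        if pattern.relation == "discourage":
            rule.discourage.add(target_id)
        elif pattern.relation == "recommend":
            rule.recommend.add(target_id)
        else:
            rule.restrict.append(
                RestrictBound(
                    target_id=target_id,
                    target_type=target_type,
                    bound_type=pattern.bound_type,
                    amount=float(m.group("amount")),
                    unit=m.group("unit"),
                )
            )
    return ParsedRules(rules=list(rules.values()), unmatched=unmatched)


# ---------------------------------------------------------------------------
# graph construction from tables
# ---------------------------------------------------------------------------


def _require_columns(table: pd.DataFrame, columns: Iterable[str], name: str) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise GraphError(f"{name}: missing columns {missing}")


def build_graph(
    recipes: pd.DataFrame,
    composition: pd.DataFrame,
    disease_rules: pd.DataFrame,
    guidelines: pd.DataFrame,
    categories: pd.DataFrame | None = None,
    *,
    dedup_threshold: float = 0.85,
    sodium_low: float = 0.008,
    sodium_high: float = 0.010,
    sodium_id: str = "sodium",
    standardize: bool = True,
    dedup: bool = True,
) -> KnowledgeGraph:
    """Assemble and close the knowledge graph from the four input tables.

    ``recipes`` is long format (one row per dish-ingredient pair):
    dish_id, name, category, flavor, cooking_method, price_level,
    ingredient_id, grams. ``composition`` is one row per
    ingredient-nutrient pair: ingredient_id, name, category_id, nutrient_id,
    amount_per_100g, unit. ``disease_rules`` is one row per typed relation:
    disease_id, disease_name, relation, target_type, target_id, bound_type,
    amount, unit. ``guidelines`` has nutrient_id, name, unit, low, high.
    ``categories`` (optional) has category_id, name, dds_group, is_seasoning;
    absent categories are created with dds_group "none".

    After entity loading the pipeline dedups dishes, standardizes the sodium
    band, materializes consist_of/belong_to/contain edges, and applies the
    two inference rules so dish-level contain and disease-level discourage
    edges exist.
    """
    _require_columns(
        recipes,
        ["dish_id", "name", "category", "flavor", "cooking_method", "price_level",
         "ingredient_id", "grams"],
        "recipes",
    )
    _require_columns(
        composition,
        ["ingredient_id", "name", "category_id", "nutrient_id", "amount_per_100g", "unit"],
        "composition",
    )
    _require_columns(guidelines, ["nutrient_id", "unit", "low", "high"], "guidelines")
    if len(disease_rules):
        _require_columns(
            disease_rules,
            ["disease_id", "relation", "target_type", "target_id"],
            "disease_rules",
        )

    kg = KnowledgeGraph()

    # nutrients from guidelines (canonical census) plus any extras in composition
    for row in guidelines.itertuples(index=False):
        low = None if pd.isna(row.low) else float(row.low)
        high = None if pd.isna(row.high) else float(row.high)
        kg.nutrients[str(row.nutrient_id)] = Nutrient(
            id=str(row.nutrient_id),
            name=str(getattr(row, "name", row.nutrient_id)),
            unit=str(row.unit),
            guideline_low=low,
            guideline_high=high,
        )

    # categories
    if categories is not None:
        _require_columns(categories, ["category_id", "name"], "categories")
        for row in categories.itertuples(index=False):
            kg.categories[str(row.category_id)] = IngredientCategory(
                id=str(row.category_id),
                name=str(row.name),
                dds_group=str(getattr(row, "dds_group", "none")),
                is_seasoning=bool(getattr(row, "is_seasoning", False)),
            )

    # ingredients from the composition table
    for (ingredient_id,), group in composition.groupby(["ingredient_id"], sort=True):
        ingredient_id = str(ingredient_id)
        first = group.iloc[0]
        category_id = str(first["category_id"])
        if category_id not in kg.categories:
            kg.categories[category_id] = IngredientCategory(
                id=category_id, name=category_id
            )
        nutrient_map: dict[str, float] = {}
        for row in group.itertuples(index=False):
            nutrient_id = str(row.nutrient_id)
            amount = float(row.amount_per_100g)
            if amount < 0:
                raise GraphError(
                    f"composition: negative amount for ingredient {ingredient_id!r}, "
                    f"nutrient {nutrient_id!r}"
                )
            if nutrient_id not in kg.nutrients:
                kg.nutrients[nutrient_id] = Nutrient(
                    id=nutrient_id, name=nutrient_id, unit=str(row.unit)
                )
            nutrient_map[nutrient_id] = amount
        kg.ingredients[ingredient_id] = Ingredient(
            id=ingredient_id,
            name=str(first["name"]),
            category_id=category_id,
            nutrient_per_100g=nutrient_map,
        )

    # dishes from the long-format recipe table
    dishes: list[Dish] = []
    for (dish_id,), group in recipes.groupby(["dish_id"], sort=True):
        dish_id = str(dish_id)
        first = group.iloc[0]
        comp: dict[str, float] = {}
        for row in group.itertuples(index=False):
            ingredient_id = str(row.ingredient_id)
            if ingredient_id not in kg.ingredients:
                raise GraphError(
                    f"recipes: dish {dish_id!r} references unknown ingredient "
                    f"{ingredient_id!r}"
                )
            grams = float(row.grams)
            if grams < 0:
                raise GraphError(
                    f"recipes: dish {dish_id!r} has negative grams for "
                    f"{ingredient_id!r}"
                )
            comp[ingredient_id] = comp.get(ingredient_id, 0.0) + grams
        dishes.append(
            Dish(
                id=dish_id,
                name=str(first["name"]),
                dish_category=str(first["category"]),
                flavor=str(first["flavor"]),
                cooking_method=str(first["cooking_method"]),
                price_level=int(first["price_level"]),
                composition=comp,
            )
        )
    if dedup:
        dishes = dedup_dishes(dishes, threshold=dedup_threshold)
    if standardize and sodium_id in kg.nutrients:
        dishes = [
            standardize_sodium(d, kg, low=sodium_low, high=sodium_high, sodium_id=sodium_id)
            for d in dishes
        ]
    for dish in dishes:
        kg.dishes[dish.id] = dish

    # disease rules
    for row in disease_rules.itertuples(index=False):
        disease_id = str(row.disease_id)
        rule = kg.diseases.setdefault(
            disease_id,
            DiseaseRule(
                id=disease_id, name=str(getattr(row, "disease_name", disease_id))
            ),
        )
        relation = str(row.relation)
        target_id = str(row.target_id)
        if relation == "discourage":
            rule.discourage.add(target_id)
        elif relation == "recommend":
            rule.recommend.add(target_id)
        elif relation == "restrict":
            rule.restrict.append(
                RestrictBound(
                    target_id=target_id,
                    target_type=str(row.target_type),
                    bound_type=str(getattr(row, "bound_type", "max")),
                    amount=float(row.amount),
                    unit=str(row.unit),
                )
            )
        else:
            raise GraphError(f"disease_rules: unknown relation {relation!r}")

    _materialize_edges(kg)
    kg.validate()
    return kg


def _materialize_edges(kg: KnowledgeGraph) -> None:
    edges = kg.edges
    for dish in kg.dishes.values():
        for ingredient_id, grams in dish.composition.items():
            edges.append(Edge(dish.id, "consist_of", ingredient_id, amount=grams))
    for ingredient in kg.ingredients.values():
        edges.append(Edge(ingredient.id, "belong_to", ingredient.category_id))
        for nutrient_id, amount in ingredient.nutrient_per_100g.items():
            unit = kg.nutrients[nutrient_id].unit if nutrient_id in kg.nutrients else None
            edges.append(
                Edge(ingredient.id, "contain", nutrient_id, amount=amount, unit=unit)
            )
    # inferred dish -> nutrient containment
    for dish_id in sorted(kg.dishes):
        totals = infer_dish_nutrients(kg.dishes[dish_id], kg)
        kg._dish_nutrients[dish_id] = totals
        for nutrient_id in sorted(totals):
            edges.append(
                Edge(dish_id, "contain", nutrient_id, amount=totals[nutrient_id])
            )
    # explicit disease relations
    for disease in kg.diseases.values():
        for target in sorted(disease.discourage):
            edges.append(Edge(disease.id, "discourage", target))
        for bound in disease.restrict:
            edges.append(
                Edge(
                    disease.id,
                    "restrict",
                    bound.target_id,
                    amount=bound.amount,
                    bound_type=bound.bound_type,
                    unit=bound.unit,
                )
            )
        for target in sorted(disease.recommend):
            edges.append(Edge(disease.id, "recommend", target))
    # inferred disease -> dish discouragement
    for disease_id in sorted(kg.diseases):
        dishes = infer_disease_dish(kg.diseases[disease_id], kg, emit_edges=False)
        kg._discouraged[disease_id] = frozenset(dishes)
        for dish_id in sorted(dishes):
            edges.append(Edge(disease_id, "discourage", dish_id))
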