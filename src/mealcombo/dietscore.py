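"""Dietary outcome indices: diversity score (DDS) and a guideline quality index.

The dietary diversity score counts how many of nine food groups --
cereals/tubers, vegetables, fruits, livestock/poultry meat, fish/seafood,
eggs, dairy, legumes/nuts, and oils/fats -- are represented by at least one
ingredient across a day's combos, so it ranges over the integers 0..9.

The diet-quality index follows the form of guideline-adherence indices used
in Chinese older-adult diet surveys: a sum of per-component piecewise-linear
scores on a 0-110 scale. Each component scores a food-group amount or a
nutrient amount: full marks inside an optimal band, falling linearly to zero
at zero intake and (symmetrically for over-consumption) at twice the band's
upper edge. The component table is data, not code -- the default shipped
spec can be replaced by a YAML file when a different component table is
preferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .foodkg import KnowledgeGraph
from .recommender import KGIndex, MealCombo, kg_index

DDS_GROUPS = (
    "cereals_tubers",
    "vegetables",
    "fruits",
    "meat",
    "fish_seafood",
    "eggs",
    "dairy",
    "legumes_nuts",
    "oils_fats",
)


class ScoringError(ValueError):
    """Raised for unmapped categories (strict mode) or malformed specs."""


@dataclass
class DiversityGroups:
    """Total mapping from ingredient-category ids to the nine DDS groups.

    Categories that should not count toward diversity (seasonings, water,
    beverages) map to ``"none"``.
    """

    mapping: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        bad = {g for g in self.mapping.values() if g not in DDS_GROUPS and g != "none"}
        if bad:
            raise ScoringError(f"unknown diversity groups: {sorted(bad)}")

    def group_of(self, category_id: str, strict: bool = False) -> str:
        group = self.mapping.get(category_id)
        if group is None:
            if strict:
                raise ScoringError(f"category {category_id!r} has no diversity group")
            return "none"
        return group

    @classmethod
    def from_yaml(cls, path) -> "DiversityGroups":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        groups = cls(mapping=dict(doc))
        groups.validate()
        return groups

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.mapping, fh, allow_unicode=True, sort_keys=True)


def groups_from_kg(kg: KnowledgeGraph) -> DiversityGroups:
    """Read the diversity mapping off category ``dds_group`` attributes."""
    groups = DiversityGroups(
        mapping={c.id: c.dds_group for c in kg.categories.values()}
    )
    groups.validate()
    return groups


def dds(
    combos: Sequence[MealCombo] | Sequence[Sequence[str]],
    groups: DiversityGroups,
    kg: KnowledgeGraph,
    strict: bool = False,
) -> int:
    """Distinct diversity groups represented across one day's combos.

    ``combos`` may be :class:`MealCombo` objects or bare dish-id sequences.
    Monotone under adding dishes; always an integer in [0, 9].
    """
    seen: set[str] = set()
    for combo in combos:
        dish_ids = combo.dish_ids if isinstance(combo, MealCombo) else combo
        for dish_id in dish_ids:
            for ingredient_id in kg.dishes[dish_id].composition:
                category_id = kg.ingredients[ingredient_id].category_id
                group = groups.group_of(category_id, strict=strict)
                if group != "none":
                    seen.add(group)
    return len(seen)


# ---------------------------------------------------------------------------
# quality index
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QualityComponent:
    """One scored component of the quality index.

    ``basis`` names the intake quantity: ``group:<dds-group>`` for food-group
    grams or ``nutrient:<nutrient-id>`` for a nutrient amount (per lunch, in
    the nutrient's native unit). Full ``max_points`` inside ``[low, high]``;
    linear decay to 0 at zero intake and at ``2 * high``.
    """

    name: str
    basis: str
    low: float
    high: float
    max_points: float


@dataclass
class QualityIndexSpec:
    components: list[QualityComponent]
    total_points: float = 110.0

    def validate(self) -> None:
        total = sum(c.max_points for c in self.components)
        if abs(total - self.total_points) > 1e-9:
            raise ScoringError(
                f"component points sum to {total}, spec declares {self.total_points}"
            )
        for c in self.components:
            if not (0 <= c.low <= c.high) or c.high <= 0:
                raise ScoringError(f"component {c.name!r}: invalid band [{c.low}, {c.high}]")

    @classmethod
    def from_yaml(cls, path) -> "QualityIndexSpec":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        spec = cls(
            components=[QualityComponent(**row) for row in doc["components"]],
            total_points=float(doc.get("total_points", 110.0)),
        )
        spec.validate()
        return spec

    def to_yaml(self, path) -> None:
        doc = {
            "total_points": self.total_points,
            "components": [vars(c) for c in self.components],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, allow_unicode=True, sort_keys=False)


def component_score(component: QualityComponent, amount: float) -> float:
    """Piecewise-linear score of one component, clamped to [0, max_points]."""
    if amount < 0:
        raise ScoringError(f"component {component.name!r}: negative intake {amount}")
    if component.low <= amount <= component.high:
        return component.max_points
    if amount < component.low:
        return component.max_points * amount / component.low if component.low > 0 else component.max_points
    # over-consumption: decay to 0 at 2 * high
    score = component.max_points * (2 * component.high - amount) / component.high
    return float(min(max(score, 0.0), component.max_points))


def quality_index(day_intake: Mapping[str, float], spec: QualityIndexSpec) -> float:
    """Sum of component scores for one day's intake; in [0, total_points].

    Bases absent from ``day_intake`` count as zero intake.
    """
    spec.validate()
    return float(
        sum(component_score(c, float(day_intake.get(c.basis, 0.0))) for c in spec.components)
    )


def day_intake_from_combos(
    combos: Sequence[MealCombo] | Sequence[Sequence[str]],
    kg: KnowledgeGraph,
    groups: DiversityGroups,
) -> dict[str, float]:
    """Aggregate one day's combos to the basis quantities the index scores.

    Food-group bases accumulate ingredient grams mapped through categories;
    nutrient bases accumulate per-portion dish nutrient totals.
    """
    intake: dict[str, float] = {}
    for combo in combos:
        dish_ids = combo.dish_ids if isinstance(combo, MealCombo) else combo
        for dish_id in dish_ids:
            dish = kg.dishes[dish_id]
            for ingredient_id, grams in dish.composition.items():
                group = groups.group_of(kg.ingredients[ingredient_id].category_id)
                if group != "none":
                    key = f"group:{group}"
                    intake[key] = intake.get(key, 0.0) + grams
            for nutrient_id, amount in kg.dish_nutrients(dish_id).items():
                key = f"nutrient:{nutrient_id}"
                intake[key] = intake.get(key, 0.0) + amount
    return intake


def default_quality_spec() -> QualityIndexSpec:
    """Default 11-component table (6 food groups + 5 nutrients), 110 points.

    Bands are per-lunch amounts for a typical older adult, derived from
    per-day guideline magnitudes at a 40% lunch share of a 3:4:3 daily
    split. Replace via YAML for a different component table.
    """
    c = QualityComponent
    spec = QualityIndexSpec(
        components=[
            c("cereals & tubers", "group:cereals_tubers", 50.0, 125.0, 10.0),
            c("vegetables", "group:vegetables", 120.0, 250.0, 10.0),
            c("animal foods (meat)", "group:meat", 30.0, 90.0, 10.0),
            c("fish & seafood", "group:fish_seafood", 20.0, 80.0, 10.0),
            c("eggs", "group:eggs", 15.0, 60.0, 10.0),
            c("legumes & nuts", "group:legumes_nuts", 15.0, 60.0, 10.0),
            c("energy", "nutrient:energy", 450.0, 650.0, 10.0),
            c("protein", "nutrient:protein", 20.0, 40.0, 10.0),
            c("fat", "nutrient:fat", 10.0, 25.0, 10.0),
            c("fiber", "nutrient:fiber", 4.0, 15.0, 10.0),
            c("carbohydrate", "nutrient:carbohydrate", 50.0, 110.0, 10.0),
        ],
        total_points=110.0,
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# fast batched scoring (used by the simulation harness)
# ---------------------------------------------------------------------------


class ComboScorer:
    """Precomputed per-dish group bitmasks and basis vectors for fast scoring."""

    def __init__(
        self,
        kg: KnowledgeGraph,
        groups: DiversityGroups | None = None,
        spec: QualityIndexSpec | None = None,
    ):
        self.kg = kg
        self.groups = groups or groups_from_kg(kg)
        self.spec = spec or default_quality_spec()
        self.spec.validate()
        index: KGIndex = kg_index(kg)
        self.index = index
        group_pos = {g: i for i, g in enumerate(DDS_GROUPS)}
        n_d = len(index.dish_ids)
        self.dish_mask = np.zeros(n_d, dtype=np.int64)
        n_comp = len(self.spec.components)
        self.dish_basis = np.zeros((n_d, n_comp))
        self.low = np.array([c.low for c in self.spec.components])
        self.high = np.array([c.high for c in self.spec.components])
        self.points = np.array([c.max_points for c in self.spec.components])
        for di, dish_id in enumerate(index.dish_ids):
            dish = kg.dishes[dish_id]
            group_grams: dict[str, float] = {}
            for ingredient_id, grams in dish.composition.items():
                group = self.groups.group_of(kg.ingredients[ingredient_id].category_id)
                if group != "none":
                    self.dish_mask[di] |= 1 << group_pos[group]
                    group_grams[group] = group_grams.get(group, 0.0) + grams
            nutrients = kg.dish_nutrients(dish_id)
            for ci, comp in enumerate(self.spec.components):
                kind, _, key = comp.basis.partition(":")
                if kind == "group":
                    self.dish_basis[di, ci] = group_grams.get(key, 0.0)
                elif kind == "nutrient":
                    self.dish_basis[di, ci] = nutrients.get(key, 0.0)

    def _rows(self, dish_ids: Iterable[str]) -> list[int]:
        return [self.index.dish_pos[d] for d in dish_ids]

    def dds(self, dish_ids: Iterable[str]) -> int:
        mask = 0
        for row in self._rows(dish_ids):
            mask |= int(self.dish_mask[row])
        return bin(mask).count("1")

    def quality(self, dish_ids: Iterable[str]) -> float:
        amounts = self.dish_basis[self._rows(dish_ids)].sum(axis=0)
        in_band = (amounts >= self.low) & (amounts <= self.high)
        below = amounts < self.low
        with np.errstate(divide="ignore", invalid="ignore"):
            below_score = np.where(self.low > 0, amounts / self.low, 1.0)
        above_score = (2 * self.high - amounts) / self.high
        frac = np.where(in_band, 1.0, np.where(below, below_score, above_score))
        return float((self.points * np.clip(frac, 0.0, 1.0)).sum())
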