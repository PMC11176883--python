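"""Two-stage combo-meal recommendation.

Stage 1 -- candidate dish generation: dishes discouraged by any of the
user's diseases are removed, then the survivors are reranked by preference.
Users with sufficient tracked eating history are ranked directly against the
gram-weighted centroid of their frequently chosen dishes (cosine similarity
over ingredient-gram vectors, "hot boot"); users without history inherit the
ranking of the most Jaccard-similar tracked user ("cold boot").

Stage 2 -- combo assembly and assessment: ranked dishes are combined into
price-tiered templates (four-dish high tier down to two-dish low tier), each
combo is checked against disease restriction bounds and the user's energy
budget, and the survivors are ordered by nutrient adequacy -- the number of
nutrients whose lunch-scaled totals fall inside guideline ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .foodkg import KnowledgeGraph
from .profiles import UserProfile, find_reference_user, selection_counts


class ConfigurationError(ValueError):
    """Raised when a constraint needs a profile field that is absent."""


# ---------------------------------------------------------------------------
# templates and combos
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComboTemplate:
    """One price-tiered combo pattern: an ordered multiset of category slots.

    Each slot is the set of dish categories allowed to fill it; slots with
    identical requirement sets are interchangeable and are filled without
    permutation duplicates.
    """

    name: str
    price_tier: str  # high | intermediate-high | intermediate | low
    slots: tuple[frozenset[str], ...]

    @property
    def dish_count(self) -> int:
        return len(self.slots)


def _slot(*categories: str) -> frozenset[str]:
    return frozenset(categories)


DEFAULT_TEMPLATES: tuple[ComboTemplate, ...] = (
    ComboTemplate("high-4a", "high",
                  (_slot("animal-derived"), _slot("vegan"), _slot("staple"), _slot("soup"))),
    ComboTemplate("high-4b", "high",
                  (_slot("omnivorous"), _slot("omnivorous"), _slot("staple"), _slot("soup"))),
    ComboTemplate("intermediate-high-3a", "intermediate-high",
                  (_slot("animal-derived"), _slot("vegan"), _slot("staple"))),
    ComboTemplate("intermediate-high-3b", "intermediate-high",
                  (_slot("omnivorous"), _slot("omnivorous"), _slot("staple"))),
    ComboTemplate("intermediate-2", "intermediate",
                  (_slot("animal-derived", "omnivorous"), _slot("complete"))),
    ComboTemplate("low-2", "low",
                  (_slot("vegan"), _slot("complete"))),
)


@dataclass
class MealCombo:
    dish_ids: tuple[str, ...]
    template: ComboTemplate
    preference_score: float = 0.0
    adequacy_count: int = 0
    _totals: np.ndarray | None = field(default=None, repr=False)
    _nutrient_order: tuple[str, ...] = field(default=(), repr=False)

    @property
    def nutrient_totals(self) -> dict[str, float]:
        if self._totals is None:
            return {}
        return {n: float(v) for n, v in zip(self._nutrient_order, self._totals)}


@dataclass
class EnergyBudget:
    """Per-user energy and macronutrient envelope for one lunch.

    Daily energy is ``kcal_per_kg * weight``; the lunch window takes the
    slice ``[daily_low * lunch_fraction_low, daily_high * lunch_fraction_high]``.
    ``lunch_fraction`` (the 0.40 middle share of a 3:4:3 daily split) scales
    per-day restriction bounds and guideline ranges down to one lunch.
    Disease-specific overrides (keyed by disease id or name, case-folded)
    narrow the window; by default diabetes tightens the lunch share to
    30%-35% and caps energy from fat at 25%.
    """

    kcal_per_kg_low: float = 20.0
    kcal_per_kg_high: float = 25.0
    lunch_fraction: float = 0.40
    lunch_fraction_low: float = 0.40
    lunch_fraction_high: float = 0.40
    fat_fraction_max: float = 0.30
    energy_nutrient: str = "energy"
    fat_nutrient: str = "fat"
    kcal_per_g_fat: float = 9.0
    disease_overrides: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "diabetes": {
                "lunch_fraction_low": 0.30,
                "lunch_fraction_high": 0.35,
                "fat_fraction_max": 0.25,
            }
        }
    )

    def effective(self, user: UserProfile, kg: KnowledgeGraph) -> tuple[float, float, float]:
        """(lunch_fraction_low, lunch_fraction_high, fat_fraction_max) for a user."""
        lo, hi, fat = self.lunch_fraction_low, self.lunch_fraction_high, self.fat_fraction_max
        keys = {d.casefold() for d in user.diseases}
        for d in user.diseases:
            rule = kg.diseases.get(d)
            if rule is not None:
                keys.add(rule.name.casefold())
        for key, override in self.disease_overrides.items():
            if key.casefold() in keys:
                lo = override.get("lunch_fraction_low", lo)
                hi = override.get("lunch_fraction_high", hi)
                fat = override.get("fat_fraction_max", fat)
        return lo, hi, fat


@dataclass
class ConstraintReport:
    passed: bool
    violations: list[str]


@dataclass
class RecommendationResult:
    combos: list[MealCombo]
    mode: str  # "hot" | "cold"
    warnings: list[str] = field(default_factory=list)

    def __iter__(self) -> Iterator[MealCombo]:
        return iter(self.combos)

    def __len__(self) -> int:
        return len(self.combos)


# ---------------------------------------------------------------------------
# numeric index over the graph (cached per KnowledgeGraph instance)
# ---------------------------------------------------------------------------


class KGIndex:
    """Dense matrices over a finished graph for fast batched evaluation."""

    def __init__(self, kg: KnowledgeGraph):
        self.kg = kg
        self.dish_ids: list[str] = sorted(kg.dishes)
        self.dish_pos = {d: i for i, d in enumerate(self.dish_ids)}
        self.nutrient_ids: list[str] = sorted(kg.nutrients)
        self.nutrient_pos = {n: i for i, n in enumerate(self.nutrient_ids)}
        self.ingredient_ids: list[str] = sorted(kg.ingredients)
        self.ingredient_pos = {i: j for j, i in enumerate(self.ingredient_ids)}
        self.category_ids: list[str] = sorted(kg.categories)
        self.category_pos = {c: i for i, c in enumerate(self.category_ids)}

        n_d, n_n, n_i, n_c = (
            len(self.dish_ids),
            len(self.nutrient_ids),
            len(self.ingredient_ids),
            len(self.category_ids),
        )
        self.dish_nutrients = np.zeros((n_d, n_n))
        self.dish_grams = np.zeros((n_d, n_i))
        self.dish_category_grams = np.zeros((n_d, n_c))
        self.dish_category = np.empty(n_d, dtype=object)
        for di, dish_id in enumerate(self.dish_ids):
            dish = kg.dishes[dish_id]
            self.dish_category[di] = dish.dish_category
            for nutrient_id, amount in kg.dish_nutrients(dish_id).items():
                if nutrient_id in self.nutrient_pos:
                    self.dish_nutrients[di, self.nutrient_pos[nutrient_id]] = amount
            for ingredient_id, grams in dish.composition.items():
                self.dish_grams[di, self.ingredient_pos[ingredient_id]] = grams
                cat = kg.ingredients[ingredient_id].category_id
                self.dish_category_grams[di, self.category_pos[cat]] += grams
        self.dish_norms = np.linalg.norm(self.dish_grams, axis=1)

        self.guideline_low = np.full(n_n, np.nan)
        self.guideline_high = np.full(n_n, np.nan)
        for n_id, nutrient in kg.nutrients.items():
            ni = self.nutrient_pos[n_id]
            if nutrient.guideline_low is not None:
                self.guideline_low[ni] = nutrient.guideline_low
            if nutrient.guideline_high is not None:
                self.guideline_high[ni] = nutrient.guideline_high
        self.has_guideline = ~np.isnan(self.guideline_low) & ~np.isnan(self.guideline_high)


def kg_index(kg: KnowledgeGraph) -> KGIndex:
    index = kg.__dict__.get("_numeric_index")
    if index is None:
        index = KGIndex(kg)
        kg.__dict__["_numeric_index"] = index
    return index


# ---------------------------------------------------------------------------
# stage 1: candidate generation
# ---------------------------------------------------------------------------


def filter_by_disease(user: UserProfile, kg: KnowledgeGraph) -> set[str]:
    """All dishes not discouraged, directly or by inference, for the user."""
    banned: set[str] = set()
    for disease_id in user.diseases:
        if disease_id in kg.diseases:
            banned |= kg.discouraged_dishes(disease_id)
    return set(kg.dishes) - banned


def _centroid(counts: Mapping[str, int], index: KGIndex) -> np.ndarray:
    """Frequency-weighted centroid of dish ingredient-gram vectors."""
    total = 0
    centroid = np.zeros(len(index.ingredient_ids))
    for dish_id, count in counts.items():
        pos = index.dish_pos.get(dish_id)
        if pos is None:
            continue
        centroid += count * index.dish_grams[pos]
        total += count
    if total:
        centroid /= total
    return centroid


def _rank_against_centroid(
    candidates: Sequence[str], centroid: np.ndarray, index: KGIndex
) -> list[tuple[str, float]]:
    cnorm = np.linalg.norm(centroid)
    ordered = sorted(candidates)
    scores = []
    for dish_id in ordered:
        pos = index.dish_pos[dish_id]
        denom = index.dish_norms[pos] * cnorm
        score = float(index.dish_grams[pos] @ centroid / denom) if denom > 0 else 0.0
        scores.append((dish_id, score))
    scores.sort(key=lambda item: (-item[1], item[0]))
    return scores


def cosine_rank(
    user: UserProfile,
    candidates: set[str],
    kg: KnowledgeGraph,
    k_frequent: int = 10,
) -> list[tuple[str, float]]:
    """Hot-boot ranking: candidates by cosine similarity to the user's taste.

    The query vector is the selection-count-weighted centroid of the
    ingredient-gram vectors of the user's ``k_frequent`` most frequent
    dishes. Candidates with a zero ingredient vector score 0 by definition.
    Descending score; ties break to the smaller dish id.
    """
    index = kg_index(kg)
    counts = selection_counts(user)
    top = dict(
        sorted(counts.items(), key=lambda item: (-item[1], item[0]))[:k_frequent]
    )
    return _rank_against_centroid(sorted(candidates), _centroid(top, index), index)


def cold_boot_rank(
    user: UserProfile,
    pool: Sequence[UserProfile],
    candidates: set[str],
    kg: KnowledgeGraph,
    min_history: int = 5,
    k_frequent: int = 10,
) -> list[tuple[str, float]]:
    """Cold-boot ranking: borrow the most similar tracked user's taste."""
    reference = find_reference_user(user, pool, min_history=min_history)
    return cosine_rank(reference, candidates, kg, k_frequent=k_frequent)


# ---------------------------------------------------------------------------
# stage 2: combo assembly, constraints, adequacy
# ---------------------------------------------------------------------------


def enumerate_combos(
    candidates: Sequence[tuple[str, float]] | Sequence[str],
    templates: Sequence[ComboTemplate] = DEFAULT_TEMPLATES,
    per_template_cap: int | None = 50,
    kg: KnowledgeGraph | None = None,
) -> list[MealCombo]:
    """Instantiate templates with distinct ranked dishes.

    ``candidates`` is a ranked list of dish ids or (dish id, score) pairs.
    Enumeration follows candidate rank lexicographically slot by slot;
    identical slots are filled in strictly increasing rank order so no combo
    appears twice. At most ``per_template_cap`` combos per template.
    """
    if kg is None:
        raise ValueError("enumerate_combos requires the knowledge graph")
    index = kg_index(kg)
    ranked: list[tuple[str, float]] = [
        (c, 0.0) if isinstance(c, str) else (c[0], float(c[1])) for c in candidates
    ]
    combos: list[MealCombo] = []
    for template in templates:
        slot_candidates: list[list[int]] = []
        for slot in template.slots:
            slot_candidates.append(
                [
                    ci
                    for ci, (dish_id, _score) in enumerate(ranked)
                    if index.dish_category[index.dish_pos[dish_id]] in slot
                ]
            )
        produced = 0

        def fill(slot_i: int, chosen: list[int]) -> Iterator[tuple[int, ...]]:
            if slot_i == len(template.slots):
                yield tuple(chosen)
                return
            same_as_prev = (
                slot_i > 0 and template.slots[slot_i] == template.slots[slot_i - 1]
            )
            for ci in slot_candidates[slot_i]:
                if ci in chosen:
                    continue
                if same_as_prev and ci <= chosen[-1]:
                    continue
                chosen.append(ci)
                yield from fill(slot_i + 1, chosen)
                chosen.pop()

        nutrient_order = tuple(index.nutrient_ids)
        for pick in fill(0, []):
            dish_ids = tuple(ranked[ci][0] for ci in pick)
            score = sum(ranked[ci][1] for ci in pick) / len(pick)
            combos.append(
                MealCombo(
                    dish_ids=dish_ids,
                    template=template,
                    preference_score=score,
                    _nutrient_order=nutrient_order,
                )
            )
            produced += 1
            if per_template_cap is not None and produced >= per_template_cap:
                break
    _fill_totals(combos, index)
    return combos


def _fill_totals(combos: Sequence[MealCombo], index: KGIndex) -> None:
    """Vectorized per-combo nutrient totals, grouped by combo size."""
    by_size: dict[int, list[MealCombo]] = {}
    for combo in combos:
        if combo._totals is None:
            by_size.setdefault(len(combo.dish_ids), []).append(combo)
    for size, group in by_size.items():
        rows = np.array(
            [[index.dish_pos[d] for d in c.dish_ids] for c in group], dtype=np.intp
        )
        totals = index.dish_nutrients[rows].sum(axis=1)
        for combo, vector in zip(group, totals):
            combo._totals = vector


def _combo_totals(combo: MealCombo, index: KGIndex) -> np.ndarray:
    if combo._totals is not None and len(combo._totals) == len(index.nutrient_ids):
        return combo._totals
    rows = [index.dish_pos[d] for d in combo.dish_ids]
    return index.dish_nutrients[rows].sum(axis=0)


def check_constraints(
    combo: MealCombo,
    user: UserProfile,
    kg: KnowledgeGraph,
    budget: EnergyBudget | None = None,
) -> ConstraintReport:
    """Assess one combo against disease and energy constraints.

    Failures are itemized: (a) a dish discouraged for one of the user's
    diseases; (b) a per-day restriction bound, scaled to one lunch by the
    lunch fraction, violated; (c) combo energy outside the lunch window of
    the user's weight-derived daily budget; (d) energy share from fat above
    the cap.
    """
    budget = budget or EnergyBudget()
    index = kg_index(kg)
    violations: list[str] = []

    for disease_id in sorted(user.diseases):
        if disease_id not in kg.diseases:
            continue
        banned = kg.discouraged_dishes(disease_id) & set(combo.dish_ids)
        for dish_id in sorted(banned):
            violations.append(f"discouraged: dish {dish_id} for disease {disease_id}")

    totals = _combo_totals(combo, index)
    lf = budget.lunch_fraction
    for disease_id in sorted(user.diseases):
        rule = kg.diseases.get(disease_id)
        if rule is None:
            continue
        for bound in rule.restrict:
            if bound.target_type == "nutrient" and bound.target_id in index.nutrient_pos:
                value = float(totals[index.nutrient_pos[bound.target_id]])
            elif bound.target_type == "ingredient" and bound.target_id in index.ingredient_pos:
                rows = [index.dish_pos[d] for d in combo.dish_ids]
                value = float(
                    index.dish_grams[rows, index.ingredient_pos[bound.target_id]].sum()
                )
            elif bound.target_type == "category" and bound.target_id in index.category_pos:
                rows = [index.dish_pos[d] for d in combo.dish_ids]
                value = float(
                    index.dish_category_grams[rows, index.category_pos[bound.target_id]].sum()
                )
            else:
                continue
            low_ok = high_ok = True
            if bound.bound_type == "max":
                high_ok = value <= bound.amount * lf
            elif bound.bound_type == "min":
                low_ok = value >= bound.amount * lf
            elif bound.bound_type == "range":
                low_ok = value >= bound.amount * lf
                high = bound.amount_high if bound.amount_high is not None else bound.amount
                high_ok = value <= high * lf
            if not (low_ok and high_ok):
                violations.append(
                    f"restrict: {bound.target_id} {bound.bound_type} "
                    f"{bound.amount}{bound.unit}/day violated for disease {disease_id} "
                    f"(lunch value {value:.2f})"
                )

    lf_low, lf_high, fat_max = budget.effective(user, kg)
    energy_pos = index.nutrient_pos.get(budget.energy_nutrient)
    if energy_pos is not None:
        if user.weight_kg is None or user.weight_kg <= 0:
            raise ConfigurationError(
                f"profile {user.id!r}: weight required for the energy constraint"
            )
        energy = float(totals[energy_pos])
        window_low = budget.kcal_per_kg_low * user.weight_kg * lf_low
        window_high = budget.kcal_per_kg_high * user.weight_kg * lf_high
        if not window_low <= energy <= window_high:
            violations.append(
                f"energy: {energy:.0f} kcal outside lunch window "
                f"[{window_low:.0f}, {window_high:.0f}]"
            )
        fat_pos = index.nutrient_pos.get(budget.fat_nutrient)
        if fat_pos is not None and energy > 0:
            fat_share = float(totals[fat_pos]) * budget.kcal_per_g_fat / energy
            if fat_share > fat_max:
                violations.append(
                    f"fat: {fat_share:.0%} of energy exceeds cap {fat_max:.0%}"
                )
    return ConstraintReport(passed=not violations, violations=violations)


def _adequacy_counts(totals: np.ndarray, index: KGIndex, lf: float) -> np.ndarray:
    """Per-combo count of nutrients inside lunch-scaled guideline ranges."""
    mask = index.has_guideline
    low = index.guideline_low[mask] * lf
    high = index.guideline_high[mask] * lf
    values = totals[:, mask]
    return ((values >= low) & (values <= high)).sum(axis=1)


def adequacy_rank(
    combos: Sequence[MealCombo],
    kg: KnowledgeGraph,
    budget: EnergyBudget | None = None,
) -> list[MealCombo]:
    """Order combos by descending nutrient adequacy.

    Ties break by higher preference score, then by the smallest dish-id
    tuple, making the order total and deterministic.
    """
    budget = budget or EnergyBudget()
    index = kg_index(kg)
    if not combos:
        return []
    totals = np.vstack([_combo_totals(c, index) for c in combos])
    counts = _adequacy_counts(totals, index, budget.lunch_fraction)
    for combo, count in zip(combos, counts):
        combo.adequacy_count = int(count)
    return sorted(
        combos,
        key=lambda c: (-c.adequacy_count, -c.preference_score, c.dish_ids),
    )


def _batch_feasible(
    combos: list[MealCombo],
    user: UserProfile,
    kg: KnowledgeGraph,
    budget: EnergyBudget,
    index: KGIndex,
) -> list[MealCombo]:
    """Vectorized constraint pass over many combos (same semantics as
    :func:`check_constraints`, used on the hot path)."""
    if not combos:
        return []
    totals = np.vstack([_combo_totals(c, index) for c in combos])
    ok = np.ones(len(combos), dtype=bool)

    banned: set[str] = set()
    rules = []
    for disease_id in user.diseases:
        if disease_id in kg.diseases:
            banned |= kg.discouraged_dishes(disease_id)
            rules.extend(kg.diseases[disease_id].restrict)
    if banned:
        ok &= np.array([not (banned & set(c.dish_ids)) for c in combos])

    lf = budget.lunch_fraction
    rows_per_combo = None
    for bound in rules:
        if bound.target_type == "nutrient" and bound.target_id in index.nutrient_pos:
            values = totals[:, index.nutrient_pos[bound.target_id]]
        elif bound.target_type in ("ingredient", "category"):
            if rows_per_combo is None:
                rows_per_combo = [
                    [index.dish_pos[d] for d in c.dish_ids] for c in combos
                ]
            if bound.target_type == "ingredient" and bound.target_id in index.ingredient_pos:
                col = index.ingredient_pos[bound.target_id]
                values = np.array(
                    [index.dish_grams[rows, col].sum() for rows in rows_per_combo]
                )
            elif bound.target_type == "category" and bound.target_id in index.category_pos:
                col = index.category_pos[bound.target_id]
                values = np.array(
                    [index.dish_category_grams[rows, col].sum() for rows in rows_per_combo]
                )
            else:
                continue
        else:
            continue
        if bound.bound_type == "max":
            ok &= values <= bound.amount * lf
        elif bound.bound_type == "min":
            ok &= values >= bound.amount * lf
        elif bound.bound_type == "range":
            high = bound.amount_high if bound.amount_high is not None else bound.amount
            ok &= (values >= bound.amount * lf) & (values <= high * lf)

    lf_low, lf_high, fat_max = budget.effective(user, kg)
    energy_pos = index.nutrient_pos.get(budget.energy_nutrient)
    if energy_pos is not None:
        if user.weight_kg is None or user.weight_kg <= 0:
            raise ConfigurationError(
                f"profile {user.id!r}: weight required for the energy constraint"
            )
        energy = totals[:, energy_pos]
        ok &= (energy >= budget.kcal_per_kg_low * user.weight_kg * lf_low) & (
            energy <= budget.kcal_per_kg_high * user.weight_kg * lf_high
        )
        fat_pos = index.nutrient_pos.get(budget.fat_nutrient)
        if fat_pos is not None:
            with np.errstate(divide="ignore", invalid="ignore"):
                share = np.where(
                    energy > 0, totals[:, fat_pos] * budget.kcal_per_g_fat / energy, 0.0
                )
            ok &= share <= fat_max
    return [c for c, keep in zip(combos, ok) if keep]


def _enumerate_picks(
    ranked: Sequence[tuple[str, float]],
    template: ComboTemplate,
    per_template_cap: int | None,
    index: KGIndex,
) -> list[tuple[int, ...]]:
    """Candidate-index tuples instantiating one template, in rank order."""
    slot_candidates = []
    for slot in template.slots:
        slot_candidates.append(
            [
                ci
                for ci, (dish_id, _score) in enumerate(ranked)
                if index.dish_category[index.dish_pos[dish_id]] in slot
            ]
        )
    picks: list[tuple[int, ...]] = []

    def fill(slot_i: int, chosen: list[int]) -> bool:
        if slot_i == len(template.slots):
            picks.append(tuple(chosen))
            return per_template_cap is not None and len(picks) >= per_template_cap
        same_as_prev = slot_i > 0 and template.slots[slot_i] == template.slots[slot_i - 1]
        for ci in slot_candidates[slot_i]:
            if ci in chosen:
                continue
            if same_as_prev and ci <= chosen[-1]:
                continue
            chosen.append(ci)
            done = fill(slot_i + 1, chosen)
            chosen.pop()
            if done:
                return True
        return False

    fill(0, [])
    return picks


def _fast_pipeline(
    ranked: Sequence[tuple[str, float]],
    user: UserProfile,
    kg: KnowledgeGraph,
    budget: EnergyBudget,
    index: KGIndex,
    templates: Sequence[ComboTemplate],
    per_template_cap: int | None,
) -> list[MealCombo]:
    """Vectorized assemble -> constrain -> adequacy path used by recommend.

    Semantically identical to enumerate_combos + check_constraints +
    adequacy_rank, but builds combo objects only for feasible survivors.
    """
    cand_rows = np.array([index.dish_pos[d] for d, _ in ranked], dtype=np.intp)
    cand_scores = np.array([s for _, s in ranked])

    banned: set[str] = set()
    rules = []
    for disease_id in user.diseases:
        if disease_id in kg.diseases:
            banned |= kg.discouraged_dishes(disease_id)
            rules.extend(kg.diseases[disease_id].restrict)
    banned_rows = np.zeros(len(index.dish_ids), dtype=bool)
    for dish_id in banned:
        banned_rows[index.dish_pos[dish_id]] = True

    lf = budget.lunch_fraction
    lf_low, lf_high, fat_max = budget.effective(user, kg)
    energy_pos = index.nutrient_pos.get(budget.energy_nutrient)
    fat_pos = index.nutrient_pos.get(budget.fat_nutrient)
    if energy_pos is not None and (user.weight_kg is None or user.weight_kg <= 0):
        raise ConfigurationError(
            f"profile {user.id!r}: weight required for the energy constraint"
        )

    survivors: list[MealCombo] = []
    for template in templates:
        picks = _enumerate_picks(ranked, template, per_template_cap, index)
        if not picks:
            continue
        idx_mat = np.array(picks, dtype=np.intp)
        row_mat = cand_rows[idx_mat]
        totals = index.dish_nutrients[row_mat].sum(axis=1)
        ok = ~banned_rows[row_mat].any(axis=1)
        for bound in rules:
            if bound.target_type == "nutrient" and bound.target_id in index.nutrient_pos:
                values = totals[:, index.nutrient_pos[bound.target_id]]
            elif bound.target_type == "ingredient" and bound.target_id in index.ingredient_pos:
                values = index.dish_grams[row_mat, index.ingredient_pos[bound.target_id]].sum(axis=1)
            elif bound.target_type == "category" and bound.target_id in index.category_pos:
                values = index.dish_category_grams[
                    row_mat, index.category_pos[bound.target_id]
                ].sum(axis=1)
            else:
                continue
            if bound.bound_type == "max":
                ok &= values <= bound.amount * lf
            elif bound.bound_type == "min":
                ok &= values >= bound.amount * lf
            elif bound.bound_type == "range":
                high = bound.amount_high if bound.amount_high is not None else bound.amount
                ok &= (values >= bound.amount * lf) & (values <= high * lf)
        if energy_pos is not None:
            energy = totals[:, energy_pos]
            ok &= (energy >= budget.kcal_per_kg_low * user.weight_kg * lf_low) & (
                energy <= budget.kcal_per_kg_high * user.weight_kg * lf_high
            )
            if fat_pos is not None:
                with np.errstate(divide="ignore", invalid="ignore"):
                    share = np.where(
                        energy > 0,
                        totals[:, fat_pos] * budget.kcal_per_g_fat / energy,
                        0.0,
                    )
                ok &= share <= fat_max
        keep = np.flatnonzero(ok)
        if not len(keep):
            continue
        adequacy = _adequacy_counts(totals[keep], index, lf)
        prefs = cand_scores[idx_mat[keep]].mean(axis=1)
        nutrient_order = tuple(index.nutrient_ids)
        for k, count, pref in zip(keep, adequacy, prefs):
            survivors.append(
                MealCombo(
                    dish_ids=tuple(ranked[ci][0] for ci in picks[k]),
                    template=template,
                    preference_score=float(pref),
                    adequacy_count=int(count),
                    _totals=totals[k],
                    _nutrient_order=nutrient_order,
                )
            )
    survivors.sort(key=lambda c: (-c.adequacy_count, -c.preference_score, c.dish_ids))
    return survivors


def recommend(
    user: UserProfile,
    kg: KnowledgeGraph,
    pool: Sequence[UserProfile] = (),
    n_options: int = 5,
    budget: EnergyBudget | None = None,
    *,
    tracked_threshold: int = 5,
    per_template_cap: int | None = 50,
    templates: Sequence[ComboTemplate] = DEFAULT_TEMPLATES,
    k_frequent: int = 10,
) -> RecommendationResult:
    """Full pipeline: filter -> (hot|cold) rank -> assemble -> constrain -> rank.

    Deterministic for fixed inputs. Users with fewer than
    ``tracked_threshold`` history records take the cold-boot path through
    ``pool``; a :class:`~mealcombo.profiles.ColdBootError` propagates if the
    pool has no tracked member. When fewer than ``n_options`` combos are
    feasible, what exists is returned together with a warning record.
    """
    budget = budget or EnergyBudget()
    index = kg_index(kg)
    safe = filter_by_disease(user, kg)
    if user.history_length() >= tracked_threshold:
        mode = "hot"
        ranked = cosine_rank(user, safe, kg, k_frequent=k_frequent)
    else:
        mode = "cold"
        ranked = cold_boot_rank(
            user, pool, safe, kg, min_history=tracked_threshold, k_frequent=k_frequent
        )
    ordered = _fast_pipeline(ranked, user, kg, budget, index, templates, per_template_cap)
    if per_template_cap is not None and len(ordered) < n_options:
        # tightly constrained users (narrow energy windows, strict bounds) can
        # exhaust the rank-capped enumeration; deepen once before giving up
        ordered = _fast_pipeline(
            ranked, user, kg, budget, index, templates, per_template_cap * 16
        )
    warnings = []
    if len(ordered) < n_options:
        warnings.append(
            f"only {len(ordered)} feasible combos for user {user.id!r} "
            f"(requested {n_options})"
        )
    return RecommendationResult(combos=ordered[:n_options], mode=mode, warnings=warnings)
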