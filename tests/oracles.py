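"""Independent brute-force oracles for the recommendation pipeline.

Everything here recomputes results directly from raw graph data with plain
Python dictionaries and itertools -- no shared code with the package's
vectorized pipeline -- so agreement is meaningful. Profile-based reference
matching for cold-boot users is delegated to the package (it is exercised by
its own unit tests); the candidate filtering, ranking arithmetic, combo
enumeration, constraint assessment, and adequacy sorting are all recomputed
here from scratch.
"""

import itertools
import math
from collections import Counter

from mealcombo.profiles import find_reference_user

# The six price-tiered combo patterns, restated independently.
ORACLE_TEMPLATES = [
    ("high-4a", [{"animal-derived"}, {"vegan"}, {"staple"}, {"soup"}]),
    ("high-4b", [{"omnivorous"}, {"omnivorous"}, {"staple"}, {"soup"}]),
    ("intermediate-high-3a", [{"animal-derived"}, {"vegan"}, {"staple"}]),
    ("intermediate-high-3b", [{"omnivorous"}, {"omnivorous"}, {"staple"}]),
    ("intermediate-2", [{"animal-derived", "omnivorous"}, {"complete"}]),
    ("low-2", [{"vegan"}, {"complete"}]),
]


def banned_dishes(user, kg):
    out = set()
    for disease_id in user.diseases:
        rule = kg.diseases.get(disease_id)
        if rule is None:
            continue
        for dish_id, dish in kg.dishes.items():
            for ing_id in dish.composition:
                ing = kg.ingredients[ing_id]
                if ing_id in rule.discourage or ing.category_id in rule.discourage:
                    out.add(dish_id)
        out |= rule.discourage & set(kg.dishes)
    return out


def dish_nutrients(dish, kg):
    totals = {}
    for ing_id, grams in dish.composition.items():
        for nid, per100 in kg.ingredients[ing_id].nutrient_per_100g.items():
            totals[nid] = totals.get(nid, 0.0) + per100 * grams / 100.0
    return totals


def combo_nutrients(dish_ids, kg):
    totals = {}
    for dish_id in dish_ids:
        for nid, v in dish_nutrients(kg.dishes[dish_id], kg).items():
            totals[nid] = totals.get(nid, 0.0) + v
    return totals


def cosine_scores(user, candidates, kg, k_frequent=10):
    """Ranked (dish_id, score) against the user's frequent-dish centroid."""
    counts = Counter()
    for _day, combo in user.history:
        counts.update(combo)
    top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k_frequent]
    vocab = sorted(kg.ingredients)
    centroid = {i: 0.0 for i in vocab}
    weight = sum(c for _d, c in top)
    for dish_id, count in top:
        if dish_id not in kg.dishes:
            continue
        for ing_id, grams in kg.dishes[dish_id].composition.items():
            centroid[ing_id] += count * grams
    if weight:
        centroid = {i: v / weight for i, v in centroid.items()}
    cnorm = math.sqrt(sum(v * v for v in centroid.values()))
    scored = []
    for dish_id in sorted(candidates):
        vec = kg.dishes[dish_id].composition
        norm = math.sqrt(sum(g * g for g in vec.values()))
        dot = sum(g * centroid[i] for i, g in vec.items())
        score = dot / (norm * cnorm) if norm > 0 and cnorm > 0 else 0.0
        scored.append((dish_id, score))
    scored.sort(key=lambda item: (-item[1], item[0]))
    return scored


def matches_some_template(dish_ids, kg):
    """True iff the dishes' categories fill exactly one slot each of a template."""
    cats = [kg.dishes[d].dish_category for d in dish_ids]
    for _name, slots in ORACLE_TEMPLATES:
        if len(slots) != len(cats):
            continue
        for perm in itertools.permutations(range(len(cats))):
            if all(cats[perm[i]] in slots[i] for i in range(len(slots))):
                return True
    return False


def enumerate_all(ranked, kg):
    """All template instantiations over ranked candidates, rank order, no cap."""
    combos = []
    for name, slots in ORACLE_TEMPLATES:
        per_slot = [
            [i for i, (d, _s) in enumerate(ranked)
             if kg.dishes[d].dish_category in slot]
            for slot in slots
        ]

        def walk(slot_i, chosen):
            if slot_i == len(slots):
                combos.append((name, tuple(chosen)))
                return
            same = slot_i > 0 and slots[slot_i] == slots[slot_i - 1]
            for ci in per_slot[slot_i]:
                if ci in chosen or (same and ci <= chosen[-1]):
                    continue
                walk(slot_i + 1, chosen + [ci])

        walk(0, [])
    return combos


def violates_constraints(dish_ids, user, kg, lunch_fraction=0.40,
                         kcal_low=20.0, kcal_high=25.0,
                         lf_low=0.40, lf_high=0.40, fat_max=0.30,
                         diabetes_override=(0.30, 0.35, 0.25)):
    banned = banned_dishes(user, kg)
    if banned & set(dish_ids):
        return True
    totals = combo_nutrients(dish_ids, kg)
    grams_by_ing = {}
    grams_by_cat = {}
    for dish_id in dish_ids:
        for ing_id, grams in kg.dishes[dish_id].composition.items():
            grams_by_ing[ing_id] = grams_by_ing.get(ing_id, 0.0) + grams
            cat = kg.ingredients[ing_id].category_id
            grams_by_cat[cat] = grams_by_cat.get(cat, 0.0) + grams
    for disease_id in user.diseases:
        rule = kg.diseases.get(disease_id)
        if rule is None:
            continue
        for bound in rule.restrict:
            if bound.target_type == "nutrient" and bound.target_id in kg.nutrients:
                value = totals.get(bound.target_id, 0.0)
            elif bound.target_type == "ingredient" and bound.target_id in kg.ingredients:
                value = grams_by_ing.get(bound.target_id, 0.0)
            elif bound.target_type == "category" and bound.target_id in kg.categories:
                value = grams_by_cat.get(bound.target_id, 0.0)
            else:
                continue
            limit = bound.amount * lunch_fraction
            if bound.bound_type == "max" and value > limit:
                return True
            if bound.bound_type == "min" and value < limit:
                return True
            if bound.bound_type == "range":
                high = bound.amount_high if bound.amount_high is not None else bound.amount
                if not limit <= value <= high * lunch_fraction:
                    return True
    names = {d.casefold() for d in user.diseases}
    for d in user.diseases:
        if d in kg.diseases:
            names.add(kg.diseases[d].name.casefold())
    if "diabetes" in names:
        lf_low, lf_high, fat_max = diabetes_override
    if "energy" in kg.nutrients:
        energy = totals.get("energy", 0.0)
        if not (kcal_low * user.weight_kg * lf_low
                <= energy <= kcal_high * user.weight_kg * lf_high):
            return True
        if "fat" in kg.nutrients and energy > 0:
            if totals.get("fat", 0.0) * 9.0 / energy > fat_max:
                return True
    return False


def adequacy(dish_ids, kg, lunch_fraction=0.40):
    totals = combo_nutrients(dish_ids, kg)
    count = 0
    for nid, nutrient in kg.nutrients.items():
        if nutrient.guideline_low is None or nutrient.guideline_high is None:
            continue
        value = totals.get(nid, 0.0)
        if nutrient.guideline_low * lunch_fraction <= value <= nutrient.guideline_high * lunch_fraction:
            count += 1
    return count


def brute_force_recommend(user, kg, pool, n_options=5, tracked_threshold=5):
    """Full-pipeline oracle: exhaustive enumeration + filtering + sorting."""
    safe = set(kg.dishes) - banned_dishes(user, kg)
    if user.history_length() >= tracked_threshold:
        base = user
    else:
        base = find_reference_user(user, pool, min_history=tracked_threshold)
    ranked = cosine_scores(base, safe, kg)
    results = []
    for _name, pick in enumerate_all(ranked, kg):
        dish_ids = tuple(ranked[ci][0] for ci in pick)
        if violates_constraints(dish_ids, user, kg):
            continue
        pref = sum(ranked[ci][1] for ci in pick) / len(pick)
        results.append((adequacy(dish_ids, kg), pref, dish_ids))
    results.sort(key=lambda item: (-item[0], -item[1], item[2]))
    return [(dish_ids, count) for count, _pref, dish_ids in results[:n_options]]
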