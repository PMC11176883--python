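# Methods

This note documents the models and procedures `mealcombo` implements, the
parameters that matter, what the synthetic data generator does and does not
emulate, and the numerical choices made where the design was open.

## Food knowledge graph

The graph stores five entity classes — dishes, ingredients, ingredient
categories, nutrients, diseases — and six typed relations (`consist_of`,
`contain`, `belong_to`, `discourage`, `restrict`, `recommend`). Edges may
carry an amount (grams for composition, nutrient-native units for
containment, per-day amounts with a bound type for restrictions). Building
the graph from the four input tables materializes the natural relations and
then applies two first-order inference rules:

* **Nutrient propagation.** A dish containing `Pᵢ` grams of ingredient `i`,
  whose composition table lists `Mᵢ` units of nutrient `n` per 100 g,
  contains `Q = Σᵢ Mᵢ·Pᵢ/100` of `n` per portion. The rule is exactly linear
  in the composition; the test suite asserts bit-exact linearity under
  power-of-two scaling.
* **Discouragement propagation.** A dish is discouraged for a disease when
  it contains a discouraged ingredient *or* an ingredient whose category is
  discouraged — category-level exclusions are inherited by members, so a
  single "shellfish" edge covers every shellfish dish.

**Deduplication.** "Ingredient similarity" between two dishes is Jaccard
similarity over their ingredient-id sets; pairs at or above the 0.85
threshold (inclusive), or with case-folded equal names, are clustered with
union–find, and the variant whose exact ingredient combination occurs most
frequently in the input is kept (frequency ties fall to the smallest dish
id for determinism). Jaccard was chosen because ingredient sets are the
only available basis; a gram-weighted alternative would need a distance on
compositions that the inputs do not define.

**Sodium standardization.** Each dish's sodium mass fraction is brought
into [0.8 %, 1.0 %] of portion mass. Sodium outside the band is treated as
seasoning-derived: the grams of the dish's seasoning ingredients are
rescaled by the factor `k` solving
`(Na_fixed + k·Na_seas) / (M_fixed + k·M_seas) = bound`, which lands the
fraction exactly on the nearest bound while leaving all non-seasoning
entries untouched. A dish whose non-seasoning sodium alone exceeds the band
cannot be standardized and is rejected with an explicit error rather than
silently altered.

**Rule extraction.** Guideline-style statements are matched against a
pattern lexicon (regular expressions with `target`, and for restrictions
`amount`/`unit`, capture groups) mapping surface forms to the three
relation types. Unmatched statements are returned for review, never
dropped; a statement matching two different relation types raises an
ambiguity error listing the colliding patterns.

**Persistence** is a JSON document (entities plus edge list) with CSV
node/edge exports and a `networkx` view — deliberately file-based and
diff-able rather than a database server, which desk-scale graphs (hundreds
of entities, ~10⁴ triples) do not need.

## User profiles and similarity

Profiles carry sociodemographics, health conditions, and four preference
dimensions (flavor, staple, oil, cooking method). For cold-start matching a
profile is flattened to categorical `dimension=value` tokens: sex, age band
(60–64 / 65–79 / 80+), BMI band (≤ 19.9 / 20.0–26.9 / ≥ 27.0), income band
(included by default, toggleable), activity level, each preference, and one
token per disease. Similarity is Jaccard over token sets; the reference
user for a cold-boot recommendation is the tracked user (history ≥ 5
records) maximizing this similarity, ties broken by smallest user id so the
choice is pool-order invariant.

## Recommendation pipeline

1. **Disease filter.** Remove every dish discouraged (directly or by
   inference) for any of the user's diseases.
2. **Preference rerank.** Hot boot: score each candidate by cosine
   similarity between its ingredient-gram vector and the selection-count-
   weighted centroid of the user's 10 most frequent dishes (`k_frequent`,
   configurable). Zero-vector candidates score 0 by definition. Cold boot
   delegates to the reference user's centroid.
3. **Combo assembly.** Six price-tiered templates (two four-dish, two
   three-dish, two two-dish patterns over the categories animal-derived /
   vegan / omnivorous / staple / soup / complete). Enumeration follows
   candidate rank lexicographically; interchangeable slots are filled in
   strictly increasing rank order so no combo is produced twice. A
   per-template cap (default 50) bounds combinatorics; when a tightly
   constrained user yields fewer than the requested options, enumeration is
   deepened once (cap × 16) before returning fewer combos with a warning.
4. **Constraint assessment.** A combo fails if it contains a discouraged
   dish; violates a restriction bound (per-day amounts scaled to one lunch
   by the lunch fraction — e.g. cholesterol ≤ 200 × 0.40 mg); falls outside
   the energy window `[kcal/kg_low · w · lf_low, kcal/kg_high · w · lf_high]`
   for body weight `w`; or exceeds the fat-energy cap. Violations are
   itemized, not just flagged.
5. **Adequacy ranking.** Feasible combos are ordered by the number of
   nutrients whose lunch-scaled totals sit inside guideline ranges, ties by
   higher preference score, then smallest dish-id tuple. Adequacy is judged
   against lunch-scaled (not daily) ranges, since the system plans exactly
   one meal.

Key defaults: lunch fraction 0.40 (the middle share of a 3:4:3 daily energy
split); energy 20–25 kcal/kg/day; fat cap 30 % of combo energy; a
disease-override table narrows the envelope for diabetes to a 30 %–35 %
lunch share and a 25 % fat cap. Because that override *shifts* the energy
window rather than narrowing it, feasibility is monotone under added
diseases only for diseases without an override; the property tests reflect
this.

The pipeline is deterministic end to end: every ordering has a total
tie-break, and no stage draws random numbers. A vectorized internal path
(index tuples + dense dish–nutrient matrices) accelerates the pipeline for
simulation use; it is asserted equal to the object-level API and to an
independent brute-force oracle in the tests.

## Outcome indices

**DDS.** Ingredient categories map onto nine diversity groups
(cereals/tubers, vegetables, fruits, meat, fish/seafood, eggs, dairy,
legumes/nuts, oils/fats; seasonings map to "none"). The score is the count
of distinct groups represented across the day's combos — integer, 0–9,
monotone under adding dishes.

**Quality index.** A data-driven component table (YAML-serializable) in the
form of guideline-adherence indices for Chinese seniors: each component
names a basis (a food-group gram amount or a nutrient amount per lunch), an
optimal band `[low, high]`, and a point mass; component score is maximal
inside the band, decays linearly to 0 at zero intake and — penalizing
over-consumption — at `2·high`. The shipped default has 11 components
(6 food groups + energy, protein, fat, fiber, carbohydrate) of 10 points
each, total 110. The exact published component table for the index this
emulates is not publicly available, so the package treats the table as
configuration: the form and range are fixed, the rows are replaceable, and
no numerical equivalence to published survey scores is claimed.

## Simulated intervention and statistics

The cohort is split at ≥ 5 history records ("≥" chosen over a conflicting
">" phrasing because the operational rule is stated with ≥). Each simulated
day (default 30 recommendation days; a weekdays-only flag restricts to the
22 weekdays of a 30-day horizon) every user is offered `n_options = 5`
combos and takes one uniformly at random from a seeded stream; tracked
users' selections are appended to their histories, so their hot-boot
centroids — and the cold-boot rankings borrowed from them — update over
time. User-days with zero feasible combos are logged as skips. The
autonomous baseline, standing in for unobservable real behavior, assembles
a uniformly random template combo from the user's disease-safe dishes with
no constraint check or adequacy ranking.

Randomness enters only through the selection and baseline streams (two
independent child seeds of the run seed): reruns with the same seed are
byte-identical, and day-one offer sets are seed-invariant. From day two
onward offers legitimately depend on the seed, because histories grow with
the seeded selections.

Comparison follows a before/after table layout: per group × indicator,
autonomous mean (SD), recommended mean (SD), *t* (df), two-sided *p*.
Tracked users get a paired *t* test on per-user means (identical vectors
return t = 0, p = 1 rather than 0/0); the untracked group's recommended
scores are tested against the *tracked* group's autonomous distribution
with Welch's unequal-variance *t* (fractional Satterthwaite df), under the
assumption that the two groups share the autonomous-choice distribution.
Per-day 95 % confidence bands are normal-approximation intervals over all
offered options' scores in the group that day. The untracked comparator is
a constant (the tracked autonomous mean), not a day-matched series.

**Sample size.** `n = ⌈2σ²(1−ρ)(z₁₋α/₂ + z₁₋β)² / δ²⌉` per arm — the
repeated-measures form with within-subject correlation ρ — and recruitment
`⌈n/(1−attrition)⌉`. With δ = 2.0, σ = 6.0, ρ = 0.5, α = 0.05, power 0.80,
attrition 0.20 this gives 71 per arm and 89 recruited. ρ = 1 is rejected as
a degenerate design.

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs. A default world has 180 dishes, 112 ingredients, 20
categories, 27 nutrients, and 30 geriatric diseases; the default cohort has
96 members, 34 of them tracked (35 %), with hypertension at 59 %, arthritis
31 %, diabetes 24 %, and remaining disease prevalences drawn once from
U(0.02, 0.09).

* **Ingredients** draw nutrient densities from per-food-kind log-uniform
  priors recorded in `NUTRIENT_PRIORS` (per 100 g, as-served). The priors
  are kind-specific for micronutrients — vitamin C and folate concentrate in
  produce, iron/zinc/B12 in meat, calcium in dairy, iodine and selenium in
  fish — because that clustering is the mechanism that makes food-group
  diversity nutritionally meaningful; with flat micronutrient priors,
  adequacy ranking would be blind to diversity in a way real food
  composition is not.
* **Dishes** are assembled per category from realistic portion ranges
  (e.g. staples 100–165 g cooked cereal; omnivorous dishes 40–80 g protein
  + 80–150 g vegetables; oil present in ~60–70 % of cooked dishes at
  2–5 g), always carry a salt seasoning, are forced to have pairwise
  distinct ingredient sets so the 0.85 dedup bar does not collapse the
  census, and are sodium-standardized at generation time (so the build step
  finds them already in band).
* **Guideline ranges and restriction bounds** are calibrated against the
  generated food supply: per nutrient, the daily guideline is the 35th–85th
  percentile band of sampled template-combo lunch totals scaled up by the
  lunch fraction, and each disease's restriction bound sits at the 90th
  percentile. This keeps adequacy counts discriminating (a typical combo
  satisfies some criteria, a good one many) for any seed and any world
  size, without hand-set magnitudes that would drift out of scale.
* **Cohort.** Age, BMI, and sex follow the banded distributions of the
  study population (14/69/17 % age bands, 2/70/28 % BMI bands, 53 % male);
  weight is derived from BMI and a sex-specific height draw. Diseases come
  from a Gaussian copula with a shared latent frailty factor (loading 0.30)
  so marginal prevalences are exact while comorbidity clusters; the loading
  was set so ~38 % of a large cohort carries ≥ 3 conditions. Tracked users
  receive 5–15 history records of uniformly chosen disease-safe combos.

What the generator does **not** emulate: real recipes or Chinese food
composition values (names and magnitudes are synthetic), seasonal or
price-driven menu variation, household co-eating, measurement error in the
IoT-style history log, and any behavioral structure in autonomous choice
beyond uniform selection. Passing tests therefore demonstrate the
machinery — safety, constraint handling, ranking, statistics — under
realistic magnitudes, not nutritional conclusions about real populations.

## Problem sizes and numerical choices

The default test/acceptance configuration simulates 96 users × 30 days × 5
options (~2 900 user-days per run) and repeats the full simulation over 100
seeds for the directional comparison; safety and oracle-equivalence checks
use 1 000 and ~40 randomized small worlds respectively. These sizes make
one simulation run in a few seconds on a single core while keeping every
cell of the comparison table populated.

Floating-point tolerances: nutrient inference is checked against hand
summation at 1e-9 absolute; the t statistics against closed forms at
1e-12; sodium fractions at the band edges within 1e-12 relative. Tie-breaks
are always lexicographic on ids after the scientific keys, so all outputs
are reproducible across platforms. Degenerate inputs (empty histories,
empty disease tables, zero-dish worlds, zero-portion dishes, identical
score vectors) take defined paths — cold boot, empty edge sets, empty
tables, explicit errors, t = 0 — rather than NaNs.

## Known limitations

* The published component table of the diet-quality index is approximated
  by a configurable default; absolute index values are not comparable to
  published survey scores, only the 0–110 form and the within-run contrasts
  are meaningful.
* The cold-boot reference is recomputed from a fixed tracked pool; if the
  pool is empty the recommender raises rather than falling back to an
  unpersonalized ranking.
* Combo enumeration is rank-capped for speed; the one-step deepening makes
  starvation rare but a pathologically constrained user can still receive
  fewer than the requested options (returned with a warning, and logged as
  a skip by the simulation when zero).
* The autonomous baseline is uniform over safe combos; real autonomous
  eating is habitual and budget-driven, so effect sizes from the harness
  should be read as mechanism checks, not predicted intervention effects.
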