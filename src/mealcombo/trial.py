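"""Simulated 30-day intervention, outcome comparison, and power calculation.

The cohort is split into a tracked group (eating history of at least five
records, hot-boot recommendations that keep updating as the simulated
history grows) and an untracked group (cold-boot recommendations borrowed
from the most similar tracked user). On each simulated day every user is
offered ``n_options`` combos and takes one uniformly at random; diversity
(DDS) and diet-quality index scores are logged per user-day, next to an
autonomous baseline in which the user assembles a uniformly random
disease-safe combo with no constraint assessment or adequacy ranking.

Outcomes are compared in the layout of a before/after table: paired t test
within the tracked group, Welch's unequal-variance t test of the untracked
group's recommended scores against the tracked group's autonomous scores.
The sample-size calculation uses the repeated-measures normal-approximation
formula n = 2*sigma^2*(1-rho)*(z_{1-alpha/2} + z_{1-beta})^2 / delta^2 per
arm, inflated for attrition by 1/(1-rate).
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dietscore import ComboScorer, DiversityGroups, QualityIndexSpec
from .foodkg import KnowledgeGraph
from .profiles import UserProfile, frequent_dishes
from .recommender import EnergyBudget, RecommendationResult, recommend
from .syndata import sample_uniform_combo


class StatisticsError(ValueError):
    """Raised when a comparison group is too small to test."""


class DegenerateDesignError(ValueError):
    """Raised when the power calculation parameters void the design."""


# ---------------------------------------------------------------------------
# groups
# ---------------------------------------------------------------------------


@dataclass
class GroupAssignment:
    tracked: set[str]
    untracked: set[str]
    threshold: int = 5

    def group_of(self, user_id: str) -> str:
        return "tracked" if user_id in self.tracked else "untracked"


def assign_groups(cohort: Sequence[UserProfile], threshold: int = 5) -> GroupAssignment:
    """Partition the cohort by eating-history length (>= threshold tracked)."""
    if not cohort:
        raise ValueError("empty cohort")
    tracked = {u.id for u in cohort if u.history_length() >= threshold}
    return GroupAssignment(
        tracked=tracked,
        untracked={u.id for u in cohort} - tracked,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


@dataclass
class SimRecord:
    user_id: str
    group: str
    day: int
    offered: list[tuple[str, ...]]
    selected: int  # index into offered
    dds: float
    quality: float
    autonomous_dds: float
    autonomous_quality: float
    offered_dds: list[float]
    offered_quality: list[float]

    def to_dict(self) -> dict:
        doc = dict(vars(self))
        doc["offered"] = [list(c) for c in self.offered]
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "SimRecord":
        doc = dict(doc)
        doc["offered"] = [tuple(c) for c in doc["offered"]]
        return cls(**doc)


@dataclass
class SimulationResult:
    records: list[SimRecord]
    assignment: GroupAssignment
    seed: int
    days: int
    n_options: int
    skipped: list[tuple[str, int]] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "user_id": r.user_id, "group": r.group, "day": r.day,
                    "dds": r.dds, "quality": r.quality,
                    "autonomous_dds": r.autonomous_dds,
                    "autonomous_quality": r.autonomous_quality,
                }
                for r in self.records
            ]
        )

    def per_user_means(self, column: str) -> dict[str, float]:
        frame = self.frame()
        return frame.groupby("user_id")[column].mean().to_dict()

    def group_day_series(self) -> pd.DataFrame:
        """Per group-day mean and 95% CI over all offered options' scores."""
        rows = []
        by_key: dict[tuple[str, int, str], list[float]] = {}
        for r in self.records:
            for indicator, values in (
                ("dds", r.offered_dds),
                ("quality", r.offered_quality),
            ):
                by_key.setdefault((r.group, r.day, indicator), []).extend(values)
        for (group, day, indicator), values in sorted(by_key.items()):
            arr = np.asarray(values, dtype=float)
            mean = float(arr.mean())
            half = 1.959963984540054 * float(arr.std(ddof=1)) / math.sqrt(len(arr)) \
                if len(arr) > 1 else 0.0
            rows.append(
                {"group": group, "day": day, "indicator": indicator, "mean": mean,
                 "ci_low": mean - half, "ci_high": mean + half, "n": len(arr)}
            )
        return pd.DataFrame(rows)

    def to_jsonl(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            header = {
                "seed": self.seed, "days": self.days, "n_options": self.n_options,
                "tracked": sorted(self.assignment.tracked),
                "untracked": sorted(self.assignment.untracked),
                "threshold": self.assignment.threshold,
                "skipped": [list(s) for s in self.skipped],
            }
            fh.write(json.dumps(header, ensure_ascii=False) + "\n")
            for r in self.records:
                fh.write(json.dumps(r.to_dict(), ensure_ascii=False) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "SimulationResult":
        with open(path, encoding="utf-8") as fh:
            header = json.loads(fh.readline())
            records = [SimRecord.from_dict(json.loads(line)) for line in fh if line.strip()]
        return cls(
            records=records,
            assignment=GroupAssignment(
                tracked=set(header["tracked"]),
                untracked=set(header["untracked"]),
                threshold=header.get("threshold", 5),
            ),
            seed=header["seed"],
            days=header["days"],
            n_options=header["n_options"],
            skipped=[tuple(s) for s in header.get("skipped", [])],
        )


def _weekdays(days: int, weekdays_only: bool) -> list[int]:
    if not weekdays_only:
        return list(range(1, days + 1))
    return [d for d in range(1, days + 1) if (d - 1) % 7 < 5]


def run_simulation(
    cohort: Sequence[UserProfile],
    kg: KnowledgeGraph,
    days: int = 30,
    n_options: int = 5,
    seed: int = 0,
    budget: EnergyBudget | None = None,
    *,
    threshold: int = 5,
    weekdays_only: bool = False,
    groups: DiversityGroups | None = None,
    quality_spec: QualityIndexSpec | None = None,
    k_frequent: int = 10,
) -> SimulationResult:
    """Run the simulated intervention.

    Each simulated day every user receives ``n_options`` recommendations and
    selects one uniformly at random from the seeded stream; tracked users'
    histories grow with their selections so hot-boot rankings update over
    time. User-days with zero feasible combos are logged as skips. Reruns
    with an equal seed are identical; the recommendation pipeline itself is
    deterministic, so randomness enters only through the selection (and
    autonomous-baseline) streams.
    """
    budget = budget or EnergyBudget()
    cohort = [copy.deepcopy(u) for u in cohort]
    assignment = assign_groups(cohort, threshold=threshold)
    pool = [u for u in cohort if u.id in assignment.tracked]
    scorer = ComboScorer(kg, groups=groups, spec=quality_spec)
    select_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]).generate_state(1))
    autonomous_rng = np.random.default_rng(np.random.SeedSequence([seed, 2]).generate_state(1))

    from .recommender import filter_by_disease  # local alias; avoids cycle at import

    safe_by_user = {u.id: sorted(filter_by_disease(u, kg)) for u in cohort}
    # offered sets are deterministic given the user's frequent-dish profile,
    # so cache on (user, taste-profile) and recompute only when taste changes
    reference_of: dict[str, str] = {}
    offer_cache: dict[tuple, RecommendationResult] = {}

    def taste_key(user: UserProfile) -> tuple:
        if user.id in assignment.tracked:
            base = user
        else:
            ref_id = reference_of.get(user.id)
            if ref_id is None:
                from .profiles import find_reference_user

                base = find_reference_user(user, pool, min_history=threshold)
                reference_of[user.id] = base.id
            else:
                base = next(u for u in pool if u.id == ref_id)
        top = tuple(frequent_dishes(base, k_frequent))
        return (user.id, base.id, top)

    records: list[SimRecord] = []
    skipped: list[tuple[str, int]] = []
    for day in _weekdays(days, weekdays_only):
        for user in cohort:
            key = taste_key(user)
            result = offer_cache.get(key)
            if result is None:
                result = recommend(
                    user, kg, pool, n_options=n_options, budget=budget,
                    tracked_threshold=threshold, k_frequent=k_frequent,
                )
                offer_cache[key] = result
            if not result.combos:
                skipped.append((user.id, day))
                continue
            pick = int(select_rng.integers(len(result.combos)))
            selected = result.combos[pick]
            autonomous = sample_uniform_combo(safe_by_user[user.id], kg, autonomous_rng)
            if autonomous is None:
                skipped.append((user.id, day))
                continue
            offered_ids = [c.dish_ids for c in result.combos]
            records.append(
                SimRecord(
                    user_id=user.id,
                    group=assignment.group_of(user.id),
                    day=day,
                    offered=offered_ids,
                    selected=pick,
                    dds=float(scorer.dds(selected.dish_ids)),
                    quality=scorer.quality(selected.dish_ids),
                    autonomous_dds=float(scorer.dds(autonomous)),
                    autonomous_quality=scorer.quality(autonomous),
                    offered_dds=[float(scorer.dds(ids)) for ids in offered_ids],
                    offered_quality=[scorer.quality(ids) for ids in offered_ids],
                )
            )
            if user.id in assignment.tracked:
                user.history.append((day, selected.dish_ids))
    return SimulationResult(
        records=records,
        assignment=assignment,
        seed=seed,
        days=days,
        n_options=n_options,
        skipped=skipped,
    )


# ---------------------------------------------------------------------------
# outcome comparison (before/after table layout)
# ---------------------------------------------------------------------------


def paired_t(after: np.ndarray, before: np.ndarray) -> tuple[float, float, float]:
    """Paired two-sided t test; returns (t, df, p).

    Identical vectors (all differences zero) yield t = 0, p = 1 rather than
    the 0/0 indeterminate form.
    """
    diff = np.asarray(after, dtype=float) - np.asarray(before, dtype=float)
    if np.all(diff == 0):
        return 0.0, float(len(diff) - 1), 1.0
    res = stats.ttest_rel(after, before)
    return float(res.statistic), float(len(after) - 1), float(res.pvalue)


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sided t test; returns (t, df, p)."""
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def compare_outcomes(
    result: SimulationResult,
    baseline: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Group x indicator comparison of recommended versus autonomous scores.

    ``baseline`` maps indicator ("dds" | "quality") to per-user autonomous
    mean scores; by default the autonomous series embedded in the simulation
    result is used. The tracked group is tested with a paired two-sided t
    test; the untracked group's recommended scores are tested against the
    tracked group's autonomous distribution with Welch's t test (the groups
    are assumed to share the autonomous-choice distribution).
    """
    frame = result.frame()
    if baseline is None:
        baseline = {
            ind: frame.groupby("user_id")[f"autonomous_{ind}"].mean().to_dict()
            for ind in ("dds", "quality")
        }
    recommended = {
        ind: frame.groupby("user_id")[ind].mean().to_dict()
        for ind in ("dds", "quality")
    }
    rows = []
    for group in ("tracked", "untracked"):
        members = sorted(getattr(result.assignment, group))
        members = [m for m in members if m in recommended["dds"]]
        tracked_members = sorted(
            m for m in result.assignment.tracked if m in recommended["dds"]
        )
        if len(members) < 2 or len(tracked_members) < 2:
            raise StatisticsError(f"group {group!r} too small for comparison")
        for indicator in ("quality", "dds"):
            rec = np.array([recommended[indicator][m] for m in members])
            if group == "tracked":
                aut = np.array([baseline[indicator][m] for m in members])
                t, df, p = paired_t(rec, aut)
            else:
                aut = np.array([baseline[indicator][m] for m in tracked_members])
                t, df, p = welch_t(rec, aut)
            rows.append(
                {
                    "group": group,
                    "indicator": indicator,
                    "autonomous_mean": float(aut.mean()),
                    "autonomous_sd": float(aut.std(ddof=1)),
                    "recommended_mean": float(rec.mean()),
                    "recommended_sd": float(rec.std(ddof=1)),
                    "t": t,
                    "df": df,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sample size / power
# ---------------------------------------------------------------------------


@dataclass
class PowerParams:
    """Inputs of the repeated-measures sample-size formula.

    delta: smallest meaningful difference (score units); sigma: common SD;
    rho: within-subject correlation between repeated measures; alpha:
    two-sided type-I error rate; power: 1 - beta; attrition: expected
    dropout fraction.
    """

    delta: float = 2.0
    sigma: float = 6.0
    rho: float = 0.5
    alpha: float = 0.05
    power: float = 0.80
    attrition: float = 0.20

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha outside (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power outside (0, 1)")
        if self.rho >= 1:
            raise DegenerateDesignError("rho = 1 leaves no residual variance")
        if not 0 <= self.rho < 1:
            raise ValueError("rho outside [0, 1)")
        if self.delta <= 0 or self.sigma <= 0:
            raise ValueError("delta and sigma must be positive")
        if not 0 <= self.attrition < 1:
            raise ValueError("attrition outside [0, 1)")


def required_sample_size(p: PowerParams) -> int:
    """Participants per arm: ceil(2*sigma^2*(1-rho)*(z_a + z_b)^2 / delta^2)."""
    p.validate()
    z = stats.norm.ppf(1 - p.alpha / 2) + stats.norm.ppf(p.power)
    n = 2 * p.sigma**2 * (1 - p.rho) * z**2 / p.delta**2
    return math.ceil(n)


def inflate_for_attrition(n: int, rate: float) -> int:
    """Recruitment target preserving ``n`` completers: ceil(n / (1 - rate))."""
    if not 0 <= rate < 1:
        raise ValueError("attrition rate outside [0, 1)")
    return math.ceil(n / (1 - rate))
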