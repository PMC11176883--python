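"""Older-adult user profiles, categorical encoding, and profile similarity.

Profiles carry three blocks of information: sociodemographics (sex, age,
BMI, income), health conditions (diagnosed diseases, activity level), and
dietary preferences (flavor, staple, oil, cooking method). For cold-start
matching a profile is flattened to a set of ``dimension=value`` tokens and
compared with Jaccard similarity; the tracked eating history (day-indexed
combo selections) drives the content-based ranking instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter
from typing import Iterable, Sequence

PREFERENCE_DIMENSIONS = ("flavor", "staple", "oil", "cooking_method")

#: Age bands used for categorical encoding (years, inclusive).
AGE_BANDS = (("60-64", 60, 64), ("65-79", 65, 79), ("80+", 80, None))
#: BMI bands (kg/m^2).
BMI_BANDS = (("<=19.9", None, 19.9), ("20.0-26.9", 20.0, 26.9), (">=27.0", 27.0, None))


class EncodingError(ValueError):
    """Raised when a profile lacks a mandatory field for encoding."""


class ColdBootError(LookupError):
    """Raised when no reference user with sufficient history exists."""


@dataclass
class UserProfile:
    id: str
    sex: str  # "male" | "female"
    age_years: int
    weight_kg: float
    bmi: float
    income_band: str
    diseases: set[str] = field(default_factory=set)
    activity_level: str = "light"  # light | moderate | vigorous
    preferences: dict[str, str] = field(default_factory=dict)
    history: list[tuple[int, tuple[str, ...]]] = field(default_factory=list)

    def history_length(self) -> int:
        return len(self.history)

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "sex": self.sex,
            "age_years": self.age_years,
            "weight_kg": self.weight_kg,
            "bmi": self.bmi,
            "income_band": self.income_band,
            "diseases": sorted(self.diseases),
            "activity_level": self.activity_level,
            "preferences": dict(self.preferences),
            "history": [[day, list(combo)] for day, combo in self.history],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "UserProfile":
        return cls(
            id=doc["id"],
            sex=doc["sex"],
            age_years=int(doc["age_years"]),
            weight_kg=float(doc["weight_kg"]),
            bmi=float(doc["bmi"]),
            income_band=str(doc["income_band"]),
            diseases=set(doc.get("diseases", [])),
            activity_level=doc.get("activity_level", "light"),
            preferences=dict(doc.get("preferences", {})),
            history=[
                (int(day), tuple(combo)) for day, combo in doc.get("history", [])
            ],
        )


@dataclass(frozen=True)
class FeatureSet:
    tokens: frozenset[str]

    def __len__(self) -> int:
        return len(self.tokens)


def _band(value: float, bands) -> str:
    for label, lo, hi in bands:
        if (lo is None or value >= lo) and (hi is None or value <= hi):
            return label
    raise EncodingError(f"value {value} falls outside all bands")


def encode_profile(user: UserProfile, include_income: bool = True) -> FeatureSet:
    """Flatten a profile to categorical ``dimension=value`` tokens.

    Tokens cover sex, age band, BMI band, income band (toggleable), activity
    level, each preference dimension present, and one token per disease.
    Equal profiles encode to equal token sets.
    """
    for name in ("sex", "age_years", "bmi", "activity_level"):
        if getattr(user, name) in (None, ""):
            raise EncodingError(f"profile {user.id!r}: missing mandatory field {name!r}")
    tokens = {
        f"sex={user.sex}",
        f"age={_band(user.age_years, AGE_BANDS)}",
        f"bmi={_band(user.bmi, BMI_BANDS)}",
        f"activity={user.activity_level}",
    }
    if include_income:
        if user.income_band in (None, ""):
            raise EncodingError(f"profile {user.id!r}: missing mandatory field 'income_band'")
        tokens.add(f"income={user.income_band}")
    for dim in PREFERENCE_DIMENSIONS:
        if dim in user.preferences:
            tokens.add(f"{dim}={user.preferences[dim]}")
    for disease in user.diseases:
        tokens.add(f"disease={disease}")
    return FeatureSet(tokens=frozenset(tokens))


def jaccard_similarity(a: FeatureSet, b: FeatureSet) -> float:
    """|a ∩ b| / |a ∪ b| over the two token sets; symmetric, in [0, 1]."""
    union = a.tokens | b.tokens
    if not union:
        raise ValueError("Jaccard similarity undefined for two empty feature sets")
    return len(a.tokens & b.tokens) / len(union)


def find_reference_user(
    target: UserProfile,
    pool: Sequence[UserProfile],
    min_history: int = 5,
    include_income: bool = True,
) -> UserProfile:
    """The pool member with >= ``min_history`` records most similar to ``target``.

    Similarity is Jaccard over encoded feature sets; ties break to the
    smallest user id, which also makes the result invariant to pool order.
    """
    target_features = encode_profile(target, include_income=include_income)
    eligible = [u for u in pool if u.history_length() >= min_history and u.id != target.id]
    if not eligible:
        raise ColdBootError(
            f"no reference user with history >= {min_history} for {target.id!r}"
        )
    return max(
        eligible,
        key=lambda u: (
            jaccard_similarity(target_features, encode_profile(u, include_income=include_income)),
            # invert id ordering for tie-break: max() keeps the smallest id
            _NegStr(u.id),
        ),
    )


class _NegStr:
    """Reverse-ordering wrapper so max() ties break to the smallest string."""

    __slots__ = ("value",)

    def __init__(self, value: str):
        self.value = value

    def __lt__(self, other: "_NegStr") -> bool:
        return self.value > other.value

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _NegStr) and self.value == other.value


def selection_counts(user: UserProfile) -> Counter:
    counts: Counter = Counter()
    for _day, combo in user.history:
        counts.update(combo)
    return counts


def frequent_dishes(user: UserProfile, k: int) -> list[str]:
    """Top-``k`` dish ids by selection count; ties break to the smaller id.

    An empty history yields an empty list -- the caller must then switch to
    the cold-boot path.
    """
    counts = selection_counts(user)
    ranked = sorted(counts.items(), key=lambda item: (-item[1], item[0]))
    return [dish_id for dish_id, _ in ranked[:k]]


def load_profiles(path) -> list[UserProfile]:
    import json

    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return [UserProfile.from_dict(row) for row in doc]


def save_profiles(users: Iterable[UserProfile], path) -> None:
    import json

    with open(path, "w", encoding="utf-8") as fh:
        json.dump([u.to_dict() for u in users], fh, ensure_ascii=False, indent=1)
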