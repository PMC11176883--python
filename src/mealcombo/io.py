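"""Shared serialization, validation, configuration, and report export.

All artifacts are plain text: CSV (UTF-8, comma, mandatory header) for
tables, JSON for nested structures, JSONL for per-record logs, YAML for
configuration. Every exported report carries a provenance block (seed,
config hash, package version) so runs can be reproduced and audited.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .syndata import FoodTables


class ValidationError(ValueError):
    """Structured table-validation failure; ``errors`` lists file/row issues."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


TABLE_SCHEMAS: dict[str, list[str]] = {
    "recipes": ["dish_id", "name", "category", "flavor", "cooking_method",
                "price_level", "ingredient_id", "grams"],
    "composition": ["ingredient_id", "name", "category_id", "nutrient_id",
                    "amount_per_100g", "unit"],
    "disease_rules": ["disease_id", "relation", "target_type", "target_id"],
    "guidelines": ["nutrient_id", "unit", "low", "high"],
    "categories": ["category_id", "name"],
}

_NON_NEGATIVE = {"recipes": "grams", "composition": "amount_per_100g"}


def load_tables(paths: dict[str, str | Path]) -> FoodTables:
    """Read and validate the input CSVs.

    ``paths`` maps table names (recipes, composition, disease_rules,
    guidelines, optionally categories) to files. Schema or value problems
    are collected into one :class:`ValidationError` naming file and row.
    """
    errors: list[str] = []
    frames: dict[str, pd.DataFrame] = {}
    for name in ("recipes", "composition", "disease_rules", "guidelines", "categories"):
        if name not in paths:
            if name == "categories":
                frames[name] = None
                continue
            errors.append(f"{name}: path not provided")
            continue
        path = Path(paths[name])
        if not path.exists():
            errors.append(f"{name}: file {path} does not exist")
            continue
        frame = pd.read_csv(path, encoding="utf-8")
        missing = [c for c in TABLE_SCHEMAS[name] if c not in frame.columns]
        if missing and not (name == "disease_rules" and frame.empty):
            errors.append(f"{path}: missing columns {missing}")
            continue
        value_col = _NON_NEGATIVE.get(name)
        if value_col and value_col in frame.columns:
            bad = frame.index[frame[value_col] < 0]
            for row in bad:
                errors.append(
                    f"{path}: row {row + 2} has negative {value_col} "
                    f"({frame.loc[row, value_col]})"
                )
        frames[name] = frame
    if errors:
        raise ValidationError(errors)
    return FoodTables(
        recipes=frames["recipes"],
        composition=frames["composition"],
        disease_rules=frames["disease_rules"],
        guidelines=frames["guidelines"],
        categories=frames["categories"],
    )


def save_tables(tables: FoodTables, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name in ("recipes", "composition", "disease_rules", "guidelines", "categories"):
        path = outdir / f"{name}.csv"
        getattr(tables, name).to_csv(path, index=False, encoding="utf-8")
        written[name] = path
    return written


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end pipeline settings; round-trips losslessly through YAML."""

    kg_path: str = "foodkg.json"
    profiles_path: str = "cohort.json"
    seed: int = 0
    lunch_fraction: float = 0.40
    dedup_threshold: float = 0.85
    tracked_threshold: int = 5
    n_options: int = 5
    days: int = 30
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0 < self.dedup_threshold <= 1:
            raise ValueError("dedup_threshold outside (0, 1]")
        if not 0 < self.lunch_fraction < 1:
            raise ValueError("lunch_fraction outside (0, 1)")
        for name in ("tracked_threshold", "n_options", "days"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            config = cls(**(yaml.safe_load(fh) or {}))
        config.validate()
        return config


def provenance(seed: int, config: dict | None = None) -> dict:
    payload = json.dumps(config or {}, sort_keys=True).encode()
    return {
        "seed": seed,
        "config_sha256": hashlib.sha256(payload).hexdigest(),
        "package_version": __version__,
    }


# ---------------------------------------------------------------------------
# report export
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "group", "indicator", "autonomous_mean", "autonomous_sd",
    "recommended_mean", "recommended_sd", "t", "df", "p",
]
SERIES_COLUMNS = ["group", "day", "indicator", "mean", "ci_low", "ci_high", "n"]


def export_report(
    comparison: pd.DataFrame,
    series: pd.DataFrame,
    out_prefix: str | Path,
    seed: int = 0,
    config: dict | None = None,
) -> dict[str, Path]:
    """Write the comparison table and per-day series as CSV plus one JSON.

    Column order is stable (group, indicator, autonomous mean/SD,
    recommended mean/SD, t, df, p); empty inputs yield header-only files.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    comparison = comparison.reindex(columns=REPORT_COLUMNS)
    series = series.reindex(columns=SERIES_COLUMNS)
    report_csv = out_prefix.with_suffix(".report.csv")
    series_csv = out_prefix.with_suffix(".series.csv")
    report_json = out_prefix.with_suffix(".report.json")
    comparison.to_csv(report_csv, index=False, encoding="utf-8")
    series.to_csv(series_csv, index=False, encoding="utf-8")
    with open(report_json, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "provenance": provenance(seed, config),
                "comparison": comparison.to_dict(orient="records"),
                "series": series.to_dict(orient="records"),
            },
            fh,
            ensure_ascii=False,
            indent=1,
        )
    return {"report_csv": report_csv, "series_csv": series_csv, "report_json": report_json}


# ---------------------------------------------------------------------------
# history log (one JSON record per user-day selection)
# ---------------------------------------------------------------------------


def save_history(users, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for user in users:
            for day, combo in user.history:
                fh.write(
                    json.dumps(
                        {"user_id": user.id, "day": day, "dishes": list(combo)},
                        ensure_ascii=False,
                    )
                    + "\n"
                )


def load_history(path: str | Path) -> dict[str, list[tuple[int, tuple[str, ...]]]]:
    histories: dict[str, list[tuple[int, tuple[str, ...]]]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            doc = json.loads(line)
            histories.setdefault(doc["user_id"], []).append(
                (int(doc["day"]), tuple(doc["dishes"]))
            )
    for records in histories.values():
        records.sort(key=lambda item: item[0])
    return histories
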