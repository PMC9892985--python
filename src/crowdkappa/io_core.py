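"""Long-format rating tables: the pipeline's universal currency.

One row per (rater, image, feature) holding a binary present/absent choice,
an optional reaction time in seconds, and a cohort tag (``panel`` for the
initial expert panel, ``crowd`` for the nonexpert crowd, ``expert_crowd``
for the expert crowd that replicated the crowd protocol).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .taxonomy import FeatureTaxonomy, canonical_name

SCHEMA_VERSION = 1

COHORTS = ("panel", "crowd", "expert_crowd")

COLUMNS = ["rater_id", "image_id", "feature", "present", "reaction_time_s", "cohort"]


@dataclass
class RatingTable:
    """Validated long-format annotation table.

    Attributes
    ----------
    df : pandas.DataFrame
        Columns ``rater_id, image_id, feature, present, reaction_time_s,
        cohort``.  ``present`` is 0/1; ``reaction_time_s`` is > 0 or NaN.
    level : str
        ``"subfeature"`` or ``"superfeature"`` — the level of the
        ``feature`` column.
    """

    df: pd.DataFrame
    level: str

    def __post_init__(self):
        if self.level not in ("subfeature", "superfeature"):
            raise ValidationError(f"invalid level: {self.level!r}")
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"rating table missing columns: {missing}")
        self.df = self.df[COLUMNS]

    def __len__(self) -> int:
        return len(self.df)

    @property
    def features(self) -> list[str]:
        return sorted(self.df["feature"].unique())

    @property
    def raters(self) -> list[str]:
        return sorted(self.df["rater_id"].unique())

    def subset(self, feature: str | None = None, cohort: str | None = None) -> "RatingTable":
        df = self.df
        if feature is not None:
            df = df[df["feature"] == canonical_name(feature)]
        if cohort is not None:
            df = df[df["cohort"] == cohort]
        return RatingTable(df=df.reset_index(drop=True), level=self.level)

    def sorted(self) -> "RatingTable":
        df = self.df.sort_values(["rater_id", "image_id", "feature"], kind="mergesort")
        return RatingTable(df=df.reset_index(drop=True), level=self.level)


def _detect_level(features, taxonomy: FeatureTaxonomy) -> str:
    subs = [f for f in features if taxonomy.is_subfeature(f)]
    sups = [f for f in features if taxonomy.is_superfeature(f)]
    if len(subs) == len(features):
        return "subfeature"
    if len(sups) == len(features):
        return "superfeature"
    unknown = [f for f in features if not (taxonomy.is_subfeature(f) or taxonomy.is_superfeature(f))]
    if unknown:
        raise ValidationError(f"unknown feature name: {unknown[0]!r}")
    raise ValidationError(
        "mixed subfeature- and superfeature-level names in one table"
    )


def validate_ratings(
    df: pd.DataFrame, taxonomy: FeatureTaxonomy | None = None, level: str | None = None
) -> RatingTable:
    """Validate a raw ratings frame and wrap it in a :class:`RatingTable`.

    Checks the schema, the 0/1 domain of ``present``, positivity of reaction
    times, cohort tags (missing cohort defaults to ``crowd`` with a warning),
    uniqueness of (rater, image, feature), and — when a taxonomy is given —
    that all feature names are valid at one single level.
    """
    df = df.copy()
    if "reaction_time_s" not in df.columns:
        df["reaction_time_s"] = np.nan
    if "cohort" not in df.columns:
        df["cohort"] = np.nan
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"ratings missing required columns: {missing}")

    df["rater_id"] = df["rater_id"].astype(str)
    df["image_id"] = df["image_id"].astype(str)
    df["feature"] = df["feature"].map(canonical_name)

    present = pd.to_numeric(df["present"], errors="coerce")
    bad = df[~present.isin([0, 1])]
    if len(bad):
        row = bad.iloc[0]
        raise ValidationError(
            f"present must be 0 or 1; got {row['present']!r} for "
            f"({row['rater_id']}, {row['image_id']}, {row['feature']})"
        )
    df["present"] = present.astype(np.int8)

    rt = pd.to_numeric(df["reaction_time_s"], errors="coerce")
    if (rt <= 0).any():
        row = df[rt <= 0].iloc[0]
        raise ValidationError(
            f"reaction_time_s must be > 0 when given; got "
            f"{row['reaction_time_s']!r} for ({row['rater_id']}, "
            f"{row['image_id']}, {row['feature']})"
        )
    df["reaction_time_s"] = rt.astype(float)

    df["cohort"] = df["cohort"].astype("object")
    blank = df["cohort"].isna() | (df["cohort"].astype(str).str.strip() == "")
    if blank.any():
        warnings.warn(
            f"{int(blank.sum())} ratings have no cohort tag; defaulting to 'crowd'",
            stacklevel=2,
        )
        df.loc[blank, "cohort"] = "crowd"
    df["cohort"] = df["cohort"].astype(str)
    bad_cohort = ~df["cohort"].isin(COHORTS)
    if bad_cohort.any():
        raise ValidationError(
            f"unknown cohort {df.loc[bad_cohort, 'cohort'].iloc[0]!r}; "
            f"expected one of {COHORTS}"
        )

    dupes = df.duplicated(["rater_id", "image_id", "feature"], keep=False)
    if dupes.any():
        row = df[dupes].iloc[0]
        raise ValidationError(
            "duplicate rating for (rater, image, feature) = "
            f"({row['rater_id']}, {row['image_id']}, {row['feature']})"
        )

    if taxonomy is not None:
        detected = _detect_level(df["feature"].unique(), taxonomy)
        if level is not None and level != detected:
            raise ValidationError(
                f"declared level {level!r} but features are at {detected!r} level"
            )
        level = detected
    elif level is None:
        level = "superfeature"

    return RatingTable(df=df.reset_index(drop=True), level=level)


def read_ratings(path: str | Path, taxonomy: FeatureTaxonomy | None = None) -> RatingTable:
    """Read a ratings CSV (schema: ``rater_id,image_id,feature,present,
    reaction_time_s,cohort``) and validate it against ``taxonomy``.

    With ``taxonomy=None`` the bundled default taxonomy is used.  Lines
    starting with ``#`` (schema-version banner) are ignored.
    """
    if taxonomy is None:
        from .taxonomy import load_taxonomy

        taxonomy = load_taxonomy()
    df = pd.read_csv(path, comment="#", dtype={"rater_id": str, "image_id": str})
    return validate_ratings(df, taxonomy=taxonomy)


def write_ratings(table: RatingTable, path: str | Path) -> None:
    """Write a ratings CSV, byte-stable (sorted by rater, image, feature)."""
    out = table.sorted().df.copy()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# schema_version: {SCHEMA_VERSION}\n")
        out.to_csv(fh, index=False, lineterminator="\n")


def total_ratings(per_feature_totals: Mapping[str, int]) -> int:
    """Grand total of ratings as the sum of per-feature totals."""
    return int(sum(int(v) for v in per_feature_totals.values()))


def percentage(numerator: int, denominator: int, digits: int = 1) -> float:
    """Percentage of ``numerator/denominator`` rounded to ``digits`` places."""
    if denominator <= 0:
        raise ValidationError("denominator must be positive")
    return round(100.0 * numerator / denominator, digits)


def summarize_dataset(table: RatingTable) -> dict:
    """Per-feature rating counts, user counts and per-user medians.

    Returns a dict with per-feature totals, distinct-user counts, the median
    number of ratings per user per feature, and the grand total (which by
    construction equals the sum of the per-feature totals).
    """
    if len(table) == 0:
        raise ValidationError("cannot summarize an empty rating table")
    df = table.df
    per_feature: dict[str, dict] = {}
    for feat, g in df.groupby("feature", sort=True):
        counts = g.groupby("rater_id").size()
        per_feature[feat] = {
            "n_ratings": int(len(g)),
            "n_users": int(counts.size),
            "median_ratings_per_user": float(counts.median()),
        }
    totals = {f: d["n_ratings"] for f, d in per_feature.items()}
    return {
        "schema_version": SCHEMA_VERSION,
        "per_feature": per_feature,
        "grand_total": total_ratings(totals),
        "n_users_total": int(df["rater_id"].nunique()),
        "n_images": int(df["image_id"].nunique()),
    }
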