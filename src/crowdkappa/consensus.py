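"""Consensus gold standards, crowd qualification, and the thresholded reader.

Gold-standard construction follows the panel vote rule: a superfeature is
*present* on an image when at least ``present_min`` (default 3) of the
panel's raters marked it present, *absent* when none did, and a *test*
image otherwise (1–2 votes) — test images carry no gold label and are the
genuinely ambiguous ones.

Crowd users qualify for analysis by scoring at least a threshold fraction
(default 83%) of correct answers on validation gold items; unqualified
users' ratings are dropped from all downstream statistics.

The thresholded consensus reader condenses the five selected expert-crowd
raters into a single synthetic rater whose label is present iff at least 3
of the 5 marked present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .errors import ConfigError, ValidationError
from .io_core import RatingTable


@dataclass(frozen=True)
class ConsensusConfig:
    """Vote thresholds and qualification parameters."""

    present_min: int = 3
    panel_size: int = 5
    qualification_threshold: float = 0.83
    validation_fraction: float = 0.5

    def validate(self) -> None:
        if not 0 < self.present_min <= self.panel_size:
            raise ConfigError("present_min must be in (0, panel_size]")
        if not 0 < self.qualification_threshold <= 1:
            raise ConfigError("qualification_threshold must be in (0, 1]")
        if not 0 < self.validation_fraction <= 1:
            raise ConfigError("validation_fraction must be in (0, 1]")


@dataclass(frozen=True)
class GoldStandardLabel:
    """Consensus status of one (image, superfeature) pair."""

    image_id: str
    superfeature: str
    status: str  # present | absent | test
    n_present_votes: int
    n_panel: int


GOLD_COLUMNS = ["image_id", "superfeature", "status", "n_present_votes", "n_panel"]


def vote_status(n_present: int, present_min: int) -> str:
    """Consensus status from a vote count: ≥present_min → present,
    0 → absent, otherwise test."""
    if n_present >= present_min:
        return "present"
    if n_present == 0:
        return "absent"
    return "test"


def build_gold_standard(
    panel_ratings: RatingTable, config: ConsensusConfig | None = None
) -> pd.DataFrame:
    """Build per-(image, superfeature) consensus labels from panel votes.

    Returns a DataFrame with columns ``image_id, superfeature, status,
    n_present_votes, n_panel``; exactly one row per (image, superfeature)
    with at least one panel rating.
    """
    config = config or ConsensusConfig()
    config.validate()
    if panel_ratings.level != "superfeature":
        raise ValidationError("gold standard requires superfeature-level ratings")
    df = panel_ratings.df
    if len(df) == 0:
        raise ValidationError("no panel ratings supplied")
    grouped = df.groupby(["image_id", "feature"], sort=True).agg(
        n_present_votes=("present", "sum"), n_panel=("present", "size")
    )
    short = grouped[grouped["n_panel"] < config.panel_size]
    if len(short):
        warnings.warn(
            f"{len(short)} (image, superfeature) pairs have fewer than "
            f"{config.panel_size} panel ratings",
            stacklevel=2,
        )
    gold = grouped.reset_index().rename(columns={"feature": "superfeature"})
    gold["status"] = [
        vote_status(int(v), config.present_min) for v in gold["n_present_votes"]
    ]
    return gold[GOLD_COLUMNS]


def gold_labels(gold: pd.DataFrame) -> list[GoldStandardLabel]:
    """View a gold-standard frame as typed label records."""
    return [
        GoldStandardLabel(
            image_id=row.image_id,
            superfeature=row.superfeature,
            status=row.status,
            n_present_votes=int(row.n_present_votes),
            n_panel=int(row.n_panel),
        )
        for row in gold.itertuples()
    ]


def split_gold_validation(
    gold: pd.DataFrame, validation_fraction: float, seed: int
) -> pd.DataFrame:
    """Assign labelled gold items to training vs validation roles.

    The split is seeded and stratified by (superfeature, status) over the
    items with status present/absent; test items receive role ``none``.
    Returns the gold frame with an added ``role`` column.
    """
    gold = gold.copy()
    gold["role"] = "none"
    rng = np.random.default_rng(derive_seed(seed, "gold_split"))
    labelled = gold[gold["status"].isin(["present", "absent"])]
    for (_, _), idx in labelled.groupby(["superfeature", "status"]).groups.items():
        idx = np.array(sorted(idx))
        perm = rng.permutation(idx.size)
        n_val = max(1, int(round(validation_fraction * idx.size)))
        val_idx = idx[perm[:n_val]]
        train_idx = idx[perm[n_val:]]
        gold.loc[val_idx, "role"] = "validation"
        gold.loc[train_idx, "role"] = "training"
    return gold


def is_qualified(n_correct: int, n_total: int, threshold: float) -> bool:
    """Qualification predicate: at least ``threshold`` correct on
    validation items, requiring at least one rated validation item."""
    if n_total <= 0:
        return False
    return n_correct / n_total >= threshold


def qualify_users(
    crowd_ratings: RatingTable,
    gold: pd.DataFrame,
    config: ConsensusConfig | None = None,
    seed: int = 0,
) -> tuple[dict[str, frozenset[str]], pd.DataFrame]:
    """Qualify crowd users against validation gold items, per task.

    Labelled gold items are split (seeded, stratified) into training and
    validation subsets; each user's correctness is the fraction of their
    validation-item ratings matching the gold status.  Users at or above
    the threshold qualify; users with no rated validation items do not.

    Returns ``(qualified, table)`` where ``qualified`` maps superfeature →
    frozenset of qualified user ids and ``table`` has one row per
    (user, superfeature) with ``n_validation, n_correct, accuracy,
    qualified``.
    """
    config = config or ConsensusConfig()
    config.validate()
    if len(gold) == 0:
        raise ValidationError("empty gold standard")
    features = sorted(crowd_ratings.df["feature"].unique())
    gold_features = set(gold["superfeature"].unique())
    missing = [f for f in features if f not in gold_features]
    if missing:
        raise ValidationError(
            f"no gold labels for feature {missing[0]!r} present in ratings"
        )

    split = split_gold_validation(gold, config.validation_fraction, seed)
    rows = []
    qualified: dict[str, frozenset[str]] = {}
    for f in features:
        gf = split[(split["superfeature"] == f) & (split["role"] == "validation")]
        statuses = set(
            split[(split["superfeature"] == f) & (split["status"].isin(["present", "absent"]))][
                "status"
            ]
        )
        if not {"present", "absent"} <= statuses:
            raise ValidationError(
                f"gold for feature {f!r} must contain both present and absent items"
            )
        truth = gf.set_index("image_id")["status"].map({"present": 1, "absent": 0})
        ratings_f = crowd_ratings.df[crowd_ratings.df["feature"] == f]
        merged = ratings_f.merge(
            truth.rename("gold"), left_on="image_id", right_index=True, how="inner"
        )
        per_user = merged.assign(correct=(merged["present"] == merged["gold"]).astype(int))
        stats = per_user.groupby("rater_id").agg(
            n_validation=("correct", "size"), n_correct=("correct", "sum")
        )
        all_users = sorted(ratings_f["rater_id"].unique())
        stats = stats.reindex(all_users, fill_value=0)
        ok = set()
        for user, row in stats.iterrows():
            n_val, n_cor = int(row["n_validation"]), int(row["n_correct"])
            q = is_qualified(n_cor, n_val, config.qualification_threshold)
            acc = n_cor / n_val if n_val else float("nan")
            rows.append((user, f, n_val, n_cor, acc, q))
            if q:
                ok.add(user)
        qualified[f] = frozenset(ok)

    table = pd.DataFrame(
        rows,
        columns=["rater_id", "superfeature", "n_validation", "n_correct", "accuracy", "qualified"],
    ).sort_values(["superfeature", "rater_id"], kind="mergesort").reset_index(drop=True)
    return qualified, table


def select_completers(
    ratings: RatingTable, feature: str, n: int = 5, raters: list[str] | None = None
) -> list[str]:
    """Select the raters standing in for the "first n completers".

    Completion timestamps are usually absent from exports, so the default
    proxy is the ``n`` raters with the most rated images for the feature,
    ties broken by rater-id order; an explicit list overrides the proxy.
    """
    if raters is not None:
        if len(raters) != n:
            raise ValidationError(f"expected exactly {n} raters, got {len(raters)}")
        return list(raters)
    df = ratings.df[ratings.df["feature"] == feature]
    counts = df.groupby("rater_id").size().sort_index()
    if counts.size < n:
        raise ValidationError(
            f"only {counts.size} raters available for feature {feature!r}; need {n}"
        )
    order = counts.sort_values(ascending=False, kind="mergesort")
    return sorted(order.index[:n])


def thresholded_consensus_reader(
    expert_crowd_ratings: RatingTable,
    min_present: int = 3,
    n_raters: int = 5,
    raters: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Condense the expert crowd into a single thresholded consensus reader.

    For each superfeature, the ``n_raters`` selected raters (see
    :func:`select_completers`) vote; an image rated by all of them gets the
    label present iff at least ``min_present`` marked present.  Images rated
    by fewer than ``n_raters`` of the selected raters are excluded with a
    warning.

    Returns a DataFrame ``image_id, superfeature, present``.
    """
    if not 0 < min_present <= n_raters:
        raise ConfigError("min_present must be in (0, n_raters]")
    out = []
    for f in sorted(expert_crowd_ratings.df["feature"].unique()):
        chosen = select_completers(
            expert_crowd_ratings, f, n=n_raters, raters=(raters or {}).get(f)
        )
        df = expert_crowd_ratings.df
        df = df[(df["feature"] == f) & (df["rater_id"].isin(chosen))]
        votes = df.groupby("image_id").agg(
            n_present=("present", "sum"), n_raters=("present", "size")
        )
        incomplete = votes[votes["n_raters"] < n_raters]
        if len(incomplete):
            warnings.warn(
                f"{len(incomplete)} images excluded for feature {f!r}: rated by "
                f"fewer than {n_raters} selected raters",
                stacklevel=2,
            )
        votes = votes[votes["n_raters"] == n_raters]
        for image_id, row in votes.iterrows():
            out.append((image_id, f, int(row["n_present"] >= min_present)))
    return pd.DataFrame(out, columns=["image_id", "superfeature", "present"]).sort_values(
        ["superfeature", "image_id"], kind="mergesort"
    ).reset_index(drop=True)
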