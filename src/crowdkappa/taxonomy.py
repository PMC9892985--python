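"""Dermoscopic feature vocabulary and the subfeature-to-superfeature collapse.

The 2016 International Dermoscopy Society consensus describes 31 fine-grained
"subfeatures" of melanocytic lesions grouped into 9 structural "superfeatures"
(dots, globules, lines, network structures, regression structures, shiny white
structures, patterns, structureless areas, vessels).  Because inter-rater
reliability at the subfeature level is poor, downstream analyses operate at the
superfeature level: a rater is taken to have marked a superfeature present on
an image iff they marked at least one of its constituent subfeatures present
(a logical OR).  Six superfeatures are "active" — carried into the crowd
studies — the remaining three having too few exemplars and too little
agreement to evaluate.

Feature names are matched case-insensitively after whitespace normalisation;
original casing is retained for display.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

from .errors import ValidationError

_DEFAULT_RESOURCE = "consensus_taxonomy.json"

_WS = re.compile(r"\s+")


def canonical_name(name: str) -> str:
    """Canonical matching form of a feature name.

    Lower-cased, leading/trailing punctuation and whitespace stripped,
    internal whitespace collapsed to single spaces.
    """
    s = _WS.sub(" ", str(name)).strip().strip(".,;:").strip()
    return s.lower()


@dataclass(frozen=True)
class FeatureTaxonomy:
    """Subfeature → superfeature map.

    Attributes
    ----------
    superfeatures : tuple of str
        Canonical superfeature names, in display order.
    mapping : Mapping[str, str]
        Canonical subfeature name → canonical superfeature name. Every
        subfeature maps to exactly one superfeature.
    active_superfeatures : tuple of str
        The subset of superfeatures carried into downstream analyses.
    display : Mapping[str, str]
        Canonical name → original display name (both levels).
    """

    superfeatures: tuple[str, ...]
    mapping: Mapping[str, str]
    active_superfeatures: tuple[str, ...]
    display: Mapping[str, str] = field(default_factory=dict)

    @property
    def subfeatures(self) -> tuple[str, ...]:
        return tuple(self.mapping.keys())

    @property
    def n_subfeatures(self) -> int:
        return len(self.mapping)

    @property
    def n_superfeatures(self) -> int:
        return len(self.superfeatures)

    def superfeature_of(self, subfeature: str) -> str:
        key = canonical_name(subfeature)
        try:
            return self.mapping[key]
        except KeyError:
            raise ValidationError(f"unknown subfeature: {subfeature!r}") from None

    def is_superfeature(self, name: str) -> bool:
        return canonical_name(name) in self.superfeatures

    def is_subfeature(self, name: str) -> bool:
        return canonical_name(name) in self.mapping

    def display_name(self, name: str) -> str:
        key = canonical_name(name)
        return self.display.get(key, name)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "FeatureTaxonomy":
        """Build and validate a taxonomy from the JSON dialect.

        Expected layout::

            {"superfeatures": [...],
             "mapping": {superfeature: [subfeature, ...], ...},
             "active": [...]}
        """
        for key in ("superfeatures", "mapping"):
            if key not in raw:
                raise ValidationError(f"taxonomy file missing key {key!r}")

        display: dict[str, str] = {}
        supers: list[str] = []
        for name in raw["superfeatures"]:
            c = canonical_name(name)
            if c in supers:
                raise ValidationError(f"duplicate superfeature: {name!r}")
            supers.append(c)
            display[c] = str(name)

        mapping: dict[str, str] = {}
        for sup, subs in raw["mapping"].items():
            c_sup = canonical_name(sup)
            if c_sup not in supers:
                raise ValidationError(
                    f"mapping refers to unknown superfeature: {sup!r}"
                )
            for sub in subs:
                c_sub = canonical_name(sub)
                if c_sub in mapping:
                    raise ValidationError(
                        f"subfeature {sub!r} mapped to more than one "
                        f"superfeature ({display.get(mapping[c_sub], mapping[c_sub])!r}"
                        f" and {sup!r})"
                    )
                mapping[c_sub] = c_sup
                display[c_sub] = str(sub)

        active_raw = raw.get("active", raw["superfeatures"])
        active: list[str] = []
        for name in active_raw:
            c = canonical_name(name)
            if c not in supers:
                raise ValidationError(f"active superfeature not defined: {name!r}")
            if c not in active:
                active.append(c)

        return cls(
            superfeatures=tuple(supers),
            mapping=mapping,
            active_superfeatures=tuple(active),
            display=display,
        )


def load_taxonomy(path: str | Path | None = None) -> FeatureTaxonomy:
    """Load a taxonomy JSON file; with no path, the bundled default.

    The bundled default reproduces the consensus vocabulary: 31 subfeatures
    under 9 superfeatures, with the 6 crowd-study superfeatures active.
    """
    if path is None:
        with resources.files("crowdkappa.data").joinpath(_DEFAULT_RESOURCE).open(
            "r", encoding="utf-8"
        ) as fh:
            raw = json.load(fh)
    else:
        with open(path, "r", encoding="utf-8") as fh:
            raw = json.load(fh)
    return FeatureTaxonomy.from_dict(raw)


def collapse_to_superfeatures(ratings, taxonomy: FeatureTaxonomy):
    """Collapse a subfeature-level rating table to superfeature level.

    For each (rater, image, superfeature), the collapsed rating is present
    iff the rater marked at least one constituent subfeature present.  A
    superfeature is rated iff at least one of its subfeatures was rated;
    reaction times are not propagated (the OR is not a timed event).

    Parameters
    ----------
    ratings : RatingTable
        Subfeature-level table.
    taxonomy : FeatureTaxonomy

    Returns
    -------
    RatingTable at superfeature level.
    """
    from .io_core import RatingTable  # local import avoids a cycle

    df = ratings.df.copy()
    if ratings.level == "superfeature":
        # already collapsed: the identity collapse is a no-op
        bad = [f for f in df["feature"].unique() if not taxonomy.is_superfeature(f)]
        if bad:
            raise ValidationError(f"unknown feature name: {bad[0]!r}")
        return RatingTable(df=df, level="superfeature")
    unknown = [f for f in df["feature"].unique() if not taxonomy.is_subfeature(f)]
    if unknown:
        raise ValidationError(f"unknown subfeature name: {unknown[0]!r}")

    df["feature"] = df["feature"].map(
        lambda f: taxonomy.mapping[canonical_name(f)]
    )
    grouped = (
        df.groupby(["rater_id", "image_id", "feature"], sort=True, as_index=False)
        .agg(present=("present", "max"), cohort=("cohort", "first"))
    )
    grouped["reaction_time_s"] = float("nan")
    grouped = grouped[
        ["rater_id", "image_id", "feature", "present", "reaction_time_s", "cohort"]
    ]
    return RatingTable(df=grouped.reset_index(drop=True), level="superfeature")
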