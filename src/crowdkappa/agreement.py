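"""Pairwise Cohen κ under overlap constraints, with median summaries.

Cohen κ corrects two raters' observed agreement for the agreement expected
from their own marginal label frequencies: ``κ = (p_o − p_e)/(1 − p_e)``.
It is 0 for completely random choices and 1 for perfect agreement.  Values
are interpreted as poor (0–0.4), fair to good (0.4–0.75), and excellent
(0.75–1.0); the median of κ over all evaluated rater pairs summarises a
cohort, since pairwise κ values are not normally distributed.

With sparse, partially overlapping raters (a crowd), a pair is evaluated
only if both raters saw at least ``min_overlap`` of the same images
(default 62, one substudy block).  Pairs in which both raters used only a
single, identical label have ``p_e = 1``; their κ is undefined and they are
flagged degenerate and excluded from medians rather than scored.

All κ arithmetic is done on the integer 2×2 cell counts, so book examples
evaluate exactly (e.g. cells 40/5/10/45 give κ = 0.70 with no rounding).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_core import RatingTable

KAPPA_BANDS = (("poor", 0.4), ("fair-good", 0.75), ("excellent", 1.0))


@dataclass(frozen=True)
class AgreementConfig:
    """Overlap constraint and interpretation bands."""

    min_overlap: int = 62

    def validate(self) -> None:
        if self.min_overlap < 2:
            raise ValidationError("min_overlap must be >= 2")


@dataclass(frozen=True)
class KappaResult:
    """One rater pair's agreement statistics."""

    rater_a: str
    rater_b: str
    superfeature: str | None
    n_overlap: int
    p_o: float
    p_e: float
    kappa: float | None
    degenerate: bool
    category: str


def interpret_kappa(kappa: float) -> str:
    """Interpretation band: poor (< 0.4, incl. negative), fair-good
    (0.4 ≤ κ < 0.75), excellent (κ ≥ 0.75)."""
    if not np.isfinite(kappa):
        raise ValidationError("kappa must be finite")
    if kappa < 0.4:
        return "poor"
    if kappa < 0.75:
        return "fair-good"
    return "excellent"


def kappa_from_counts(
    n11: int, n10: int, n01: int, n00: int
) -> tuple[float, float, float | None, bool]:
    """(p_o, p_e, κ, degenerate) from 2×2 cell counts.

    ``n11`` both present, ``n10`` a-only, ``n01`` b-only, ``n00`` both
    absent.  κ is computed as a ratio of integers, ``(n·agree − pe_num) /
    (n² − pe_num)``, so exact cell counts give exact κ.
    """
    n11, n10, n01, n00 = int(n11), int(n10), int(n01), int(n00)
    n = n11 + n10 + n01 + n00
    if n < 2:
        raise ValidationError(f"need at least 2 shared items; got {n}")
    agree = n11 + n00
    a_pres, b_pres = n11 + n10, n11 + n01
    pe_num = a_pres * b_pres + (n - a_pres) * (n - b_pres)  # scaled by n^2
    p_o = agree / n
    p_e = pe_num / (n * n)
    if pe_num == n * n:
        return p_o, p_e, None, True
    kappa = (n * agree - pe_num) / (n * n - pe_num)
    return p_o, p_e, kappa, False


def cohen_kappa(labels_a, labels_b) -> KappaResult:
    """Cohen κ between two equal-length binary label sequences.

    Observed agreement is the fraction of identical labels; expected
    agreement comes from each rater's own marginals.  Degenerate pairs
    (both raters constant with the same label, ``p_e = 1``) get
    ``kappa=None`` and category ``undefined``.
    """
    a = np.asarray(labels_a).astype(int)
    b = np.asarray(labels_b).astype(int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("label sequences must be 1-D and equal length")
    if a.size < 2:
        raise ValidationError("need at least 2 shared items")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValidationError("labels must be binary 0/1")
    n11 = int(np.sum((a == 1) & (b == 1)))
    n10 = int(np.sum((a == 1) & (b == 0)))
    n01 = int(np.sum((a == 0) & (b == 1)))
    n00 = int(np.sum((a == 0) & (b == 0)))
    p_o, p_e, kappa, degenerate = kappa_from_counts(n11, n10, n01, n00)
    category = "undefined" if degenerate else interpret_kappa(kappa)
    return KappaResult(
        rater_a="a",
        rater_b="b",
        superfeature=None,
        n_overlap=a.size,
        p_o=p_o,
        p_e=p_e,
        kappa=kappa,
        degenerate=degenerate,
        category=category,
    )


def pairwise_kappas(
    ratings: RatingTable,
    superfeature: str,
    config: AgreementConfig | None = None,
    cohort: str | None = None,
    raters: list[str] | None = None,
) -> list[KappaResult]:
    """κ for every unordered rater pair with sufficient image overlap.

    Pairs are enumerated once, ordered lexicographically by rater id, and
    emitted iff the raters share at least ``config.min_overlap`` images for
    the superfeature.  Degenerate pairs are emitted flagged.

    The 2×2 cell counts for all pairs are obtained by boolean matrix
    products over the rater × image incidence matrices.
    """
    config = config or AgreementConfig()
    config.validate()
    df = ratings.df
    df = df[df["feature"] == superfeature]
    if cohort is not None:
        df = df[df["cohort"] == cohort]
    if raters is not None:
        df = df[df["rater_id"].isin(raters)]
    rater_ids = sorted(df["rater_id"].unique())
    if len(rater_ids) < 2:
        warnings.warn(
            f"fewer than 2 raters for feature {superfeature!r}; no pairs",
            stacklevel=2,
        )
        return []
    pivot = df.pivot(index="rater_id", columns="image_id", values="present")
    pivot = pivot.loc[rater_ids]
    m = pivot.to_numpy(dtype=float)
    return pairwise_from_matrix(m, rater_ids, superfeature, config)


def pairwise_from_matrix(
    m: np.ndarray,
    rater_ids: list[str],
    superfeature: str | None,
    config: AgreementConfig | None = None,
) -> list[KappaResult]:
    """κ for all unordered rater pairs of a rater × image matrix.

    ``m`` holds 0/1 ratings with NaN for unrated images.  Cell counts for
    every pair come from boolean matrix products, so the cost is one
    matrix multiply per cell rather than a per-pair scan.
    """
    config = config or AgreementConfig()
    config.validate()
    rated = ~np.isnan(m)
    pres = (m == 1).astype(np.int64)
    absn = (m == 0).astype(np.int64)
    n11 = pres @ pres.T
    n10 = pres @ absn.T
    n01 = absn @ pres.T
    n00 = absn @ absn.T
    overlap = rated.astype(np.int64) @ rated.T.astype(np.int64)

    results = []
    for i in range(len(rater_ids)):
        for j in range(i + 1, len(rater_ids)):
            n = int(overlap[i, j])
            if n < config.min_overlap:
                continue
            p_o, p_e, kappa, degenerate = kappa_from_counts(
                n11[i, j], n10[i, j], n01[i, j], n00[i, j]
            )
            results.append(
                KappaResult(
                    rater_a=rater_ids[i],
                    rater_b=rater_ids[j],
                    superfeature=superfeature,
                    n_overlap=n,
                    p_o=p_o,
                    p_e=p_e,
                    kappa=kappa,
                    degenerate=degenerate,
                    category="undefined" if degenerate else interpret_kappa(kappa),
                )
            )
    return results


def median_kappa(results) -> float:
    """Median κ over non-degenerate results (even count: mean of the two
    middle values)."""
    values = [
        (r.kappa if isinstance(r, KappaResult) else float(r))
        for r in results
        if not (isinstance(r, KappaResult) and r.degenerate)
    ]
    if not values:
        raise ValidationError("no non-degenerate kappa values to summarise")
    return float(np.median(values))


def summarize_kappas(results: list[KappaResult]) -> dict:
    """Per-superfeature summary: pair count, median κ, band, quartiles."""
    values = [r.kappa for r in results if not r.degenerate]
    if not values:
        raise ValidationError("no non-degenerate kappa values to summarise")
    med = float(np.median(values))
    q1, q3 = (float(q) for q in np.percentile(values, [25, 75]))
    return {
        "n_pairs": len(results),
        "n_degenerate": sum(r.degenerate for r in results),
        "median_kappa": med,
        "category": interpret_kappa(med),
        "q1": q1,
        "q3": q3,
    }


def kappa_results_frame(results: list[KappaResult]) -> pd.DataFrame:
    """Flatten κ results to the CSV-facing frame."""
    return pd.DataFrame(
        [
            {
                "rater_a": r.rater_a,
                "rater_b": r.rater_b,
                "superfeature": r.superfeature,
                "n_overlap": r.n_overlap,
                "p_o": r.p_o,
                "p_e": r.p_e,
                "kappa": r.kappa,
                "degenerate": r.degenerate,
                "category": r.category,
            }
            for r in results
        ]
    )


def crowd_vs_consensus(
    crowd_ratings: RatingTable,
    consensus: pd.DataFrame,
    superfeature: str,
    config: AgreementConfig | None = None,
) -> tuple[list[KappaResult], float]:
    """κ of each crowd user against the thresholded consensus reader.

    The consensus reader (frame ``image_id, superfeature, present``) acts
    as rater_b for every user; users sharing fewer than ``min_overlap``
    images with the consensus are skipped with a warning.  Returns the
    per-user results and their median κ.
    """
    config = config or AgreementConfig()
    config.validate()
    cons = consensus[consensus["superfeature"] == superfeature]
    if len(cons) == 0:
        raise ValidationError(f"consensus has no labels for {superfeature!r}")
    cons_map = cons.set_index("image_id")["present"]
    df = crowd_ratings.df
    df = df[df["feature"] == superfeature]
    users = sorted(df["rater_id"].unique())
    if not users:
        raise ValidationError(f"no crowd users for feature {superfeature!r}")
    results = []
    skipped = 0
    for user in users:
        du = df[df["rater_id"] == user]
        merged = du.merge(
            cons_map.rename("consensus"), left_on="image_id", right_index=True, how="inner"
        )
        if len(merged) < config.min_overlap:
            skipped += 1
            continue
        p_o, p_e, kappa, degenerate = kappa_from_counts(
            int(((merged["present"] == 1) & (merged["consensus"] == 1)).sum()),
            int(((merged["present"] == 1) & (merged["consensus"] == 0)).sum()),
            int(((merged["present"] == 0) & (merged["consensus"] == 1)).sum()),
            int(((merged["present"] == 0) & (merged["consensus"] == 0)).sum()),
        )
        results.append(
            KappaResult(
                rater_a=user,
                rater_b="consensus",
                superfeature=superfeature,
                n_overlap=len(merged),
                p_o=p_o,
                p_e=p_e,
                kappa=kappa,
                degenerate=degenerate,
                category="undefined" if degenerate else interpret_kappa(kappa),
            )
        )
    if skipped:
        warnings.warn(
            f"{skipped} users below the {config.min_overlap}-image overlap "
            f"with the consensus for {superfeature!r} were skipped",
            stacklevel=2,
        )
    if not results:
        raise ValidationError(
            f"no users with sufficient consensus overlap for {superfeature!r}"
        )
    return results, median_kappa(results)
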