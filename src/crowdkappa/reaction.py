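"""Reaction-time transforms and the inverted-U difficulty regression.

Reaction times proxy decision difficulty: raters hesitate longest near the
across-readers point of indecision (average response ≈ 0.5) and answer
faster when the feature is clearly present.  Per-item averaged
``log(1 + RT)`` values are regressed on the item's average response and
its square by ordinary least squares; an inverted-U shows up as a negative
quadratic coefficient, and the presence speed-up as a negative linear
coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import ValidationError
from .io_core import RatingTable

_ZERO_COEF_ATOL = 1e-10


def log_rt(rt) -> np.ndarray | float:
    """Natural log of (1 + reaction time); errors on negative input."""
    arr = np.asarray(rt, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("reaction times must be >= 0")
    out = np.log1p(arr)
    return float(out) if np.isscalar(rt) or arr.ndim == 0 else out


@dataclass
class RTRegressionFit:
    """OLS fit of mean log RT on {1, t, t²}, t = average response − center.

    The default center is 0.5, the across-readers point of indecision, so
    the linear coefficient b1 is the present-minus-absent reaction-time
    contrast (negative = faster when the feature is present) and the
    quadratic coefficient b2 carries the inverted-U (negative = slower
    near indecision).  The fitted curve itself is parametrisation-free;
    :attr:`uncentered_coefficients` gives the exact {1, x, x²} form.
    """

    n_items: int
    params: np.ndarray  # b0, b1, b2 in the centered basis
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    df_resid: int
    center: float
    items: pd.DataFrame  # image_id, mean_log_rt, avg_response[, gold_status]

    @property
    def b0(self) -> float:
        return float(self.params[0])

    @property
    def b1(self) -> float:
        return float(self.params[1])

    @property
    def b2(self) -> float:
        return float(self.params[2])

    @property
    def uncentered_coefficients(self) -> tuple[float, float, float]:
        """Exact (a0, a1, a2) of the same parabola written as
        ``a0 + a1·x + a2·x²``."""
        c = self.center
        a2 = self.b2
        a1 = self.b1 - 2.0 * self.b2 * c
        a0 = self.b0 - self.b1 * c + self.b2 * c * c
        return a0, a1, a2

    @property
    def vertex(self) -> float:
        """Peak of the fitted parabola on the average-response scale."""
        if self.b2 == 0:
            raise ValidationError("vertex undefined for b2 = 0")
        return self.center - self.b1 / (2.0 * self.b2)

    def predict(self, x) -> np.ndarray:
        t = np.asarray(x, dtype=float) - self.center
        return self.b0 + self.b1 * t + self.b2 * t * t

    def to_dict(self) -> dict:
        a0, a1, a2 = self.uncentered_coefficients
        return {
            "n_items": self.n_items,
            "df_resid": self.df_resid,
            "center": self.center,
            "coefficients": {"b0": self.b0, "b1": self.b1, "b2": self.b2},
            "uncentered_coefficients": {"a0": a0, "a1": a1, "a2": a2},
            "bse": {k: float(v) for k, v in zip(("b0", "b1", "b2"), self.bse)},
            "t": {k: float(v) for k, v in zip(("b0", "b1", "b2"), self.tvalues)},
            "p": {k: float(v) for k, v in zip(("b0", "b1", "b2"), self.pvalues)},
        }


def item_rt_summary(
    ratings: RatingTable, superfeature: str, raters: list[str] | None = None
) -> pd.DataFrame:
    """Per-image mean log(1+RT) and average response for one superfeature.

    The average response is the proportion of raters answering present
    (over all ratings of the item); the RT mean is over timed ratings only.
    Items with no timed ratings are dropped with a warning.
    """
    df = ratings.df
    df = df[df["feature"] == superfeature]
    if raters is not None:
        df = df[df["rater_id"].isin(raters)]
    if len(df) == 0:
        raise ValidationError(f"no ratings for feature {superfeature!r}")
    timed = df.dropna(subset=["reaction_time_s"])
    if len(timed) == 0:
        raise ValidationError(f"no timed ratings for feature {superfeature!r}")
    resp = df.groupby("image_id")["present"].mean().rename("avg_response")
    rt = (
        timed.assign(log_rt=log_rt(timed["reaction_time_s"].to_numpy()))
        .groupby("image_id")["log_rt"]
        .mean()
        .rename("mean_log_rt")
    )
    out = pd.concat([rt, resp], axis=1, join="outer").reset_index()
    dropped = out["mean_log_rt"].isna()
    if dropped.any():
        warnings.warn(
            f"{int(dropped.sum())} items without timed ratings dropped for "
            f"{superfeature!r}",
            stacklevel=2,
        )
        out = out[~dropped]
    return out.sort_values("image_id", kind="mergesort").reset_index(drop=True)


def rt_quadratic_fit(
    items: pd.DataFrame, weighted: bool = False, center: float = 0.5
) -> RTRegressionFit:
    """OLS of mean log RT on {1, t, t²} with t = average response − center.

    The default ``center=0.5`` anchors the linear term at the point of
    indecision (see :class:`RTRegressionFit`); ``center=0`` gives the raw
    {1, x, x²} regression.  Reports coefficients, standard errors,
    t-values (coefficient / SE) and two-tailed p-values against the t
    distribution with ``n_items − 3`` residual degrees of freedom.  With
    ``weighted=True``, items are weighted by their rater count (column
    ``n_raters``); the default is unweighted.

    Zero-residual (exactly interpolated) fits yield SE = 0; their t-values
    are reported as 0 for zero coefficients and ±inf otherwise.
    """
    if not {"mean_log_rt", "avg_response"} <= set(items.columns):
        raise ValidationError("items frame needs mean_log_rt and avg_response")
    x = items["avg_response"].to_numpy(dtype=float)
    y = items["mean_log_rt"].to_numpy(dtype=float)
    n = x.size
    if n < 4:
        raise ValidationError(f"need at least 4 items; got {n}")
    if np.unique(x).size < 3:
        raise ValidationError(
            "rank-deficient design: need at least 3 distinct average responses"
        )
    t = x - center
    X = np.column_stack([np.ones(n), t, t * t])
    if weighted:
        if "n_raters" not in items.columns:
            raise ValidationError("weighted fit requires an n_raters column")
        w = items["n_raters"].to_numpy(dtype=float)
        model = sm.WLS(y, X, weights=w)
    else:
        model = sm.OLS(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = model.fit()
        params = np.asarray(res.params)
        bse = np.asarray(res.bse)
        df_resid = int(res.df_resid)
        tvals = np.empty(3)
        pvals = np.empty(3)
        for k in range(3):
            if abs(params[k]) <= _ZERO_COEF_ATOL and bse[k] <= _ZERO_COEF_ATOL:
                # exactly interpolated null coefficient (e.g. constant y)
                tvals[k], pvals[k] = 0.0, 1.0
            elif bse[k] == 0 or not np.isfinite(bse[k]):
                tvals[k] = np.inf * np.sign(params[k])
                pvals[k] = 0.0
            else:
                tvals[k] = params[k] / bse[k]
                pvals[k] = 2.0 * sps.t.sf(abs(tvals[k]), df_resid)
    return RTRegressionFit(
        n_items=n,
        params=params,
        bse=bse,
        tvalues=tvals,
        pvalues=pvals,
        df_resid=df_resid,
        center=center,
        items=items.reset_index(drop=True),
    )


def rt_variability_summary(ratings: RatingTable) -> dict:
    """Across-user vs within-user reaction-time spread, in raw seconds.

    Across: IQR of per-user median RT.  Within: IQR of per-rating
    deviations from the user's own median.  Returns both IQRs, their
    quartile endpoints, and whether within-user spread exceeds across-user
    spread (the qualitative pattern expected of engaged raters whose
    hesitation varies image by image).
    """
    timed = ratings.df.dropna(subset=["reaction_time_s"])
    users = timed.groupby("rater_id")["reaction_time_s"]
    sizes = users.size()
    if (sizes >= 2).sum() < 2:
        raise ValidationError("need >= 2 users with >= 2 timed ratings each")
    medians = users.median()
    q1a, q3a = np.percentile(medians.to_numpy(), [25, 75])
    deviations = timed["reaction_time_s"] - timed["rater_id"].map(medians)
    q1w, q3w = np.percentile(deviations.to_numpy(), [25, 75])
    return {
        "across_user_iqr": float(q3a - q1a),
        "across_user_quartiles": (float(q1a), float(q3a)),
        "within_user_iqr": float(q3w - q1w),
        "within_user_quartiles": (float(q1w), float(q3w)),
        "within_exceeds_across": bool((q3w - q1w) > (q3a - q1a)),
        "n_users": int(sizes.size),
        "n_timed_ratings": int(len(timed)),
    }
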