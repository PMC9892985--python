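"""Synthetic three-study rater simulator.

Generates datasets with the statistical structure the agreement analysis
assumes, so every downstream stage is testable without any data download:

* a latent binary truth ``z_if`` per (image, superfeature), drawn with
  per-feature prevalence;
* per-(image, superfeature) difficulty ``δ ∈ [0, 1)`` that shrinks every
  rater toward chance;
* rater ability ``a ∈ [0.5, 1]``; a rater answers correctly with
  probability ``q = 0.5 + (1 − δ)(a − 0.5)``, so a = 1 on an easy image is
  always right and a = 0.5 is a coin flip regardless of difficulty;
* study 1: a panel of experts split into non-overlapping substudies, each
  expert rating every image of their block, giving a fixed number of panel
  ratings per image;
* study 2: a crowd per superfeature task with highly variable per-user
  rating counts (log-normal, truncated) over random image subsets, with
  reaction times;
* study 3: a small expert crowd rating every image of every task, with
  reaction times.

Reaction times follow a log-linear model: ``log(1 + RT) = α_j +
β_U·4p(1−p) − β_P·z + ε`` where ``p`` is the model-expected proportion of
the cohort answering "present" for the item.  The ``4p(1−p)`` term peaks at
the point of indecision (p = 0.5), producing the inverted-U; ``β_P`` makes
raters faster when the feature is present.

All randomness derives from a single seed via stable hashing of stage
names, so enlarging the crowd never perturbs the truth draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import derive_seed
from .errors import ConfigError
from .io_core import RatingTable

ACTIVE_SUPERFEATURES = (
    "dots",
    "globules",
    "lines",
    "network structures",
    "regression structures",
    "vessels",
)

# Truth prevalence defaults: fraction of the 248 study images whose panel
# consensus was "present" (gold present count / 248) per superfeature.
DEFAULT_PREVALENCE = {
    "dots": 0.25,
    "globules": 0.37,
    "lines": 0.24,
    "network structures": 0.56,
    "regression structures": 0.24,
    "vessels": 0.27,
}

# Fraction of genuinely ambiguous ("hard") images per superfeature,
# derived from the printed per-feature counts of images on which only 1-2
# of 5 panel experts agreed (ambiguous / 248).  The study images were
# curated exemplars, so difficulty is bimodal: a clear easy bulk plus a
# hard minority near the point of indecision.
DEFAULT_HARD_FRACTION = {
    "dots": 0.38,
    "globules": 0.40,
    "lines": 0.24,
    "network structures": 0.18,
    "regression structures": 0.31,
    "vessels": 0.12,
}

# Crowd sizes and per-user rating-count medians per task, as reported for
# the nonexpert crowd study.
DEFAULT_CROWD_USERS = {
    "dots": 92,
    "globules": 111,
    "lines": 82,
    "network structures": 97,
    "regression structures": 79,
    "vessels": 95,
}
DEFAULT_CROWD_MEDIANS = {
    "dots": 160,
    "globules": 131,
    "lines": 177,
    "network structures": 91,
    "regression structures": 124,
    "vessels": 104,
}


def _per_feature(value, features: Sequence[str], name: str) -> dict:
    """Normalise scalar-or-mapping config values to a per-feature dict."""
    if isinstance(value, Mapping):
        out = {}
        for f in features:
            if f not in value:
                raise ConfigError(f"{name} missing entry for feature {f!r}")
            out[f] = value[f]
        return out
    return {f: value for f in features}


@dataclass
class SimulationConfig:
    """All generative parameters of the three-study simulator.

    Ability distributions are given as ``("beta", a, b)`` — ability is
    ``0.5 + 0.5·Beta(a, b)`` — or ``("fixed", v)`` for a degenerate rater
    population (v = 1.0 gives perfect raters, v = 0.5 coin-flippers).
    """

    n_images: int = 248
    superfeatures: tuple[str, ...] = ACTIVE_SUPERFEATURES
    prevalence: Mapping[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )

    n_panel_experts: int = 20
    substudies: int = 4
    panel_size: int = 5

    crowd_users: Mapping[str, int] | int = field(
        default_factory=lambda: dict(DEFAULT_CROWD_USERS)
    )
    crowd_ratings_median: Mapping[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_CROWD_MEDIANS)
    )
    crowd_ratings_sigma: float = 0.6
    min_ratings_per_user: int = 10

    expert_crowd_size: int = 7
    expert_crowd_used: int = 5

    panel_ability: tuple = ("beta", 40.0, 1.0)
    crowd_ability: tuple = ("beta", 14.0, 2.0)
    expert_crowd_ability: tuple = ("beta", 20.0, 1.5)

    # Difficulty is a two-component mixture per (image, superfeature): an
    # easy bulk Beta(mean*c, (1-mean)*c) and a hard mode Beta(a, b) near 1.
    difficulty_easy_mean: Mapping[str, float] | float = 0.03
    difficulty_concentration: float = 4.0
    difficulty_hard_fraction: Mapping[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_HARD_FRACTION)
    )
    difficulty_hard_beta: tuple[float, float] = (8.0, 2.0)

    # Reaction-time model: log(1+RT) = alpha_j + beta_u*4p(1-p) - beta_p*z + eps
    rt_alpha_mean: float = 1.1
    rt_alpha_sd: float = 0.18
    rt_beta_u: float = 0.2
    rt_beta_p: float = 0.6
    rt_sigma: float = 0.45
    rt_min: float = 0.05

    seed: int = 0

    # --- derived, normalised views -------------------------------------
    def prevalence_of(self, feature: str) -> float:
        return _per_feature(self.prevalence, self.superfeatures, "prevalence")[feature]

    def difficulty_easy_mean_of(self, feature: str) -> float:
        return _per_feature(
            self.difficulty_easy_mean, self.superfeatures, "difficulty_easy_mean"
        )[feature]

    def hard_fraction_of(self, feature: str) -> float:
        return _per_feature(
            self.difficulty_hard_fraction, self.superfeatures, "difficulty_hard_fraction"
        )[feature]

    def crowd_users_of(self, feature: str) -> int:
        return int(_per_feature(self.crowd_users, self.superfeatures, "crowd_users")[feature])

    def crowd_median_of(self, feature: str) -> float:
        return float(
            _per_feature(
                self.crowd_ratings_median, self.superfeatures, "crowd_ratings_median"
            )[feature]
        )

    def validate(self) -> None:
        if self.n_panel_experts % self.substudies != 0:
            raise ConfigError(
                f"n_panel_experts ({self.n_panel_experts}) not divisible by "
                f"substudies ({self.substudies})"
            )
        if self.n_images % self.substudies != 0:
            raise ConfigError(
                f"n_images ({self.n_images}) not divisible by substudies "
                f"({self.substudies})"
            )
        if self.n_panel_experts // self.substudies != self.panel_size:
            raise ConfigError(
                "panel_size must equal n_panel_experts / substudies "
                f"({self.n_panel_experts}/{self.substudies} != {self.panel_size})"
            )
        for f in self.superfeatures:
            p = self.prevalence_of(f)
            if not 0.0 < p < 1.0:
                raise ConfigError(f"prevalence for {f!r} must be in (0,1); got {p}")
            m = self.difficulty_easy_mean_of(f)
            if not 0.0 < m < 1.0:
                raise ConfigError(
                    f"difficulty_easy_mean for {f!r} must be in (0,1); got {m}"
                )
            h = self.hard_fraction_of(f)
            if not 0.0 <= h < 1.0:
                raise ConfigError(
                    f"difficulty_hard_fraction for {f!r} must be in [0,1); got {h}"
                )
        for name in ("rt_beta_u", "rt_beta_p", "rt_sigma", "rt_alpha_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("panel_ability", "crowd_ability", "expert_crowd_ability"):
            spec = getattr(self, name)
            if spec[0] == "fixed":
                if not 0.5 <= spec[1] <= 1.0:
                    raise ConfigError(f"{name}: fixed ability must be in [0.5, 1]")
            elif spec[0] == "beta":
                if spec[1] <= 0 or spec[2] <= 0:
                    raise ConfigError(f"{name}: beta parameters must be positive")
            else:
                raise ConfigError(f"{name}: unknown ability model {spec[0]!r}")
        if not 0 < self.expert_crowd_used <= self.expert_crowd_size:
            raise ConfigError("expert_crowd_used must be in (0, expert_crowd_size]")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimulationConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "superfeatures" in kwargs:
            kwargs["superfeatures"] = tuple(kwargs["superfeatures"])
        for key in ("panel_ability", "crowd_ability", "expert_crowd_ability"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class SimulatedDataset:
    """A simulated three-study dataset plus its latent generating state."""

    truth: pd.DataFrame  # image_id, superfeature, present
    difficulty: pd.DataFrame  # image_id, superfeature, difficulty
    abilities: pd.DataFrame  # rater_id, cohort, ability
    ratings: RatingTable
    config: SimulationConfig

    def truth_matrix(self) -> pd.DataFrame:
        return self.truth.pivot(index="image_id", columns="superfeature", values="present")


def mean_ability(spec: tuple) -> float:
    """Expected rater ability under an ability model spec."""
    if spec[0] == "fixed":
        return float(spec[1])
    a, b = float(spec[1]), float(spec[2])
    return 0.5 + 0.5 * a / (a + b)


def _draw_abilities(spec: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec[0] == "fixed":
        return np.full(n, float(spec[1]))
    return 0.5 + 0.5 * rng.beta(float(spec[1]), float(spec[2]), size=n)


def assign_panel(n_experts: int, n_images: int, substudies: int) -> dict[int, np.ndarray]:
    """Partition experts and images into non-overlapping substudy blocks.

    Images are split into ``substudies`` equal blocks and experts into
    ``substudies`` equal groups; every expert in a group rates every image
    of its block, so each image receives exactly ``n_experts/substudies``
    raters.

    Returns a mapping expert index → array of image indices.
    """
    if n_experts % substudies != 0:
        raise ConfigError(
            f"n_experts ({n_experts}) not divisible by substudies ({substudies})"
        )
    if n_images % substudies != 0:
        raise ConfigError(
            f"n_images ({n_images}) not divisible by substudies ({substudies})"
        )
    experts_per_block = n_experts // substudies
    images_per_block = n_images // substudies
    assignment: dict[int, np.ndarray] = {}
    for e in range(n_experts):
        block = e // experts_per_block
        assignment[e] = np.arange(
            block * images_per_block, (block + 1) * images_per_block
        )
    return assignment


def draw_difficulty(
    config: SimulationConfig,
    feature: str,
    u_mix: np.ndarray,
    u_delta: np.ndarray,
    hard_fraction: float | None = None,
) -> np.ndarray:
    """Map uniform draws to mixture difficulties for one superfeature.

    ``u_mix`` selects the mixture component (hard iff below the hard
    fraction) and ``u_delta`` is mapped through the component's Beta
    quantile function.  Expressing the draw as a quantile transform keeps
    it monotone in the hard fraction under common random numbers, which
    the difficulty calibration relies on.
    """
    if hard_fraction is None:
        hard_fraction = config.hard_fraction_of(feature)
    mu = config.difficulty_easy_mean_of(feature)
    c = config.difficulty_concentration
    a_h, b_h = config.difficulty_hard_beta
    easy = stats.beta.ppf(u_delta, mu * c, (1.0 - mu) * c)
    hard = stats.beta.ppf(u_delta, a_h, b_h)
    delta = np.where(u_mix < hard_fraction, hard, easy)
    return np.clip(delta, 0.0, np.nextafter(1.0, 0.0))


def response_prob(z, delta, ability):
    """Probability of answering "present": q if z=1 else 1−q, with
    ``q = 0.5 + (1 − δ)(a − 0.5)`` the probability of a correct answer."""
    q = 0.5 + (1.0 - np.asarray(delta)) * (np.asarray(ability) - 0.5)
    z = np.asarray(z)
    return z * q + (1 - z) * (1 - q)


def simulate_response(z, delta, ability, rng: np.random.Generator):
    """Draw binary ratings: the correct label with probability
    ``q = 0.5 + (1 − δ)(a − 0.5)``, else the flipped label.

    Vectorised over broadcastable inputs.
    """
    z = np.asarray(z)
    delta = np.asarray(delta, dtype=float)
    ability = np.asarray(ability, dtype=float)
    if np.any((delta < 0) | (delta >= 1)):
        raise ConfigError("difficulty must be in [0, 1)")
    if np.any((ability < 0.5) | (ability > 1.0)):
        raise ConfigError("ability must be in [0.5, 1]")
    q = 0.5 + (1.0 - delta) * (ability - 0.5)
    correct = rng.random(np.broadcast(z, q).shape) < q
    return np.where(correct, z, 1 - z).astype(np.int8)


def simulate_rt(
    z,
    p,
    alpha,
    rng: np.random.Generator,
    *,
    beta_u: float,
    beta_p: float,
    sigma: float,
    rt_min: float = 0.05,
):
    """Draw reaction times from the log-linear inverted-U model.

    ``RT = exp(α + β_U·4p(1−p) − β_P·z + ε) − 1`` with ``ε ~ N(0, σ)``,
    floored at ``rt_min``.  Expected log(1+RT) is maximal at p = 0.5 for
    fixed z and lower when the feature is present (z = 1).
    """
    z = np.asarray(z)
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ConfigError("expected present-proportion p must be in [0, 1]")
    shape = np.broadcast(z, p, np.asarray(alpha)).shape
    eps = rng.normal(0.0, sigma, size=shape) if sigma > 0 else 0.0
    log_rt1 = np.asarray(alpha) + beta_u * 4.0 * p * (1.0 - p) - beta_p * z + eps
    return np.maximum(np.exp(log_rt1) - 1.0, rt_min)


def _feature_slug(feature: str) -> str:
    return feature.replace(" ", "_")


def simulate_study(config: SimulationConfig, seed: int | None = None) -> SimulatedDataset:
    """Simulate the full three-study dataset from a config.

    Emits panel-expert ratings (study 1 analogue, untimed), crowd ratings
    over per-user random image subsets (study 2 analogue, timed), and
    expert-crowd ratings over all images (study 3 analogue, timed), fully
    reproducible from the seed.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    feats = list(config.superfeatures)
    n_feats = len(feats)
    n_img = config.n_images

    # -- latent state ----------------------------------------------------
    rng_truth = np.random.default_rng(derive_seed(seed, "truth"))
    pi = np.array([config.prevalence_of(f) for f in feats])
    z = (rng_truth.random((n_img, n_feats)) < pi).astype(np.int8)

    rng_diff = np.random.default_rng(derive_seed(seed, "difficulty"))
    delta = np.empty((n_img, n_feats))
    for j, f in enumerate(feats):
        delta[:, j] = draw_difficulty(
            config, f, rng_diff.random(n_img), rng_diff.random(n_img)
        )

    image_ids = np.array([f"img{i:04d}" for i in range(n_img)])

    # -- abilities -------------------------------------------------------
    rng_abil = np.random.default_rng(derive_seed(seed, "abilities"))
    panel_ability = _draw_abilities(config.panel_ability, config.n_panel_experts, rng_abil)
    ec_ability = _draw_abilities(
        config.expert_crowd_ability, config.expert_crowd_size, rng_abil
    )
    crowd_ability = {
        f: _draw_abilities(config.crowd_ability, config.crowd_users_of(f), rng_abil)
        for f in feats
    }

    ability_rows = []
    frames = []

    # -- study 1: panel --------------------------------------------------
    assignment = assign_panel(config.n_panel_experts, n_img, config.substudies)
    rng_panel = np.random.default_rng(derive_seed(seed, "panel"))
    p_rater, p_img, p_feat, p_resp = [], [], [], []
    for e in range(config.n_panel_experts):
        rid = f"panel{e:02d}"
        ability_rows.append((rid, "panel", float(panel_ability[e])))
        imgs = assignment[e]
        for j, f in enumerate(feats):
            resp = simulate_response(
                z[imgs, j], delta[imgs, j], panel_ability[e], rng_panel
            )
            p_rater.append(np.full(imgs.size, rid))
            p_img.append(image_ids[imgs])
            p_feat.append(np.full(imgs.size, f))
            p_resp.append(resp)
    frames.append(
        pd.DataFrame(
            {
                "rater_id": np.concatenate(p_rater),
                "image_id": np.concatenate(p_img),
                "feature": np.concatenate(p_feat),
                "present": np.concatenate(p_resp),
                "reaction_time_s": np.nan,
                "cohort": "panel",
            }
        )
    )

    # -- study 2: crowd (per-feature tasks) ------------------------------
    crowd_mean_a = mean_ability(config.crowd_ability)
    for j, f in enumerate(feats):
        rng_f = np.random.default_rng(derive_seed(seed, "crowd", f))
        n_users = config.crowd_users_of(f)
        median = config.crowd_median_of(f)
        counts = np.rint(
            rng_f.lognormal(np.log(median), config.crowd_ratings_sigma, size=n_users)
        ).astype(int)
        counts = np.clip(counts, config.min_ratings_per_user, n_img)
        abil = crowd_ability[f]
        rater_col, img_col, resp_col, rt_col = [], [], [], []
        alphas = rng_f.normal(config.rt_alpha_mean, config.rt_alpha_sd, size=n_users)
        for u in range(n_users):
            rid = f"crowd_{_feature_slug(f)}_{u:03d}"
            ability_rows.append((rid, "crowd", float(abil[u])))
            imgs = rng_f.choice(n_img, size=counts[u], replace=False)
            resp = simulate_response(z[imgs, j], delta[imgs, j], abil[u], rng_f)
            p_item = response_prob(z[imgs, j], delta[imgs, j], crowd_mean_a)
            rt = simulate_rt(
                z[imgs, j],
                p_item,
                alphas[u],
                rng_f,
                beta_u=config.rt_beta_u,
                beta_p=config.rt_beta_p,
                sigma=config.rt_sigma,
                rt_min=config.rt_min,
            )
            rater_col.append(np.full(imgs.size, rid))
            img_col.append(image_ids[imgs])
            resp_col.append(resp)
            rt_col.append(rt)
        frames.append(
            pd.DataFrame(
                {
                    "rater_id": np.concatenate(rater_col),
                    "image_id": np.concatenate(img_col),
                    "feature": f,
                    "present": np.concatenate(resp_col),
                    "reaction_time_s": np.concatenate(rt_col),
                    "cohort": "crowd",
                }
            )
        )

    # -- study 3: expert crowd ------------------------------------------
    ec_mean_a = mean_ability(config.expert_crowd_ability)
    rng_ec = np.random.default_rng(derive_seed(seed, "expert_crowd"))
    ec_alphas = rng_ec.normal(
        config.rt_alpha_mean, config.rt_alpha_sd, size=config.expert_crowd_size
    )
    all_imgs = np.arange(n_img)
    for r in range(config.expert_crowd_size):
        rid = f"excrowd{r:02d}"
        ability_rows.append((rid, "expert_crowd", float(ec_ability[r])))
        for j, f in enumerate(feats):
            resp = simulate_response(z[:, j], delta[:, j], ec_ability[r], rng_ec)
            p_item = response_prob(z[:, j], delta[:, j], ec_mean_a)
            rt = simulate_rt(
                z[:, j],
                p_item,
                ec_alphas[r],
                rng_ec,
                beta_u=config.rt_beta_u,
                beta_p=config.rt_beta_p,
                sigma=config.rt_sigma,
                rt_min=config.rt_min,
            )
            frames.append(
                pd.DataFrame(
                    {
                        "rater_id": rid,
                        "image_id": image_ids[all_imgs],
                        "feature": f,
                        "present": resp,
                        "reaction_time_s": rt,
                        "cohort": "expert_crowd",
                    }
                )
            )

    ratings_df = pd.concat(frames, ignore_index=True)
    ratings_df = ratings_df.sort_values(
        ["cohort", "rater_id", "image_id", "feature"], kind="mergesort"
    ).reset_index(drop=True)
    table = RatingTable(df=ratings_df, level="superfeature")

    truth_df = pd.DataFrame(
        {
            "image_id": np.repeat(image_ids, n_feats),
            "superfeature": np.tile(feats, n_img),
            "present": z.ravel(),
        }
    )
    diff_df = pd.DataFrame(
        {
            "image_id": np.repeat(image_ids, n_feats),
            "superfeature": np.tile(feats, n_img),
            "difficulty": delta.ravel(),
        }
    )
    abil_df = pd.DataFrame(ability_rows, columns=["rater_id", "cohort", "ability"])

    return SimulatedDataset(
        truth=truth_df,
        difficulty=diff_df,
        abilities=abil_df,
        ratings=table,
        config=replace(config, seed=seed),
    )
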