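"""Seed-reproducible synthetic data with the structure of the vervet analyses.

Two generators mirror the two empirical designs:

* **Spread observations** — per-focal-follow records (group, census size,
  season, ordinal spatial-spread category 1-4) drawn from a cumulative-logit
  (proportional-odds) law with equidistant thresholds.  The linear predictor
  is ``eta = beta_size * (size - center) + beta_season * winter +
  beta_interaction * (size - center) * winter`` and
  ``P(Y <= j) = logistic(theta_j - eta)`` with ``theta_j = theta_base +
  (j - 1) * spacing``.
* **Contests** — per-encounter records (dyad, season, spatial-spread
  difference in {-3..3} minus 0, relative NDVI, focal-win indicator) with
  win probability ``logistic(intercept + beta_dq * spread_diff +
  beta_season * winter + beta_ndvi * rel_ndvi)``.

Default effect sizes are the published point estimates (size slope 0.15,
size-by-winter interaction 0.04, season shift -0.03; spread-difference
log-odds -0.52); default group sizes, group shares, and per-dyad encounter
counts follow the study population.  The generators fit what the inference
module estimates: fixed effects only, no random-effect heterogeneity by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "GeneratorConfig",
    "DEFAULT_CONFIG",
    "SPREAD_COLUMNS",
    "CONTEST_COLUMNS",
    "generate_spread_observations",
    "generate_contests",
    "summarize_spread_by_group",
    "spread_category_probabilities",
]

SPREAD_COLUMNS = ["group_id", "group_size", "season", "spread_category"]
CONTEST_COLUMNS = ["dyad", "season", "spread_diff", "rel_ndvi", "focal_win"]

#: Spatial-spread categories: 1 = 0-20 m, 2 = 20-50 m, 3 = 50-100 m, 4 = >100 m.
N_CATEGORIES = 4

_GROUPS = ("AK", "NH", "BD")
_DYADS = ("AK-BD", "AK-NH", "BD-CR", "BD-NH")


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of both generators; the defaults are the study conditions."""

    seed: int = 0
    # --- spread-observation (ordinal) design ---
    n_obs: int = 5000
    group_size_means: Mapping[str, float] = field(
        default_factory=lambda: {"AK": 21.32, "NH": 34.04, "BD": 50.58}
    )
    group_size_sds: Mapping[str, float] = field(
        default_factory=lambda: {"AK": 1.5, "NH": 4.88, "BD": 2.64}
    )
    # observation shares per group from the published per-group counts
    # (792, 2003, 2427 of 5222)
    group_shares: Mapping[str, float] = field(
        default_factory=lambda: {"AK": 792 / 5222, "NH": 2003 / 5222, "BD": 2427 / 5222}
    )
    winter_prob: float = 0.5
    beta_size: float = 0.15
    beta_season: float = -0.03
    beta_interaction: float = 0.04
    threshold_base: float = -1.0
    threshold_spacing: float = 2.0
    # --- contest (logistic) design ---
    contest_counts: Mapping[str, int] = field(
        default_factory=lambda: {"AK-BD": 34, "AK-NH": 16, "BD-CR": 10, "BD-NH": 11}
    )
    total_contests: Optional[int] = None  # override: dyads drawn by default shares
    ndvi_sd: float = 0.1
    intercept: float = 0.0
    beta_dq: float = -0.52
    contest_beta_season: float = 0.0
    beta_ndvi: float = 0.0

    def __post_init__(self) -> None:
        if self.n_obs < 0 or (self.total_contests is not None and self.total_contests < 0):
            raise ValueError("counts must be non-negative")
        if any(sd < 0 for sd in self.group_size_sds.values()):
            raise ValueError("group size sds must be non-negative")
        if self.threshold_spacing <= 0:
            raise ValueError("threshold_spacing must be positive")

    @property
    def size_center(self) -> float:
        """Pooled mean census size the slopes are centered at."""
        return sum(
            self.group_shares[g] * self.group_size_means[g] for g in self.group_size_means
        )

    def with_(self, **changes) -> "GeneratorConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


DEFAULT_CONFIG = GeneratorConfig()


def spread_category_probabilities(
    eta: np.ndarray, theta_base: float, spacing: float
) -> np.ndarray:
    """Closed-form cumulative-logit category probabilities, shape (n, 4).

    ``P(Y <= j) = expit(theta_j - eta)`` with equidistant thresholds
    ``theta_j = theta_base + (j - 1) * spacing`` for j = 1..3.
    """
    eta = np.asarray(eta, dtype=float)
    thetas = theta_base + spacing * np.arange(N_CATEGORIES - 1)
    cum = expit(thetas - eta[..., None])  # (n, 3)
    ones = np.ones(eta.shape + (1,))
    zeros = np.zeros(eta.shape + (1,))
    return np.diff(np.concatenate([zeros, cum, ones], axis=-1), axis=-1)


def generate_spread_observations(
    config: GeneratorConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Simulate per-observation ordinal spread records (one per focal follow).

    Columns: group_id, group_size, season ("summer"/"winter"),
    spread_category (1-4).  Deterministic for a fixed config (seed included).
    """
    if config.n_obs <= 0:
        raise ValueError("n_obs must be positive")
    rng = np.random.default_rng(config.seed)
    groups = list(config.group_size_means)
    shares = np.array([config.group_shares[g] for g in groups], dtype=float)
    shares = shares / shares.sum()
    gidx = rng.choice(len(groups), size=config.n_obs, p=shares)
    means = np.array([config.group_size_means[g] for g in groups])[gidx]
    sds = np.array([config.group_size_sds[g] for g in groups])[gidx]
    sizes = rng.normal(means, sds)
    sizes = np.maximum(sizes, 1.0)  # census sizes stay positive
    winter = rng.random(config.n_obs) < config.winter_prob
    centered = sizes - config.size_center
    eta = (
        config.beta_size * centered
        + config.beta_season * winter
        + config.beta_interaction * centered * winter
    )
    probs = spread_category_probabilities(
        eta, config.threshold_base, config.threshold_spacing
    )
    u = rng.random(config.n_obs)
    category = 1 + (u[:, None] > probs.cumsum(axis=1)[:, :-1]).sum(axis=1)
    return pd.DataFrame(
        {
            "group_id": np.asarray(groups, dtype=object)[gidx],
            "group_size": sizes,
            "season": np.where(winter, "winter", "summer"),
            "spread_category": category.astype(int),
        }
    )


def generate_contests(config: GeneratorConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Simulate between-group encounters with a binary focal-win outcome.

    Columns: dyad, season, spread_diff (integer in {-3..3} \\ {0}: focal
    category minus rival category), rel_ndvi (greenness relative to the
    home-range annual mean), focal_win (0/1).  Per-dyad encounter counts
    follow ``config.contest_counts`` exactly unless ``total_contests``
    overrides them, in which case dyads are drawn with the default shares.
    """
    rng = np.random.default_rng(config.seed + 1)  # independent of the spread stream
    if config.total_contests is not None:
        n = config.total_contests
        dyads = list(config.contest_counts)
        w = np.array([config.contest_counts[d] for d in dyads], dtype=float)
        dyad = np.asarray(dyads, dtype=object)[rng.choice(len(dyads), size=n, p=w / w.sum())]
    else:
        dyad = np.repeat(
            np.asarray(list(config.contest_counts), dtype=object),
            list(config.contest_counts.values()),
        )
        n = len(dyad)
    if n == 0:
        import warnings

        warnings.warn("contest configuration yields zero encounters", stacklevel=2)
        return pd.DataFrame(columns=CONTEST_COLUMNS)
    winter = rng.random(n) < config.winter_prob
    # identical-spread encounters are excluded by design, so 0 never occurs
    diff = rng.choice([-3, -2, -1, 1, 2, 3], size=n)
    ndvi = rng.normal(0.0, config.ndvi_sd, size=n)
    p_win = expit(
        config.intercept
        + config.beta_dq * diff
        + config.contest_beta_season * winter
        + config.beta_ndvi * ndvi
    )
    win = (rng.random(n) < p_win).astype(int)
    return pd.DataFrame(
        {
            "dyad": dyad,
            "season": np.where(winter, "winter", "summer"),
            "spread_diff": diff.astype(int),
            "rel_ndvi": ndvi,
            "focal_win": win,
        }
    )


def summarize_spread_by_group(records: pd.DataFrame) -> pd.DataFrame:
    """Per-group distribution over the four spread categories.

    Returns one row per group with columns ``cat_1 .. cat_4`` (proportions
    summing to 1 within a group), ``n_obs`` and ``share_pct`` (the group's
    percentage of the pooled observations).
    """
    if len(records) == 0:
        raise ValueError("cannot summarize an empty observation table")
    counts = (
        records.groupby("group_id")["spread_category"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=range(1, N_CATEGORIES + 1), fill_value=0)
    )
    out = counts.div(counts.sum(axis=1), axis=0)
    out.columns = [f"cat_{j}" for j in out.columns]
    out["n_obs"] = counts.sum(axis=1)
    out["share_pct"] = 100.0 * out["n_obs"] / out["n_obs"].sum()
    return out.reset_index()
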