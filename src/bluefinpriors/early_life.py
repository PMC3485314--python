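"""Early-life growth and young-of-the-year mortality.

The cumulative age-0 mortality M_0 is the sum of a fertilization/hatching
loss M_fh and 180 daily instantaneous rates M_d(x), x counted in days after
fertilization. Daily rates follow the allometric "small fish die fast"
regression of McGurk: mu(w) = a * w^b below a dry weight of 0.00504 g and
mu(w) = a' * w^b' above it, with a lognormal residual exp(Z), Z ~ N(0,
sigma) drawn independently each day. The dry weight path w_d(x) is pieced
together over five physiological stages:

1. incubation: constant egg weight until hatching (t_hatch ~ U(1, 2) d);
2. yolk-sac: linear weight loss from the egg weight down to the weight at
   first exogenous feeding w_ef over t_ef ~ U(2, 4) d;
3. early larva: power growth w_ef * (d + 1)^k1 for d = 0..20 days post
   exogenous feeding (dpef);
4. late larva: exponential growth from 20 to 60 dpef, with the rate k2
   solved so the path meets the juvenile growth curve at 60 dpef;
5. juvenile: dry weight (1 - hf) * W_juv(fl(dpef)) up to day 150 after
   fertilization, then linear interpolation to the age-1 von Bertalanffy
   weight at day 180.

Because daily rates exceed 1 d^-1 while the larva is tiny, most of M_0
accrues within the first week or two of life; the per-day residual is what
gives M_0 its wide spread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import LifeHistoryConfig
from .distributions import sample

__all__ = [
    "GrowthTrajectory",
    "EarlyLifeDraw",
    "build_trajectory",
    "mean_daily_mortality",
    "daily_mortality",
    "draw_M0",
    "sample_M0",
    "sample_fert_hatch_loss",
]

STAGES = ("incubation", "yolk_sac", "power_growth", "exponential_growth",
          "juvenile", "year_end_interpolation")


@dataclass
class GrowthTrajectory:
    """Daily dry-weight path over the first-year horizon.

    ``days`` are integer days post-fertilization (1..horizon); ``dry_weight``
    in grams; ``stage`` holds one of :data:`STAGES` per day. Realized
    stochastic inputs (t_hatch, t_ef, w_ef, the solved exponential rate k2
    and the cohort-level juvenile size deviate) are kept for diagnostics.
    """

    days: np.ndarray
    dry_weight: np.ndarray
    stage: np.ndarray
    t_hatch: float
    t_ef: float
    w_ef: float
    k2: float
    juvenile_factor: float


@dataclass
class EarlyLifeDraw:
    """One Monte-Carlo realization of the age-0 mortality integration."""

    trajectory: GrowthTrajectory | None
    M_fh: float                 # fertilization + hatching loss (instantaneous)
    M_d: np.ndarray             # realized daily rates, day^-1
    M_y: float                  # sum of daily rates over the horizon
    M_0: float                  # M_fh + M_y, year^-1 by the 180-day convention
    S_0: float                  # exp(-M_0)


def age1_dry_weight(cfg: LifeHistoryConfig) -> float:
    """Dry weight (g) of an age-1 fish from the adult growth curves."""
    length_cm = float(cfg.vb_growth.length(1.0))
    wet_kg = float(cfg.length_weight.weight(length_cm))
    return (1.0 - cfg.hf) * wet_kg * 1000.0


def build_trajectory(cfg: LifeHistoryConfig, rng: np.random.Generator) -> GrowthTrajectory:
    """Realize one daily dry-weight path over ``cfg.early_life_horizon`` days.

    Stage boundaries fall on fractional days; each integer day takes the
    stage of the interval containing it. The path is continuous at every
    boundary by construction (the power stage is anchored at w_ef, the
    exponential rate k2 is solved to meet the juvenile curve, and the final
    segment interpolates linearly to the age-1 weight).
    """
    horizon = cfg.early_life_horizon
    days = np.arange(1, horizon + 1, dtype=float)
    w = np.empty(horizon)
    stage = np.empty(horizon, dtype=object)

    t_hatch = sample(cfg.t_hatch, rng)
    t_ef = sample(cfg.t_ef, rng)
    w_ef = sample(cfg.w_ef, rng)
    t_ff = t_hatch + t_ef  # first exogenous feeding, days post-fertilization

    jg = cfg.juvenile_growth
    # one multiplicative size deviate per cohort draw (between-individual CV)
    juv_factor = 0.0
    while juv_factor <= 0.0:
        juv_factor = 1.0 + rng.normal(0.0, jg.weight_cv)

    def juvenile_dry(day):
        dpef = np.asarray(day, dtype=float) - t_ff
        return (1.0 - cfg.hf) * jg.wet_weight(dpef) * juv_factor

    # exponential stage must reach the juvenile curve at 60 dpef
    w20 = w_ef * 21.0 ** cfg.k1
    w60 = float(juvenile_dry(t_ff + 60.0))
    if not (np.isfinite(w20) and np.isfinite(w60)) or w20 <= 0 or w60 <= 0:
        raise ValueError("exponential_growth stage: no solution for k2 "
                         f"(w20={w20}, w60={w60})")
    k2 = np.log(w60 / w20) / 40.0

    end_day = cfg.juvenile_end_day
    w_end = age1_dry_weight(cfg) * juv_factor
    w_150 = float(juvenile_dry(end_day))

    incub = days <= t_hatch
    yolk = (days > t_hatch) & (days <= t_ff)
    power = (days > t_ff) & (days <= t_ff + 20.0)
    expo = (days > t_ff + 20.0) & (days <= t_ff + 60.0)
    juv = (days > t_ff + 60.0) & (days <= end_day)
    tail = days > end_day

    w[incub] = cfg.w_egg
    stage[incub] = "incubation"
    w[yolk] = cfg.w_egg + (w_ef - cfg.w_egg) * (days[yolk] - t_hatch) / t_ef
    stage[yolk] = "yolk_sac"
    w[power] = w_ef * (days[power] - t_ff + 1.0) ** cfg.k1
    stage[power] = "power_growth"
    w[expo] = w20 * np.exp(k2 * (days[expo] - t_ff - 20.0))
    stage[expo] = "exponential_growth"
    w[juv] = juvenile_dry(days[juv])
    stage[juv] = "juvenile"
    w[tail] = w_150 + (w_end - w_150) * (days[tail] - end_day) / (horizon - end_day)
    stage[tail] = "year_end_interpolation"

    if not np.all(np.isfinite(w)) or (w <= 0).any():
        bad = int(np.argmax(~np.isfinite(w) | (w <= 0)))
        raise ValueError(f"non-positive or non-finite weight at day {bad + 1} "
                         f"(stage {stage[bad]})")
    return GrowthTrajectory(days=days, dry_weight=w, stage=stage,
                            t_hatch=t_hatch, t_ef=t_ef, w_ef=w_ef, k2=k2,
                            juvenile_factor=juv_factor)


def mean_daily_mortality(w, cfg: LifeHistoryConfig) -> np.ndarray:
    """Allometric mean daily mortality mu(w), day^-1, without residual error."""
    w = np.asarray(w, dtype=float)
    if (w <= 0).any():
        raise ValueError("dry weight must be positive")
    small = cfg.mcgurk_small
    large = cfg.mcgurk_large
    return np.where(
        w < cfg.weight_threshold,
        small.coef * w ** small.exponent,
        large.coef * w ** large.exponent,
    )


def daily_mortality(w, cfg: LifeHistoryConfig, rng: np.random.Generator,
                    with_error: bool | None = None) -> np.ndarray:
    """Realized daily mortality: mu(w) * exp(Z), Z drawn independently per day.

    ``with_error=False`` (or ``cfg.mcgurk_error = False``) returns the bare
    regression mean; comparing the two modes reproduces the large dispersion
    the regression residual injects into cumulative early mortality.
    """
    w = np.atleast_1d(np.asarray(w, dtype=float))
    mu = mean_daily_mortality(w, cfg)
    if with_error is None:
        with_error = cfg.mcgurk_error
    if not with_error:
        return mu
    sigma = np.where(w < cfg.weight_threshold,
                     cfg.mcgurk_small.sigma, cfg.mcgurk_large.sigma)
    z = rng.normal(0.0, 1.0, size=w.shape)
    return mu * np.exp(sigma * z)


def sample_fert_hatch_loss(cfg: LifeHistoryConfig, rng: np.random.Generator) -> float:
    """Instantaneous fertilization+hatching mortality M_fh.

    The default scale is the rate itself (mean -ln 0.5); the alternative
    expresses the loss as a survival fraction and converts with -ln(s).
    """
    x = sample(cfg.fert_hatch_loss, rng)
    if cfg.fert_hatch_scale == "survival":
        return float(-np.log(x))
    return float(x)


def draw_M0(cfg: LifeHistoryConfig, rng: np.random.Generator,
            keep_trajectory: bool = True) -> EarlyLifeDraw:
    """One Monte-Carlo draw of the cumulative young-of-the-year mortality.

    When ``cfg.m0_override`` is set (informative-M_0 scenarios) the whole
    growth-mortality integration is bypassed and M_0 is drawn directly from
    the override distribution.
    """
    if cfg.m0_override is not None:
        m0 = max(sample(cfg.m0_override, rng), 0.0)
        return EarlyLifeDraw(trajectory=None, M_fh=np.nan,
                             M_d=np.empty(0), M_y=np.nan,
                             M_0=m0, S_0=float(np.exp(-m0)))
    m_fh = sample_fert_hatch_loss(cfg, rng)
    traj = build_trajectory(cfg, rng)
    m_d = daily_mortality(traj.dry_weight, cfg, rng)
    m_y = float(m_d.sum())
    m0 = m_fh + m_y
    return EarlyLifeDraw(trajectory=traj if keep_trajectory else None,
                         M_fh=m_fh, M_d=m_d, M_y=m_y,
                         M_0=m0, S_0=float(np.exp(-m0)))


def sample_M0(cfg: LifeHistoryConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """n independent M_0 draws (the marginal the priors inherit their spread from)."""
    return np.array([draw_M0(cfg, rng, keep_trajectory=False).M_0 for _ in range(n)])
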