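"""Post-recruitment vital rates: mortality, growth, and fecundity at age.

Ages run from recruitment (age 1) to the terminal age A. Each Monte-Carlo
draw realizes a mortality-at-age vector (Gaussian noise, CV 10%, truncated
at zero), lengths at age around the von Bertalanffy mean (CV 10%), weights
through the length-weight power law, and an absolute annual fecundity
f_A(i) = bf * W_g(i) * N_batch (oocytes), where bf is the relative batch
fecundity in oocytes per gram and N_batch the number of batches per
spawning season. The expected per-year contribution of an age-i female to
the age-0 class is

    F(i) = sr * g(i) * f_A(i) * Rf

with g(i) the maturity ogive, sr the sex ratio, and Rf the reproduction
frequency: 1/Spe where the spawning periodicity Spe (years between
spawnings) is drawn per cohort, or an explicit Rf distribution when the
configuration carries one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import LifeHistoryConfig
from .distributions import sample

__all__ = [
    "VitalRatesDraw",
    "sample_mortality_at_age",
    "length_weight_at_age",
    "fecundity_at_age",
    "draw_vital_rates",
]


@dataclass
class VitalRatesDraw:
    """One realized set of age-structured vital rates (ages 1..A)."""

    M: np.ndarray           # instantaneous mortality, year^-1
    S: np.ndarray           # annual survival e^-M
    survivorship: np.ndarray  # l(a): P(survive from recruitment to age a), l(1)=1
    length: np.ndarray      # fork length, cm
    weight: np.ndarray      # female weight, kg
    maturity: np.ndarray    # g(a)
    bf: float               # oocytes per gram
    n_batch: float
    reproduction_frequency: float  # Rf = 1/Spe (or sampled Rf)
    f_annual: np.ndarray    # f_A(a): oocytes per mature female per spawning year
    F: np.ndarray           # expected age-0 females per female per year

    @property
    def total_fecundity(self) -> float:
        """Summed F over ages; the scalar used for rank-coupling with M_0."""
        return float(self.F.sum())


def sample_mortality_at_age(cfg: LifeHistoryConfig, rng: np.random.Generator,
                            noise: bool = True):
    """Mortality-at-age, survival and survivorship for one draw.

    M(i) ~ N(mu_M(i), cv * mu_M(i)) truncated at zero; with ``noise=False``
    the schedule's means are returned unchanged.
    """
    mu = cfg.post_recruit_mortality_means
    if noise and cfg.post_recruit_mortality_cv > 0:
        sd = cfg.post_recruit_mortality_cv * mu
        M = rng.normal(mu, sd)
        bad = M < 0
        while bad.any():
            M[bad] = rng.normal(mu[bad], sd[bad])
            bad = M < 0
    else:
        M = mu.copy()
    S = np.exp(-M)
    # l(1) = 1; l(a) = prod_{j<a} S(j)
    surv = np.concatenate([[1.0], np.cumprod(S[:-1])])
    return M, S, surv


def length_weight_at_age(cfg: LifeHistoryConfig, ages=None,
                         rng: np.random.Generator | None = None,
                         noise: bool = True):
    """Fork length (cm) and female weight (kg) at the given ages.

    Lengths are Gaussian around the von Bertalanffy mean with the configured
    CV, truncated at zero; weights follow W = B * L^C.
    """
    if ages is None:
        ages = np.arange(1, cfg.terminal_age + 1)
    ages = np.asarray(ages, dtype=float)
    mean_len = cfg.vb_growth.length(ages)
    if noise and cfg.length_cv > 0:
        if rng is None:
            raise ValueError("rng is required when noise is enabled")
        sd = cfg.length_cv * mean_len
        L = rng.normal(mean_len, sd)
        bad = L <= 0
        while bad.any():
            L[bad] = rng.normal(mean_len[bad], sd[bad])
            bad = L <= 0
    else:
        L = mean_len
    W = cfg.length_weight.weight(L)
    return L, W


def expected_reproduction_frequency(cfg: LifeHistoryConfig) -> float:
    """E[1/Spe] for a discrete (or constant) spawning-periodicity spec."""
    spec = cfg.spe
    if spec.family == "constant":
        return 1.0 / spec.params[0]
    if spec.family == "discrete_uniform":
        vals = np.asarray(spec.params)
        probs = np.asarray(spec.probs) if spec.probs is not None else np.full(len(vals), 1.0 / len(vals))
        return float(np.sum(probs / vals))
    raise ValueError(f"expected spe mode needs a discrete or constant Spe spec, got {spec.family}")


def sample_reproduction_frequency(cfg: LifeHistoryConfig, rng: np.random.Generator) -> float:
    """Rf, spawnings per year.

    A Leslie fecundity entry is an *expected* annual rate, so the default
    (``spe_mode="expected"``) averages skip-spawning out analytically:
    Rf = E[1/Spe]. ``spe_mode="sampled"`` instead realizes Spe once per
    cohort draw (Rf = 1/Spe), pushing skip-spawning variability between
    draws. An explicit ``spawning_frequency`` spec overrides both.
    """
    if cfg.spawning_frequency is not None:
        return float(sample(cfg.spawning_frequency, rng))
    if cfg.spe_mode == "expected":
        return expected_reproduction_frequency(cfg)
    return 1.0 / float(sample(cfg.spe, rng))


def fecundity_at_age(cfg: LifeHistoryConfig, weight_kg: np.ndarray,
                     rng: np.random.Generator,
                     bf: float | None = None, n_batch: float | None = None,
                     rf: float | None = None):
    """Annual fecundity f_A and expected age-0-female output F per age.

    All oocytes are counted as eggs (full hydration). bf, N_batch and the
    reproduction frequency are drawn once per cohort unless supplied.
    """
    if bf is None:
        bf = sample(cfg.bf, rng)
    if n_batch is None:
        n_batch = sample(cfg.n_batch, rng)
    if rf is None:
        rf = sample_reproduction_frequency(cfg, rng)
    f_annual = bf * (np.asarray(weight_kg) * 1000.0) * n_batch
    F = cfg.sr * cfg.maturity_ogive * f_annual * rf
    return f_annual, F, bf, n_batch, rf


def draw_vital_rates(cfg: LifeHistoryConfig, rng: np.random.Generator,
                     noise: bool = True) -> VitalRatesDraw:
    """One joint draw of all post-recruitment vital rates."""
    M, S, surv = sample_mortality_at_age(cfg, rng, noise=noise)
    L, W = length_weight_at_age(cfg, rng=rng if noise else None, noise=noise)
    f_annual, F, bf, n_batch, rf = fecundity_at_age(cfg, W, rng)
    return VitalRatesDraw(M=M, S=S, survivorship=surv, length=L, weight=W,
                          maturity=cfg.maturity_ogive.copy(), bf=bf,
                          n_batch=n_batch, reproduction_frequency=rf,
                          f_annual=f_annual, F=F)
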