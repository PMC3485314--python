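"""Beverton-Holt steepness from simulated age-structured populations.

Steepness h is the fraction of unfished recruitment produced when spawning
biomass falls to 20% of its unfished level. For a Beverton-Holt
stock-recruitment curve it can be written as a compound of three
quantities:

    h = a_bar / (4 + a_bar),     a_bar = alpha * sr * W_bpr

where alpha is the maximum number of recruits per kilogram of spawning
biomass (the slope of the stock-recruit curve at the origin), sr the sex
ratio, and W_bpr the expected mature-female biomass per recruit under
natural mortality alone. alpha is obtained by simulating a population of N
individuals whose ages follow the unfished stationary age structure
(proportional to survivorship), evaluating each individual's life-history
traits at its age, and taking

    alpha = exp(-M_0) * F_sim / B_sim

with F_sim the total annual oocyte production and B_sim the total mature
female biomass of the simulated population. Because survival from egg to
recruitment is exp(-M_0), alpha inherits M_0's full spread — which is what
drives the shape of the steepness prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import LifeHistoryConfig
from .early_life import draw_M0
from .vital_rates import VitalRatesDraw, draw_vital_rates

__all__ = [
    "PopulationSample",
    "SteepnessDraw",
    "simulate_population",
    "alpha",
    "spawning_biomass_per_recruit",
    "steepness",
    "draw_steepness",
]


@dataclass
class PopulationSample:
    """A simulated unfished population snapshot."""

    ages: np.ndarray        # integer ages, 1..A
    weight: np.ndarray      # per-individual female weight, kg
    maturity: np.ndarray    # g(age) per individual
    fecundity: np.ndarray   # per-individual annual oocyte output
    F_sim: float            # total oocytes produced per year
    B_sim: float            # total mature female biomass, kg


@dataclass
class SteepnessDraw:
    """One Monte-Carlo realization of (M_0, alpha, W_bpr, h)."""

    M_0: float
    alpha: float            # recruits per kg spawning biomass
    W_bpr: float            # kg mature biomass per recruit
    h: float


def simulate_population(vr: VitalRatesDraw, cfg: LifeHistoryConfig, N: int,
                        rng: np.random.Generator) -> PopulationSample:
    """Simulate N individuals under the stationary unfished age structure.

    Ages are sampled with probability proportional to survivorship l(a);
    each individual receives a length (hence weight) drawn around the von
    Bertalanffy mean for its age, the maturity probability g(age), and an
    annual fecundity bf * W_g * N_batch * Rf using the cohort's shared
    reproductive draws.
    """
    if N < 100:
        raise ValueError(f"population size must be >= 100, got {N}")
    A = cfg.terminal_age
    if not (vr.maturity > 0).any():
        raise ValueError("no mature age class in 1..A; spawning biomass undefined")
    p = vr.survivorship / vr.survivorship.sum()
    ages = rng.choice(np.arange(1, A + 1), size=N, p=p)
    mean_len = cfg.vb_growth.length(ages)
    if cfg.length_cv > 0:
        sd = cfg.length_cv * mean_len
        L = rng.normal(mean_len, sd)
        bad = L <= 0
        while bad.any():
            L[bad] = rng.normal(mean_len[bad], sd[bad])
            bad = L <= 0
    else:
        L = mean_len
    W = cfg.length_weight.weight(L)
    g = vr.maturity[ages - 1]
    fec = g * vr.bf * (W * 1000.0) * vr.n_batch * vr.reproduction_frequency
    B_sim = float(np.sum(g * W))
    if B_sim <= 0:
        raise ValueError("simulated population has zero spawning biomass")
    return PopulationSample(ages=ages, weight=W, maturity=g, fecundity=fec,
                            F_sim=float(fec.sum()), B_sim=B_sim)


def alpha(pop: PopulationSample, M_0: float) -> float:
    """Recruits per kg spawning biomass: exp(-M_0) * F_sim / B_sim."""
    if pop.B_sim <= 0:
        raise ValueError("B_sim must be positive")
    return float(np.exp(-M_0) * pop.F_sim / pop.B_sim)


def spawning_biomass_per_recruit(vr: VitalRatesDraw) -> float:
    """W_bpr = sum_a l(a) * W_f(a) * g(a), kg per recruit, unfished."""
    return float(np.sum(vr.survivorship * vr.weight * vr.maturity))


def steepness(alpha_: float, sr: float, W_bpr: float) -> float:
    """Beverton-Holt steepness h = a/(4+a) with a = alpha * sr * W_bpr.

    Equals 0.2 exactly at replacement-level recruitment (a = 1) and
    approaches 1 as alpha grows without bound.
    """
    if alpha_ < 0 or W_bpr < 0:
        raise ValueError("alpha and W_bpr must be nonnegative")
    a_bar = alpha_ * sr * W_bpr
    return float(a_bar / (4.0 + a_bar))


def draw_steepness(cfg: LifeHistoryConfig, rng: np.random.Generator,
                   N: int | None = None,
                   M_0: float | None = None,
                   vr: VitalRatesDraw | None = None) -> SteepnessDraw:
    """One full steepness draw: M_0, vital rates, population, (alpha, W_bpr, h).

    ``M_0`` and ``vr`` may be supplied to reuse pre-drawn components (as the
    correlated-sampling machinery does); otherwise they are drawn fresh.
    """
    if N is None:
        N = cfg.mc.pop_size
    if M_0 is None:
        M_0 = draw_M0(cfg, rng, keep_trajectory=False).M_0
    if vr is None:
        vr = draw_vital_rates(cfg, rng)
    pop = simulate_population(vr, cfg, N, rng)
    a = alpha(pop, M_0)
    w_bpr = spawning_biomass_per_recruit(vr)
    return SteepnessDraw(M_0=M_0, alpha=a, W_bpr=w_bpr,
                         h=steepness(a, cfg.sr, w_bpr))
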