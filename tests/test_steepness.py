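import numpy as np
import pytest
from scipy import stats

from bluefinpriors.steepness import (
    PopulationSample,
    alpha,
    draw_steepness,
    simulate_population,
    spawning_biomass_per_recruit,
    steepness,
)
from bluefinpriors.vital_rates import draw_vital_rates, sample_mortality_at_age


def test_steepness_lower_bound_at_replacement():
    # alpha * sr * W_bpr = 1 is replacement-level recruitment: h = 0.2 exactly
    assert steepness(1.0, 0.5, 2.0) == pytest.approx(0.2, rel=1e-14)


def test_steepness_limits_and_monotonicity():
    assert steepness(0.0, 0.5, 470.0) == 0.0
    assert steepness(1e9, 0.5, 470.0) == pytest.approx(1.0, abs=1e-6)
    hs = [steepness(a, 0.5, 470.0) for a in np.logspace(-4, 2, 20)]
    assert (np.diff(hs) > 0).all()
    with pytest.raises(ValueError):
        steepness(-0.1, 0.5, 470.0)


def test_alpha_direct_evaluation():
    pop = PopulationSample(ages=np.array([10]), weight=np.array([100.0]),
                           maturity=np.array([1.0]), fecundity=np.array([1.9e7]),
                           F_sim=1.9e7, B_sim=100.0)
    # 1.9e5 oocytes per kg of SSB at M_0 = 12.5 -> ~0.7 recruits per kg
    assert alpha(pop, 12.5) == pytest.approx(np.exp(-12.5) * 1.9e5, rel=1e-12)
    assert alpha(pop, 12.5) == pytest.approx(0.71, abs=0.02)
    assert alpha(pop, 1e3) == pytest.approx(0.0, abs=1e-12)


def test_wbpr_matches_direct_sum(deterministic_cfg, rng):
    """Noise-free W_bpr equals the hand-computed survivorship-weight-maturity sum."""
    vr = draw_vital_rates(deterministic_cfg, rng)
    cfg = deterministic_cfg
    _, S, l = sample_mortality_at_age(cfg, rng, noise=False)
    L = cfg.vb_growth.length(np.arange(1, 31))
    W = cfg.length_weight.weight(L)
    expected = float(np.sum(l * W * cfg.maturity_ogive))
    assert spawning_biomass_per_recruit(vr) == pytest.approx(expected, rel=1e-12)
    # unfished lifetime mature biomass per recruit is a few hundred kg
    assert 400 < expected < 550


def test_population_age_structure_matches_survivorship(baseline, rng):
    vr = draw_vital_rates(baseline, rng)
    pop = simulate_population(vr, baseline, N=60_000, rng=rng)
    counts = np.bincount(pop.ages, minlength=31)[1:]
    expected = vr.survivorship / vr.survivorship.sum() * len(pop.ages)
    chi2 = stats.chisquare(counts, expected)
    assert chi2.pvalue > 1e-4  # consistent with the sampling weights


def test_two_age_uniform_survivorship_is_symmetric(baseline, rng):
    cfg = baseline.copy()
    doc = cfg.to_dict()
    doc["terminal_age"] = 2
    doc["post_recruit_mortality_means"] = [0.0, 0.0]
    doc["maturity_ogive"] = [1.0, 1.0]
    from bluefinpriors import load_config
    cfg2 = load_config(doc)
    vr = draw_vital_rates(cfg2, rng, noise=False)
    pop = simulate_population(vr, cfg2, N=20_000, rng=rng)
    frac_age1 = (pop.ages == 1).mean()
    assert frac_age1 == pytest.approx(0.5, abs=0.02)


def test_biomass_scales_linearly_with_population_size(baseline, rng):
    vr = draw_vital_rates(baseline, rng)
    b_small = np.mean([simulate_population(vr, baseline, 1000, rng).B_sim for _ in range(20)])
    b_large = np.mean([simulate_population(vr, baseline, 4000, rng).B_sim for _ in range(20)])
    assert b_large / b_small == pytest.approx(4.0, rel=0.1)


def test_all_immature_population_errors(baseline, rng):
    vr = draw_vital_rates(baseline, rng)
    vr.maturity = np.zeros_like(vr.maturity)
    with pytest.raises(ValueError, match="mature"):
        simulate_population(vr, baseline, 1000, rng)
    with pytest.raises(ValueError, match=">= 100"):
        simulate_population(draw_vital_rates(baseline, rng), baseline, 10, rng)


def test_alpha_stable_in_population_size(baseline, rng):
    """For fixed vital rates and M_0, alpha is insensitive to the simulated
    population size once N is ~1000: the ratio F_sim/B_sim estimates the
    same population-level quantity at any N."""
    vr = draw_vital_rates(baseline, rng)
    m0 = 12.5
    a_by_n = {N: np.mean([draw_steepness(baseline, rng, N=N, M_0=m0, vr=vr).alpha
                          for _ in range(15)])
              for N in (1000, 8000)}
    assert a_by_n[1000] == pytest.approx(a_by_n[8000], rel=0.02)


def test_h_tracks_alpha_not_wbpr(small_ensemble):
    """Steepness is driven by alpha (hence M_0); W_bpr adds no systematic signal."""
    ens = small_ensemble
    rho_a = stats.spearmanr(ens.alpha, ens.h).statistic
    rho_w = stats.spearmanr(ens.W_bpr, ens.h).statistic
    assert rho_a > 0.95
    assert abs(rho_w) < 0.25
    # alpha > 0.1 recruits/kg implies h > 0.8 in the baseline configuration
    assert (ens.h[ens.alpha > 0.1] > 0.8).all()
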