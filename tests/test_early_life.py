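import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bluefinpriors.early_life import (
    build_trajectory,
    daily_mortality,
    draw_M0,
    mean_daily_mortality,
    sample_M0,
    sample_fert_hatch_loss,
)
from bluefinpriors.distributions import constant


def test_incubation_days_hold_egg_weight(deterministic_cfg, rng):
    traj = build_trajectory(deterministic_cfg, rng)
    incub = traj.stage == "incubation"
    assert incub.any()
    assert np.all(traj.dry_weight[incub] == 42.8e-6)


def test_weight_at_first_feeding_matches_w_ef(deterministic_cfg, rng):
    # with t_hatch=1.5, t_ef=3 the linear yolk-sac segment must hit w_ef at
    # the first-feeding boundary (day 4.5); evaluate the interpolant there
    traj = build_trajectory(deterministic_cfg, rng)
    t_ff = traj.t_hatch + traj.t_ef
    w_at_ff = 42.8e-6 + (traj.w_ef - 42.8e-6) * (t_ff - traj.t_hatch) / traj.t_ef
    assert w_at_ff == pytest.approx(21.7e-6, rel=1e-12)
    # yolk-sac days are non-increasing (endogenous feeding: weight loss)
    yolk = traj.stage == "yolk_sac"
    assert (np.diff(traj.dry_weight[yolk]) <= 0).all()


def test_trajectory_monotone_after_first_feeding(baseline, rng):
    for _ in range(5):
        traj = build_trajectory(baseline, rng)
        after = traj.days > traj.t_hatch + traj.t_ef
        w = traj.dry_weight[after]
        assert (np.diff(w) > 0).all()
        assert (traj.dry_weight > 0).all()


def test_stage_boundaries_continuous(deterministic_cfg, rng):
    """Evaluate each stage's formula at the shared boundary: equal within 1e-9."""
    traj = build_trajectory(deterministic_cfg, rng)
    cfg = deterministic_cfg
    t_ff = traj.t_hatch + traj.t_ef
    # power stage at its start equals w_ef
    w_power_start = traj.w_ef * (t_ff - t_ff + 1.0) ** cfg.k1
    assert w_power_start == pytest.approx(traj.w_ef, rel=1e-12)
    # exponential start equals power end at 20 dpef
    w20 = traj.w_ef * 21.0 ** cfg.k1
    w_exp_start = w20 * np.exp(traj.k2 * 0.0)
    assert w_exp_start == pytest.approx(w20, rel=1e-12)
    # exponential end at 60 dpef equals the juvenile curve there
    w60 = w20 * np.exp(traj.k2 * 40.0)
    juv60 = (1 - cfg.hf) * cfg.juvenile_growth.wet_weight(60.0) * traj.juvenile_factor
    assert w60 == pytest.approx(juv60, rel=1e-9)


def test_juvenile_weight_magnitude(deterministic_cfg, rng):
    # fl(60) = 41.20 + 2.37*60 mm -> wet weight ~90 g at 60 dpef
    wet = deterministic_cfg.juvenile_growth.wet_weight(60.0)
    assert wet == pytest.approx(90.0, rel=0.02)
    traj = build_trajectory(deterministic_cfg, rng)
    day60 = int(np.ceil(traj.t_hatch + traj.t_ef + 60))
    dry = traj.dry_weight[day60 - 1]
    assert dry == pytest.approx((1 - 0.85) * wet, rel=0.05)


def test_mean_daily_mortality_small_regime_value(baseline):
    # egg-sized larvae die at over 1 per day
    mu = float(mean_daily_mortality(42.8e-6, baseline))
    assert mu == pytest.approx(2.2e-4 * 42.8e-6 ** -0.85, rel=1e-12)
    assert mu == pytest.approx(1.14, abs=0.01)


def test_mcgurk_regimes_continuous_at_threshold(baseline):
    w = baseline.weight_threshold
    lo = float(mean_daily_mortality(w * (1 - 1e-9), baseline))
    hi = float(mean_daily_mortality(w, baseline))
    assert abs(lo - hi) / hi < 1e-3
    assert hi == pytest.approx(0.0197, abs=0.0002)


@given(st.floats(1e-7, 10.0), st.floats(1e-7, 10.0))
@settings(max_examples=60, deadline=None)
def test_mortality_monotone_decreasing_in_weight(w1, w2):
    from bluefinpriors import load_config
    cfg = load_config("abft_baseline")
    lo, hi = sorted([w1, w2])
    assert mean_daily_mortality(lo, cfg) >= mean_daily_mortality(hi, cfg) - 1e-15


def test_nonpositive_weight_rejected(baseline, rng):
    with pytest.raises(ValueError):
        mean_daily_mortality(0.0, baseline)
    with pytest.raises(ValueError):
        daily_mortality(np.array([1e-5, -1e-5]), baseline, rng)


def test_fert_hatch_loss_scales_agree(baseline, rng):
    # rate scale centred on -ln(0.5); survival scale converts with -ln(s)
    cfg = baseline.copy()
    cfg.fert_hatch_loss = constant(np.log(2.0))
    assert sample_fert_hatch_loss(cfg, rng) == pytest.approx(0.6931, abs=1e-4)
    cfg.fert_hatch_loss = constant(0.5)
    cfg.fert_hatch_scale = "survival"
    assert sample_fert_hatch_loss(cfg, rng) == pytest.approx(0.6931, abs=1e-4)


def test_M0_decomposition_identity(baseline, rng):
    d = draw_M0(baseline, rng)
    assert d.M_0 == pytest.approx(d.M_fh + d.M_d.sum(), rel=1e-12)
    assert d.M_d.shape == (baseline.early_life_horizon,)
    assert (d.M_d >= 0).all()
    assert 0 < d.S_0 < 1
    assert d.S_0 == pytest.approx(np.exp(-d.M_0))


def test_cumulative_mortality_front_loaded(baseline, rng):
    """Most of the year-0 mortality accrues within the first ~8 days."""
    fracs = []
    for _ in range(300):
        d = draw_M0(baseline, rng)
        cum = d.M_fh + np.cumsum(d.M_d)
        fracs.append(cum[7] / d.M_0)
    med = np.median(fracs)
    assert 0.7 < med < 0.9


def test_mean_daily_rate_low_by_day_30(baseline, rng):
    mus = np.array([mean_daily_mortality(build_trajectory(baseline, rng).dry_weight, baseline)
                    for _ in range(100)])
    assert mus[:, 29].mean() < 0.02


def test_residual_error_drives_dispersion(baseline, rng):
    """Without the regression residual, M_0 spread collapses to that induced
    by the duration/weight variables alone."""
    cfg_no = baseline.copy()
    cfg_no.mcgurk_error = False
    with_err = sample_M0(baseline, 400, np.random.default_rng(5))
    without = sample_M0(cfg_no, 400, np.random.default_rng(5))
    assert with_err.var() > 4 * without.var()


def test_m0_override_bypasses_growth_model(baseline, rng):
    cfg = baseline.copy()
    from bluefinpriors.distributions import normal
    cfg.m0_override = normal(12.5, 1.25, truncation=(0.0, None))
    draws = sample_M0(cfg, 2000, rng)
    assert abs(draws.mean() - 12.5) < 0.1
    assert abs(draws.std() - 1.25) < 0.1
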