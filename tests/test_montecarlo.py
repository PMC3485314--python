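import numpy as np
import pytest
from scipy import stats

from bluefinpriors import accept_reject, correlated_draws, run_ensemble, summarize
from bluefinpriors.montecarlo import EnsembleResult


def _tiny(**kw):
    kw.setdefault("n_draws", 150)
    kw.setdefault("k_pops", 60)
    kw.setdefault("pop_size", 300)
    return run_ensemble("abft_baseline", **kw)


def test_same_seed_identical_results():
    a = _tiny(seed=9)
    b = _tiny(seed=9)
    for att in ("M0", "r", "alpha", "W_bpr", "h"):
        np.testing.assert_array_equal(getattr(a, att), getattr(b, att))
    assert a.summary().equals(b.summary())


def test_different_seeds_differ():
    a = _tiny(seed=9)
    b = _tiny(seed=10)
    assert not np.array_equal(a.r, b.r)


def test_summary_shape_and_ordering(small_ensemble):
    tab = summarize(small_ensemble)
    assert list(tab.index) == ["M0", "W_bpr", "alpha", "r", "h"]
    assert list(tab.columns) == ["5%", "25%", "50%", "75%", "95%", "mean", "sd"]
    q = tab[["5%", "25%", "50%", "75%", "95%"]].to_numpy()
    assert (np.diff(q, axis=1) >= 0).all()


def test_summary_of_degenerate_arrays():
    c = np.full(40, 3.14)
    ens = EnsembleResult(M0=c, r=c, M0_pop=c, alpha=c, W_bpr=c, h=c)
    tab = summarize(ens)
    assert (tab.loc["r", ["5%", "50%", "95%", "mean"]] == 3.14).all()
    assert tab.loc["r", "sd"] == 0.0
    five = np.array([1.0, 2, 3, 4, 5])
    ens5 = EnsembleResult(M0=five, r=five, M0_pop=five, alpha=five, W_bpr=five, h=five)
    assert summarize(ens5).loc["r", "50%"] == 3.0
    assert summarize(ens5).loc["r", "mean"] == 3.0


def test_accept_reject_noop_when_all_valid():
    x = np.linspace(0.1, 1.0, 30)
    h = np.linspace(0.3, 0.99, 30)
    ens = EnsembleResult(M0=x, r=x, M0_pop=x, alpha=x, W_bpr=x, h=h)
    out = accept_reject(ens)
    np.testing.assert_array_equal(out.r, x)
    np.testing.assert_array_equal(out.h, h)
    assert out.rejection["r_rejected_fraction"] == 0.0


def test_accept_reject_filters_and_reports(small_ensemble):
    out = accept_reject(small_ensemble)
    assert (out.r >= 0).all()
    assert (out.h >= 0.2).all()
    exp_frac = (small_ensemble.r < 0).mean()
    assert out.rejection["r_rejected_fraction"] == pytest.approx(exp_frac)
    # truncation from below raises the mean
    assert out.r.mean() > small_ensemble.r.mean()
    # paired M0 values are filtered with their r draws
    assert len(out.M0) == len(out.r)


def test_accept_reject_empty_errors():
    x = np.array([-1.0, -2.0])
    ens = EnsembleResult(M0=x, r=x, M0_pop=x, alpha=x, W_bpr=x, h=x)
    with pytest.raises(ValueError):
        accept_reject(ens)


def test_draws_frame_layout(small_ensemble):
    df = small_ensemble.draws_frame()
    assert set(df["ensemble"]) == {"leslie", "population"}
    assert {"M0", "r", "alpha", "W_bpr", "h"} <= set(df.columns)


@pytest.mark.parametrize("rho", [0.7, 0.9])
def test_copula_preserves_marginals_and_hits_rho(rho):
    """Rank coupling must leave the M_0 marginal untouched (a permutation)
    and achieve the requested Spearman correlation with total fecundity."""
    ind = run_ensemble("abft_baseline", seed=21, n_draws=400, k_pops=50, pop_size=300)
    cor = correlated_draws("abft_baseline", rho, seed=21, n_draws=400, k_pops=50,
                           pop_size=300)
    # the coupled M_0 marginal is distributionally unchanged: the coupling is
    # a permutation of independent draws, so the two samples share one law
    ks = stats.ks_2samp(ind.M0, cor.M0)
    assert ks.pvalue > 1e-3
    q_ind = np.quantile(ind.M0, [0.05, 0.25, 0.5, 0.75, 0.95])
    q_cor = np.quantile(cor.M0, [0.05, 0.25, 0.5, 0.75, 0.95])
    np.testing.assert_allclose(q_cor, q_ind, rtol=0.10)
    assert cor.meta["achieved_rho"] == pytest.approx(rho, abs=0.05)
    # M_0 still dominates r under strong positive M0-fecundity coupling
    assert stats.spearmanr(cor.M0, cor.r).statistic < -0.9


def test_zero_correlation_recovers_independence():
    cor = correlated_draws("abft_baseline", 0.0, seed=23, n_draws=400, k_pops=50,
                           pop_size=300)
    assert abs(cor.meta["achieved_rho"]) < 0.12
    assert -1.0 <= stats.spearmanr(cor.M0, cor.r).statistic < -0.85


def test_invalid_correlation_rejected():
    with pytest.raises(ValueError):
        correlated_draws("abft_baseline", 1.5, seed=1, n_draws=50, k_pops=50,
                         pop_size=300)
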