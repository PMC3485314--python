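import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None,
                          database=None)
settings.load_profile("deterministic")

from bluefinpriors import load_config, run_ensemble
from bluefinpriors.config import JuvenileGrowth
from bluefinpriors.distributions import constant


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def baseline():
    return load_config("abft_baseline")


@pytest.fixture
def deterministic_cfg():
    """Baseline with every stochastic input pinned to its central value."""
    cfg = load_config("abft_baseline")
    cfg.mcgurk_error = False
    cfg.post_recruit_mortality_cv = 0.0
    cfg.length_cv = 0.0
    cfg.fert_hatch_loss = constant(float(np.log(2.0)))
    cfg.t_hatch = constant(1.5)
    cfg.t_ef = constant(3.0)
    cfg.w_ef = constant(21.7e-6)
    cfg.bf = constant(61.44)
    cfg.n_batch = constant(6.0)
    cfg.juvenile_growth = JuvenileGrowth(
        fl_intercept=41.20, fl_slope=2.37, lw_factor=1.92e-6,
        lw_exponent=3.39, weight_cv=1e-12,
    )
    return cfg


@pytest.fixture(scope="session")
def small_ensemble():
    """A shared reduced-scale baseline ensemble for distribution-shape tests."""
    return run_ensemble("abft_baseline", seed=101, n_draws=600, k_pops=200)
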