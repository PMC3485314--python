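"""Named sensitivity scenarios as declarative overrides of the baseline.

Each scenario is a set of (field path -> value) overrides applied to a
fresh copy of the configuration, so applying and discarding a scenario can
never contaminate the baseline. Field paths use dots for nested dataclass
attributes (``"mc.n_draws_r"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config import ConfigError, LifeHistoryConfig
from .distributions import DistributionSpec, constant, normal, uniform

__all__ = ["Scenario", "apply_scenario", "builtin_scenarios", "get_scenario"]


@dataclass(frozen=True)
class Scenario:
    id: str
    description: str
    overrides: dict = field(default_factory=dict)
    #: Spearman correlation between M_0 and total fecundity, for the
    #: correlated-sampling scenarios; None means independent sampling.
    rho: float | None = None


def _set_path(cfg: LifeHistoryConfig, path: str, value) -> None:
    parts = path.split(".")
    obj = cfg
    for p in parts[:-1]:
        if not hasattr(obj, p):
            raise ConfigError(f"scenario override targets unknown field {path!r}")
        obj = getattr(obj, p)
    leaf = parts[-1]
    if not hasattr(obj, leaf):
        raise ConfigError(f"scenario override targets unknown field {path!r}")
    if obj is cfg:
        setattr(cfg, leaf, value)
    else:
        # nested frozen dataclasses are replaced wholesale
        parent = cfg
        for p in parts[:-2]:
            parent = getattr(parent, p)
        setattr(parent, parts[-2], replace(obj, **{leaf: value}))


def apply_scenario(cfg: LifeHistoryConfig, scenario: Scenario) -> LifeHistoryConfig:
    """Deep-merged copy of ``cfg`` with the scenario's overrides applied."""
    out = cfg.copy()
    for path, value in scenario.overrides.items():
        if callable(value) and not isinstance(value, DistributionSpec):
            value = value(cfg)
        _set_path(out, path, value)
    out.validate()
    return out


def _scaled_mortality(factor: float):
    return lambda cfg: cfg.post_recruit_mortality_means * factor


def _western_ogive(cfg: LifeHistoryConfig) -> np.ndarray:
    g = np.zeros(cfg.terminal_age)
    g[8] = 0.5      # age 9
    g[9:] = 1.0
    return g


def _informative_m0(mean: float) -> DistributionSpec:
    return normal(mean, 0.10 * mean, truncation=(0.0, None), units="year^-1")


def builtin_scenarios() -> list[Scenario]:
    """All shipped sensitivity scenarios (baseline included)."""
    sc = [
        Scenario("baseline", "Baseline parameterization, all traits stochastic."),
        Scenario("tef_fixed_2",
                 "Yolk-sac duration fixed at 2 days (lower bound).",
                 {"t_ef": constant(2.0, units="days")}),
        Scenario("tef_fixed_4",
                 "Yolk-sac duration fixed at 4 days (upper bound).",
                 {"t_ef": constant(4.0, units="days")}),
        Scenario("western_maturity",
                 "Western-stock maturity schedule: 50% mature at age 9, "
                 "fully mature from age 10.",
                 {"maturity_ogive": _western_ogive}),
        Scenario("reduced_fecundity",
                 "Reproduction frequency ~ U(0.25, 0.33) replacing 1/Spe and "
                 "N_batch ~ U(2, 5).",
                 {"spawning_frequency": uniform(0.25, 0.33, units="1/year"),
                  "n_batch": uniform(2.0, 5.0, units="batches")}),
        Scenario("mortality_scale_0.9",
                 "Post-recruit mortality means reduced by 10%.",
                 {"post_recruit_mortality_means": _scaled_mortality(0.9)}),
        Scenario("mortality_scale_0.8",
                 "Post-recruit mortality means reduced by 20%.",
                 {"post_recruit_mortality_means": _scaled_mortality(0.8)}),
        Scenario("terminal_age_20",
                 "Terminal age 20 instead of 30 (schedules truncated).",
                 {"terminal_age": 20,
                  "post_recruit_mortality_means":
                      lambda cfg: cfg.post_recruit_mortality_means[:20],
                  "maturity_ogive": lambda cfg: cfg.maturity_ogive[:20]}),
        Scenario("informative_M0_low",
                 "M_0 drawn from N(12.5, CV 10%) instead of the growth-"
                 "mortality integration.",
                 {"m0_override": _informative_m0(12.5)}),
        Scenario("informative_M0_mid",
                 "M_0 drawn from N(18.5, CV 10%).",
                 {"m0_override": _informative_m0(18.5)}),
        Scenario("informative_M0_high",
                 "M_0 drawn from N(21.5, CV 10%).",
                 {"m0_override": _informative_m0(21.5)}),
        Scenario("informative_M0_mid_text",
                 "M_0 drawn from N(17.5, CV 10%) (alternative mid mean).",
                 {"m0_override": _informative_m0(17.5)}),
        Scenario("informative_M0_high_text",
                 "M_0 drawn from N(19.5, CV 10%) (alternative high mean).",
                 {"m0_override": _informative_m0(19.5)}),
        Scenario("correlated_rho_0.7",
                 "M_0 and total fecundity rank-coupled at Spearman 0.7.",
                 rho=0.7),
        Scenario("correlated_rho_0.9",
                 "M_0 and total fecundity rank-coupled at Spearman 0.9.",
                 rho=0.9),
        Scenario("cv_25_sensitivity",
                 "CV raised to 25% on the fertilization/hatching loss and the "
                 "post-recruit mortality schedule.",
                 {"fert_hatch_loss":
                      lambda cfg: DistributionSpec(
                          "normal",
                          (cfg.fert_hatch_loss.params[0],
                           0.25 * cfg.fert_hatch_loss.params[0]),
                          truncation=(0.0, None),
                          units=cfg.fert_hatch_loss.units),
                  "post_recruit_mortality_cv": 0.25}),
    ]
    return sc


_BY_ID = None


def get_scenario(scenario_id: str) -> Scenario:
    global _BY_ID
    if _BY_ID is None:
        _BY_ID = {s.id: s for s in builtin_scenarios()}
    try:
        return _BY_ID[scenario_id]
    except KeyError:
        raise ConfigError(
            f"unknown scenario {scenario_id!r}; available: {sorted(_BY_ID)}"
        ) from None
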