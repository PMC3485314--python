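"""Sensitivity scenarios, correlated sampling, and corrected Bayesian priors.

Shows three ways of stressing the baseline: a named scenario (delayed
western-stock maturity), rank-coupling M_0 with total fecundity through a
Gaussian copula, and the acceptance-rejection correction that discards
draws inconsistent with the downstream assessment models (r < 0, h < 0.2).
"""

import numpy as np

from bluefinpriors import accept_reject, builtin_scenarios, correlated_draws, run_ensemble

print("built-in scenarios:", ", ".join(s.id for s in builtin_scenarios()))

base = run_ensemble("abft_baseline", seed=0, n_draws=1500, k_pops=300)
west = run_ensemble("abft_baseline", scenario="western_maturity",
                    seed=0, n_draws=1500, k_pops=300)
print(f"\nr median: baseline {np.median(base.r):.2f} -> "
      f"maturity at age 9: {np.median(west.r):.2f}")
print("delaying maturity by five years costs about 0.2 in median growth rate.")

cor = correlated_draws("abft_baseline", rho=0.9, seed=0, n_draws=1500, k_pops=300)
from scipy import stats
print(f"\ncoupling M_0 with fecundity at Spearman 0.9 "
      f"(achieved {cor.meta['achieved_rho']:.2f}): "
      f"r sd {base.r.std():.2f} -> {cor.r.std():.2f}, "
      f"Spearman(M_0, r) = {stats.spearmanr(cor.M0, cor.r).statistic:.2f}")
print("high fecundity partially offsets high M_0, narrowing r a little, but "
      "M_0 still dominates the prior.")

ar = accept_reject(base)
print(f"\naccept-reject (r >= 0, h >= 0.2): rejected "
      f"{ar.rejection['r_rejected_fraction']:.0%} of r draws, "
      f"{ar.rejection['h_rejected_fraction']:.0%} of h draws")
print(f"corrected priors: r mean {ar.r.mean():.2f} (sd {ar.r.std():.2f}), "
      f"h mean {ar.h.mean():.2f} (median {np.median(ar.h):.2f})")
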