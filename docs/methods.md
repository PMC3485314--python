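# Methods

`bluefinpriors` elicits Bayesian prior distributions for two demographic
parameters of an exploited fish population — the intrinsic population
growth rate *r* of the surplus-production (biomass-dynamic) model and the
steepness *h* of the Beverton–Holt stock–recruitment relationship — by
Monte-Carlo propagation of life-history uncertainty. The shipped baseline
is the Atlantic bluefin tuna (*Thunnus thynnus*); every quantity is
configurable, so other long-lived, highly fecund teleosts can be
parameterized the same way.

## Model overview

A single Monte-Carlo draw realizes the full life cycle:

1. **Age-0 mortality** M₀ = M_fh + Σₓ M_d(x): a fertilization-plus-hatching
   loss (centred on −ln 0.5, i.e. a 50% loss of expelled oocytes) plus 180
   daily instantaneous rates, x counted in days after fertilization.
2. **Post-recruit vital rates**: a mortality-at-age vector M(i) around the
   ICCAT-style schedule (0.49 in year 1, declining to 0.1 from age 9),
   von Bertalanffy lengths L(i) (L∞ = 314.9 cm, k = 0.089 yr⁻¹,
   t₀ = −1.13), weights W = 1.96·10⁻⁵·L^3.0092 kg, a maturity ogive (50%
   at age 4), and fecundity at age.
3. **Growth rate**: a Leslie matrix with fecundities F(i) in the first row
   and survivals on the sub-diagonal; r = ln λ with λ the dominant
   eigenvalue.
4. **Steepness**: a simulated unfished population of N individuals gives
   α = e^(−M₀)·F_sim/B_sim (recruits per kg of spawning biomass), the
   per-recruit spawning biomass W_bpr = Σ l(a)·W_f(a)·g(a), and
   h = ā/(4 + ā) with ā = α·sr·W_bpr.

The r ensemble uses 10000 draws; the h ensemble uses K = 1000 replicate
populations of N = 1000 individuals. N is not critical: for fixed vital
rates, α is a ratio of population sums and is insensitive to N beyond
~1000 (tested).

## Early-life growth and mortality

Daily dry weight w_d(x) is pieced together over five stages, continuous at
every boundary:

| stage | span | form |
|---|---|---|
| incubation | x ≤ t_hatch | constant w_egg = 42.8·10⁻⁶ g |
| yolk sac | t_hatch < x ≤ t_hatch + t_ef | linear decline to w_ef |
| early larva | 0–20 dpef | w_ef·(d+1)^k₁, k₁ = 1.851 |
| late larva | 20–60 dpef | exponential, rate k₂ solved to meet the juvenile curve at 60 dpef |
| juvenile | to day 150 | (1−h_f)·1.92·10⁻⁶·fl(d)^3.39 g, fl(d) = 41.20 + 2.37·d mm |

with t_hatch ~ U(1, 2) d, t_ef ~ U(2, 4) d, w_ef ~ N(21.7, 4)·10⁻⁶ g
(truncated positive), and dpef = days post exogenous feeding. From day 150
to day 180 the weight interpolates linearly to the age-1 von Bertalanffy
weight (converted to dry weight with the hydration factor h_f = 0.85,
i.e. dry = 0.15·wet — wet fish are ~85% water; we state the direction
because the sources do not).

Daily mortality follows the two-regime allometric regression
μ(w) = a·w^b (a = 2.2·10⁻⁴, b = −0.85) below 0.00504 g dry and
μ(w) = a′·w^b′ (a′ = 5.26·10⁻³, b′ = −0.25) above it; the two branches
agree to 0.1% at the threshold (≈0.0197 d⁻¹). The realized rate is
μ·exp(Z) with Z ~ N(0, σ) (σ = 0.80 / σ′ = 0.86) **drawn independently
each day**. This is the single most consequential numerical choice: about
eight early days carry rates above ~1 d⁻¹, and independent lognormal
residuals on those days give the M₀ ensemble its sd of ≈4.6 yr⁻¹; a
residual shared across days would roughly triple that spread, and
disabling it collapses the spread entirely (both behaviours are tested).
Roughly 80% of M₀ accrues within the first 8 days.

Juvenile between-individual size variability (CV 0.1 on the juvenile
weight curve) is realized as **one multiplicative deviate per cohort
draw**, not per day: per-day noise would break the monotonicity of an
individual growth path, and the variability being emulated is between
individuals, not within a trajectory.

Design choices where the sources are ambiguous, all selectable in the
configuration rather than silently reconciled:

* the fertilization/hatching loss is drawn on the instantaneous-rate scale,
  M_fh ~ N(ln 2, 0.1·ln 2); a survival-scale alternative
  (s ~ N(0.5, 0.05), M_fh = −ln s) is shipped;
* incubation bounds default to (1, 2) d; a wider (0.77, 2) variant exists
  (`abft_table_variant` preset);
* batch count N_batch ~ U(2, 10) by default; a U(1, 10) spec is available;
* mortality accrues from day 1 (eggs are exposed during incubation);
* the power-growth stage is anchored so the curve equals w_ef on the first
  feeding day (only the exponent is published; the anchoring is ours);
* fl(x) takes x in dpef and returns mm, which puts late-juvenile wet
  weights at O(100 g) — consistent with the mortality magnitudes.

## Fecundity and spawning periodicity

Annual fecundity is f_A(i) = bf·(1000·W_f(i))·N_batch oocytes, with the
relative batch fecundity bf ~ N(61.44, 48.33) oocytes·g⁻¹ truncated at
zero (roughly 10% of untruncated mass is negative, which is biologically
impossible), and all oocytes counted as eggs. The Leslie fecundity entry is

F(i) = sr·g(i)·f_A(i)·Rf,

where Rf is the reproduction frequency accounting for skip-spawning (the
spawning periodicity Spe is 1–4 years with equal probability). Because a
Leslie matrix entry is by definition an *expected* annual rate, the default
uses Rf = E[1/Spe] = 25/48 ≈ 0.521 (`spe_mode="expected"`); drawing Spe
once per cohort (`spe_mode="sampled"`) is available and pushes the
skip-spawning variability between draws instead. The expected mode is also
the one whose r ensemble reproduces the published summary quantiles.

## Leslie matrix conventions

The pipeline uses the collapsed A×A matrix: first row F(i)·e^(−M₀),
survivals S(1..A−1) on the sub-diagonal (prebreeding census). An explicit
age-0 representation is provided as the postbreeding-census matrix whose
first-row entries are s_j·F(j+1) (survive the year, then spawn); this is
the unique age-0-explicit layout with the same nonzero spectrum as the
collapse, so r is convention-independent — a property the test suite
verifies. Note that the naive layout one might write first (raw F(i) in
the first row above a sub-diagonal starting with e^(−M₀)) is *not*
equivalent: it inserts a spurious extra year between spawning and
recruitment and biases r low.

The dominant eigenvalue comes from a dense eigen-decomposition by default;
a power-iteration alternative (tolerance 10⁻¹⁰) agrees to 10⁻⁸ on random
valid matrices. Negative r values are retained in the raw ensemble — they
are meaningful before the prior correction.

A useful identity: the net reproductive rate of a draw,
R₀ = Σ l(a)·F(a)·e^(−M₀), equals ā = α·sr·W_bpr computed from the same
vital rates. Hence r < 0 ⟺ λ < 1 ⟺ R₀ < 1 ⟺ h < 0.2: the two
acceptance-rejection conditions are the same biological statement
(replacement-level recruitment), applied to the two sub-ensembles.

## Ensembles, correlated sampling, prior correction

The two sub-ensembles (Leslie draws; population replicates) are disjoint,
each deterministic given the seed. Summaries report 5/25/50/75/95%
quantiles (linear interpolation between order statistics), mean, sd, and
Spearman correlations.

Correlated sampling couples M₀ with total fecundity through a Gaussian
copula at a requested Spearman ρ (latent Pearson 2·sin(πρ/6)): the two
independent marginal ensembles are re-paired by rank, so each marginal is
preserved exactly (a permutation) while the joint attains ρ to within
sampling error; r and h are recomputed on the coupled pairs.

The acceptance-rejection correction keeps r ≥ 0 in the r ensemble and
h ≥ 0.2 in the h ensemble (values below these bounds contradict the
assumptions of the models the priors feed) and reports rejected fractions.
Because the sub-ensembles are disjoint, per-quantity and joint rejection
rules coincide here.

## What the generator emulates — and what it does not

The synthetic machinery reproduces between-cohort variability in early
survival, growth and reproduction as *independent* stochastic inputs
(optionally rank-coupled as above). It does not model density dependence
(the allometric mortality-size relationship integrates density-dependent
and density-independent mortality without separating them), temperature
forcing of incubation (the U(1, 2)-day bound encodes it), sexual
dimorphism in growth, or age-dependent skip-spawning. Passing tests
therefore demonstrate faithful uncertainty propagation through the stated
life-history model — not that the real stock's recruitment obeys it.

## Numerical notes and degenerate inputs

Truncated distributions are rejection-sampled; a truncation region holding
under 10⁻⁶ probability mass raises instead of looping. Stage boundaries
fall on fractional days and each integer day takes the stage of the
interval containing it. A zero or non-finite weight anywhere in a
trajectory, an all-immature population, a zero spawning biomass, and a
zero projection matrix all raise with the offending stage or field named.
Quantile method, seeds, draw counts and the configuration hash are
recorded in run manifests.

## Problem sizes

Full scale is 10000 Leslie draws and K = 1000 populations of N = 1000
individuals (about a minute in total). Unit and property tests run at
reduced scale (hundreds of draws); the full-scale checks live in the
acceptance tests and `scripts/acceptance.py`.

## Known limitations

* The M₀ spread conditional on a fixed yolk-sac duration grows with that
  duration (sd ≈3.8 at t_ef = 2 d vs ≈4.7 at t_ef = 4 d): the extra
  high-mortality days mechanically add lognormal-residual variance. Claims
  that these conditional spreads are equivalent hold only qualitatively.
* The fraction of steepness draws below 0.2 (~0.16–0.18) exceeds the
  high-M₀ tail probability P(M₀ > 18) ≈ 0.13 because low-fecundity draws
  (bf has CV ≈ 0.79) also depress α.
* α has an extremely heavy right tail; its mean is unstable across seeds
  and only the quantiles are meaningful summaries.
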