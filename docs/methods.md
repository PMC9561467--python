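# Methods

This note documents the models, the synthetic data-generating processes
(DGPs), the numerical choices, and the known limitations of the `ehra`
package.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The equity index

Each province-year's equity of healthcare resource allocation is a weighted
combination of four inequality indices computed across the province's
cities: medical institutions per km², and beds, licensed doctors, and
registered nurses per 1,000 residents.  Design choices:

* **Log base.**  The Theil-T index uses the natural logarithm (the standard
  convention); the base only rescales the index and cannot change rankings.
  This is an interpretive choice — the printed formula does not fix it.
* **City weighting.**  Cities enter with equal weight 1/n, exactly as the
  index formula is written, not population-weighted.  A population-weighted
  variant would be a reasonable extension but is deliberately out of scope.
* **Entropy weighting is pooled.**  The entropy weights are fit once on the
  pooled province-year × indicator matrix, not per year, so the composite
  is comparable over time.  Per-year weighting would let the meaning of the
  index drift across waves.  This too is interpretive: either reading is
  consistent with how such indices are usually described.
* **Zero convention.**  0·ln 0 = 0 throughout (Theil terms and entropy
  shares).  A constant indicator column carries no information and receives
  entropy weight 0; if *every* column is constant the weights fall back to
  equal shares with a logged warning.
* **Gini.**  Implemented with the sorted-rank formula (O(n log n)); the
  O(n²) pairwise-difference formula serves as the test oracle.

**Missing-data rules.**  City series with gaps are completed by linear
interpolation between the nearest observed years; leading/trailing gaps are
extrapolated with the geometric mean of the observed year-over-year growth
ratios.  Growth extrapolation is undefined when observed values are
non-positive; the code then carries the nearest observed value and logs a
warning.  At least two observed values are required per series.

## Synthetic panels

The generator runs the analysis models *forward* so that every downstream
stage can be checked against recorded ground truth.

* **Dimensions.**  22 provinces × 10 years, 5–21 cities per province
  (uniform draw, fixed over time), matching the scale of the provincial
  panels such studies assemble.
* **Covariates.**  Marginal means/SDs default to the published provincial
  summary statistics (e.g. FASG 0.4820/0.1597, PGDP 10.6344/0.3669).  PGDP,
  PD, and AHRH are generated on the natural-log scale — magnitudes like a
  "per-capita GDP" of 10.63 only make sense logged.  FASG follows a
  stationary AR(1) with persistence 0.8 clipped to (0.05, 0.95), so its
  one-year lag is a strong instrument, mirroring the lag-IV design; the
  other covariates use persistence 0.5.  FASG is bounded inside (0, 1):
  provinces whose own revenue exceeds expenditure are not represented
  (their published summary statistics do not indicate any).
* **Index equation.**  THEIL = 0.1391 − 0.0849·FASG + Σ δₗXₗ + φᵢ + ωₜ + ε
  with province effects of SD 0.05, year effects of SD 0.005, and
  idiosyncratic noise σ_ε = 0.01.  The fixed-effect and noise scales were
  set from the published per-province index summaries: between-province
  spread of the index mean is ≈ 0.05 while within-province year-to-year SDs
  are 0.005–0.018.  The control coefficients default to the published
  baseline estimates.
* **Threshold mode** replaces β·FASG by regime-specific coefficients
  β₁·FASG·I(q ≤ γ) + β₂·FASG·I(q > γ).  The threshold variable's *own*
  linear effect is set to zero in this mode because the estimating equation
  excludes it from the controls; keeping it would make every recovery
  simulation a test of a misspecified model.
* **Mediators.**  IGHE (government share of health expenditure) and AHRH
  (log health workforce) are generated with their own fixed effects and a
  configurable FASG effect (defaults +0.0474 and +0.1079).
* **Alternative indices.**  The CV and GINI columns of the generated
  province panel are noisy monotone companions of THEIL (correlation 0.9,
  published means/SDs) standing in for the alternative index constructions
  used as robustness dependent variables.
* **Prefecture resources.**  City log per-capita (per-km² for
  institutions) rates are drawn around province-year means with an SD given
  by a per-cell dispersion driver; for lognormal rates the Theil index is
  ≈ σ²/2, so the computed composite is monotone in the driver.  Counts are
  rounded to integers, which leaves a ≤ 1e-6 composite residual even at
  zero dispersion.
* **What the generator does not emulate:** spatial correlation between
  provinces, measurement error in yearbook counts, the GDP-deflator
  treatment of nominal series, and administrative boundary changes.
  Passing tests therefore demonstrate correctness of the *methods*, not
  robustness to those real-data features.

## Panel estimators

* **Fixed effects** are estimated by iterated unit/time demeaning
  (tolerance 1e-10; one sweep suffices on balanced panels) with a
  degrees-of-freedom correction for the absorbed effects.  Point estimates
  are identical to dummy-variable OLS; the test suite asserts agreement to
  1e-10 on random balanced and unbalanced panels.
* **Random effects** use Swamy–Arora-style variance components (within
  residual variance + between regression), with time effects entering as
  dummies when requested.
* **The "three problems" covariance** (heteroscedasticity, autocorrelation,
  cross-sectional correlation) is implemented as a Driscoll–Kraay kernel
  estimator: per-period cross-sectional score sums smoothed over time lags
  with a Bartlett kernel, lag window ⌊4(T/100)^{2/9}⌋ + 1.  Classical and
  cluster-by-unit covariances are selectable for comparison.  *Known
  small-T limitation:* with two-way fixed effects the T score vectors sum
  to zero, so at T = 10 the kernel variance is biased downward (kernel SEs
  sit ≈ 25–30% below classical ones even under iid errors); the estimator
  is well behaved by T ≈ 40, and confidence intervals should use t(T−1)
  quantiles.  The covariance calibration tests therefore run at T = 40.
* **Hausman** uses a pseudo-inverse of V_FE − V_RE and rank-based degrees
  of freedom, with the statistic floored at zero: in small panels the
  variance difference is frequently indefinite.  When the random-effects
  model is *grossly* wrong its estimated variance can exceed the FE
  variance and the statistic truncates — power is non-monotone in the
  degree of misspecification.  The calibration test uses 50 units and
  moderate effect-regressor correlation, inside the regime where the
  classical form is informative.
* **2SLS** instruments the key regressor with its one-year lag inside the
  within transformation (N×T input → N×(T−1) observations, 220 → 198 at
  the study scale).  A first-stage F below 10 logs a weak-instrument
  warning rather than failing.  *Known small-T limitation:* demeaning puts
  all periods into the unit mean, so with persistent regressors the lagged
  instrument carries an O(1/T) Nickell-type bias; the bias-reduction
  demonstration runs at T = 40, where 2SLS removes ≳ 80% of the OLS bias.

## Panel unit-root battery

LLC (pooled ADF t with per-unit standardization), IPS (standardized mean of
per-unit ADF t), and Fisher-ADF / Fisher-PP (P = −2Σ ln pᵢ ~ χ²(2N)) with
H0 "unit root" throughout; the per-variable verdict is stationary iff at
least 3 of 4 tests reject (a 2–2 tie counts as non-stationary).  The ADF
lag order is fixed by the configured (c, t, l) triple (default lag 1), not
information-criterion selected, for determinism.

**Calibration constants are simulated, not tabulated.**  Null means and
variances of the pooled and per-unit t statistics, and the per-unit null
CDFs behind the Fisher p-values, are obtained by simulating driftless
random walks under H0 (20,000 unit-level / 4,000 panel-level draws) with a
fixed internal seed, once per (T, lag, deterministic) configuration, and
cached.  At T = 10 the asymptotic moment and p-value approximations are
visibly biased, and any miscalibration of per-unit p-values is *amplified*
by the 22-unit Fisher combination; a simulated finite-sample null keeps
every test's size at its nominal level by construction (measured size
0.02–0.06, power 0.92–1.0 at 22 × 10).

**The screen is advisory by default.**  At T = 10 the battery has little
power against stationary-but-persistent series such as the AR(0.8) FASG
path, so the pipeline's default is to warn and proceed
(`allow_nonstationary=True`); setting it to `False` restores the hard
refusal for users who want the screen enforced.

## Threshold model

Estimation searches the observed values of the threshold variable between
the 5% trim quantiles, skipping candidates that would leave either regime
with under 5% of observations (neither the trim nor the occupancy rule is
dictated by the source analysis; both are conventional practice and prevent
degenerate regimes).  SSR is piecewise constant between observed values, so
an interpolated lattice would add nothing.  Argmin ties break toward the
smaller candidate.  A second threshold is found by a conditional search
holding the first fixed, followed by exactly one refinement pass of the
first — the standard sequential shortcut; a joint O(grid²) search is
unnecessary.

Implementation: all candidate regime columns x·I(q ≤ γ) are projected off
the fixed effects and controls once; every subsequent SSR — including the
full grid search inside each bootstrap replicate — is evaluated from the
Gram matrix of the projected columns (2×2 or 3×3 solves), which makes a
100 × 100 bootstrap size study a matter of seconds.

The threshold-effect test is a residual bootstrap (default 300 replicates;
calibration studies use 100): regressors and estimated fixed effects are
held fixed, the dependent variable is regenerated under the null from iid
resampled residuals, and the full search is re-run per replicate.  For the
second-threshold test the first threshold is held at its sample estimate
inside replicates.  σ̂² = SSR_alt/(n − k − absorbed) throughout, including
the LR profile LR(γ) = (S(γ) − S(γ̂))/σ̂² whose 95% inversion uses
c = −2 ln(1 − √0.95) ≈ 7.35.

Two properties deserve emphasis:

* **The equation omits the threshold variable's linear term.**  If the
  variable truly enters the linear model, the regime split partially
  proxies the omitted effect and the bootstrap F test *correctly* rejects
  the (misspecified) linear null — on the default synthetic study this is
  visible as significant splits on PD and DR.  Size simulations therefore
  use a null DGP in which the threshold variable's own effect is zero, the
  only DGP under which H0 actually holds.
* **Threshold-location precision is Op(1) in rank terms.**  The SSR argmin
  identifies γ exactly in the noise-free case, but under noise the estimate
  lands within a few *observed values* of the truth (compound-Poisson
  limit theory): at the default noise on 60 × 20 panels the median
  |γ̂ − γ| is ≈ 0.0004 (0.6% of the threshold variable's SD), within 3
  observed ranks ≈ 90% of the time, but in the *exact* adjacent grid cell
  only ≈ 50% of the time.  Exact-cell recovery is not an attainable target
  at this signal-to-noise ratio; interval statements should come from the
  LR confidence set.

## Pipeline and reproducibility

All randomness flows from one integer seed; bootstrap sub-seeds are derived
deterministically per threshold variable.  Reports contain no timestamps;
`provenance.json` records a SHA-256 hash of the canonical YAML config, the
seed, and library versions, so a fixed configuration reproduces every table
byte for byte.  Significance stars follow the 1/5/10% convention (a/b/c)
with SEs in parentheses; the per-province index table ranks provinces by
ascending mean (rank 1 = most equitable).  The full default study (index
construction, unit roots, six baseline columns, 2SLS, four robustness
columns, two mechanism fits, three threshold analyses at 100 bootstrap
replicates) runs in a few seconds on one CPU.

## Problem sizes used in the validation suite

Chosen to make each check informative at interactive runtimes: 1,000
random vectors for the index oracles; 50 random panels for the FE/LSDV
equivalence; 200 replicates at 22 × 10 for coefficient recovery and CI
coverage; 100 replicates at 60 × 20 for threshold recovery; 100 outer × 100
bootstrap replicates for threshold-test size (50 outer for power); 200
replicates for 2SLS bias comparison and for unit-root size/power.
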