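# Methods

This note documents the models, the synthetic study design, the numerical
choices, and the limits of what the test suite demonstrates.

## Data model and transition scoring

A census table has one row per tagged plant per year with `stage` in
{seedling, vegetative, flowering} and `size` = ln taproot diameter (mm),
present exactly for vegetative plants (seedlings are tagged but not
measured; flowering plants die the year they flower).  Transitions are
built per plant from consecutive censuses:

- A plant seen at t and at t+1 survived; it flowered if its t+1 stage is
  flowering.  Seedling → vegetative transitions contribute both an `S1`
  success and a first-size (`D`) observation.
- A plant re-found after a gap is treated as alive through the gap.  Gap
  years yield survival credit but carry no sizes, so they contribute
  nothing to the size-dependent models — no size is ever fabricated.
- A plant never seen again is scored dead in its first missing year.  In
  the field, three missing years build confidence in that call; in the
  analysis the rule is applied to terminal absences of any length, because
  censoring short terminal absences would keep their survivors (seen
  later) while dropping their deaths, biasing final-year survival toward 1
  and inflating the apparent year-to-year variance.

## Vital-rate models

`S1`, `S2`, `A` are Bernoulli with a logit link; `G`, `D` are Gaussian.
Size (ln mm, centered on the fitted data's mean; the constant is stored
and undone in reporting) is a fixed effect for `S2`, `G`, `A`.  The only
random term is the year-by-zone interaction: intercept-only for the
size-independent rates, correlated intercept + size-slope pairs for the
size-dependent ones.  Separate year and zone random effects are
deliberately omitted — they would shrink zones moving in opposite
directions within a year toward a common mean, which is precisely the
signal under study.  A slope-only random term cannot produce between-cell
level differences, so the pair includes the intercept.

Estimation: Bernoulli models use a package-authored Laplace-approximation
ML fitter (penalized Newton for the joint mode, block-diagonal
log-determinant correction, variance parameters optimized on a
transformed scale with the correlation clipped to |ρ| ≤ 0.995 to keep
singular fits finite).  The Gaussian growth model is fit by statsmodels
`MixedLM`; the size-independent Gaussian rate uses a profiled-ML
random-intercept solver.  Complete separation (constant response) raises
an error rather than returning a divergent coefficient.  Wald standard
errors are conditional on the estimated variance parameters, the standard
mixed-model approximation; the acceptance suite verifies ≥ 90% empirical
coverage of nominal 95% intervals under the generator.

Recruitment is the ratio estimator `r_zone = Σ_t seedlings(t+1) /
Σ_t flowering(t)`, pooled over years so that years with flowering plants
but no seedlings (or vice versa) do not produce divisions by zero.

## Integral projection model

State ordering (seedlings, m size bins, adults); one annual step couples
`n(z', t+1) = S(t)·s1·d(z') + ∫ s2(z)(1−a(z))G(z',z)n(z,t)dz`,
`S(t+1) = r·A(t)`, `A(t+1) = ∫ s2(z)a(z)n(z,t)dz`, and every adult dies
after reproduction.  Numerical choices:

- Midpoint rule, m = 200 bins by default; mesh bounds extend the observed
  size range by 20% of that range on each side (the alternative reading —
  ±20% of each endpoint's value — is available as `mode="endpoint"`).
- Growth and first-size kernels are Gaussian densities truncated to the
  mesh by renormalizing each discretized column to unit mass, which
  enforces the column-mass identity (continuous-block column sums equal
  `s2(z)(1−a(z))`) to machine precision and removes eviction exactly.
- λ by power iteration on the (m+2)-vector.  Successive growth-rate
  differences underestimate the remaining error when subdominant
  eigenvalues are close or complex, so convergence requires the
  geometric-tail error bound estimated over a 6-iteration window to fall
  below the tolerance (default 1e-8); a verified margin keeps the realized
  error well inside it.  Imprimitive (cyclic) kernels are reported as
  non-convergent, not silently returned.
- Cells missing from any vital-rate fit yield no kernel and are reported
  as NaN, never imputed; zones with no flowering plants in a given year
  still get the pooled zone recruitment.

## Synchrony and portfolio effect

All variances use the sample (n−1) denominator — the choice cancels in φ
but not in the scaling regression, so it is fixed rather than
configurable.  Taylor's law is fit by OLS on natural logs across zones
(≥ 3 zones required for residual degrees of freedom).  The portfolio
effect extrapolates the fitted law to the mean total abundance:
`PE = exp(β₀ + z·log E(N_total)) / Var_obs(N_total)`.  PE compares the
observed total variance against a synchronous-scaling benchmark: if
variance scales with the mean with z near 2 (constant CV), independent
zone fluctuations push PE above 1, while with z near 0 (equal absolute
variance regardless of mean) PE drops below 1 — PE is only interpretable
jointly with the fitted z.  Pairwise zone correlations use Pearson r with
two-sided t-tests and no multiple-testing correction by default (a
correction option exists), matching per-pair reporting conventions.

## Sliding-window scan

Candidate model per rate: family as above, fixed effects = zone indicators
(+ size for size-dependent rates) + one climate slope per zone, random
intercept per transition year.  The per-zone-slope parameterization spans
the same space as main-effect + interaction contrasts and reads the
climate-by-zone interaction off directly.  The covariate is the mean
monthly anomaly (per-calendar-month z-score against a reference period,
sample-SD denominator) over a window of 0–36 month offsets anchored at
June 30 of the transition's second year; all (open ≥ close) offset pairs
give 703 windows, five variables are scanned one at a time, and the
winner minimizes AICc = AIC + 2k(k+1)/(n−k−1) with k counting every
estimated parameter including variance components.  Windows whose
covariate is constant across years are flagged and excluded, not fit.
Exact AICc ties break deterministically: shorter window, then more recent,
then variable order.

Because the randomization test refits thousands of candidates, the scan
uses a batched fitter: all candidate designs (which differ only in their
climate columns) are stacked and estimated simultaneously, with the
random-intercept SD profiled on a shared log grid followed by two
quadratic refinements.  The scalar reference fitter and the batched path
agree to ≲ 1e-3 AICc, far below selection-relevant differences; baseline
and candidates always use the same fitter so ΔAICc is internally
consistent.  The size-independent Bernoulli rate is aggregated to
per-(year, zone) binomial counts — every fixed covariate is cell-constant,
so the Bernoulli likelihood is reproduced exactly at a fraction of the
rows.

The randomization test permutes biological years against climate years as
whole blocks (record-level shuffling would destroy the within-year
dependence the random intercept models), reruns the full scan per
permutation, and reports the add-one estimator
`p = (1 + #{null best ΔAICc ≤ observed}) / (n_perm + 1)`.  The baseline
has no climate term and is invariant under the permutation, so it is
computed once.  Null best-ΔAICc values are often strongly negative even
with climate decoupled — free zone-by-year slope terms soak up genuine
zone-by-year variance that the baseline cannot — which is exactly why the
observed support must be referred to this null rather than to zero.

## Attribution

For each rate, the best scan model's per-zone climate slopes are paired
with the Pearson correlation between that zone's yearly cell-prediction
series and zone 1's (predictions at the mean size for survival and
growth, mean + 1 SD for flowering, whose variation is invisible at small
sizes).  Zone 1's own point (its coefficient, r = 1) is included by
default.  A least-squares line with a two-sided slope test is fit per
rate, not pooled.  Note the expected sign under the package's generator:
zone 1 responds negatively to the driver, so zones correlated with it have
negative coefficients and the regression slope is negative; the
substantive claim is the significance of the association, not its sign,
which simply mirrors the reference zone's response direction.

## Synthetic study design

The generator emulates the assumed field design: 5 zones × 17 annual June
censuses, initialized with 60 vegetative plants per zone (first sizes from
the new-plant distribution truncated to positive ln-size), Poisson
recruitment around `r·A` (integer seedling counts with the ratio
estimator's mean), and a 40-year monthly climate record starting 21 years
before the census so anomalies have a stable reference and the scan can
look back 36 months.  Climate anomalies inside the generator are computed
with the same standardization code the analysis uses, so the scan sees the
generating scale.  Default rates (logit/ln-mm scale) were chosen once for
a quasi-stationary population of a few hundred plants with realistic stage
structure: `S1` intercept −0.2; `S2` = −0.2 + 0.9·size; growth
0.55 + 0.82·size (residual SD 0.25); flowering −6.5 + 2.4·size; new size
N(1.2, 0.35); recruitment 7 seedlings per flowering adult.  Climate
slopes default to a monotone gradient from −1 (zone 1) to +1 (zone 5) on
the mean precipitation anomaly over months 4–8 before the census;
year-level noise (shared across zones within a rate, SD 0.3 on the logit
scales, 0.08 on the ln-mm scales) supplies temporal variation climate does
not explain, making climate the sole source of between-zone asynchrony —
the property the attribution test needs.  The synthetic drought index is
an SPI-like stand-in: a 3-month running mean of precipitation-minus-
temperature z-scores, restandardized per calendar month; it deliberately
includes a temperature component so it is statistically distinguishable
from raw precipitation windows.

What the generator does *not* emulate: spatial structure within zones,
herbivory, seed dormancy and between-zone dispersal, observation error in
size, and non-Gaussian climate tails.  Passing recovery tests therefore
shows the estimators are correct under the stated model, not that the
model captures every process in real dune censuses.

## Problem sizes and test design

The statistical acceptance checks run at sizes chosen to give stable
Monte-Carlo verdicts: 100 replicates (~4000–4500 transitions each) for
interval coverage; 50 replicates on a 13-month grid for scan power with a
strong planted effect (slopes ±2); 200 null studies × 99 permutations on a
3-month grid for type-I calibration of the randomization p (the add-one
estimator at 99 permutations makes P(p < 0.05) = 0.04 under
exchangeability; the check uses 99% binomial bounds around the 5% level);
20 replicates for the attribution regression.  The acceptance script runs
the paper-scale configuration — full 37-month grids for all five rates and
a 99-permutation randomization of the seedling-survival scan.

## Known limitations

- Laplace ML for Bernoulli mixed models shares lme4's small-cluster bias:
  variance components from 16 year levels are noisy, and Wald intervals
  ignore their uncertainty (coverage is verified empirically instead).
- AICc's `n` is taken as the transition count; with clustered data the
  effective sample size is smaller, so the small-sample correction is
  conservative in spirit but not exact.
- The randomization p has resolution 1/(n_perm+1) and the add-one
  estimator never returns 0.
- PE extrapolates the zone-level scaling law to the total's mean, outside
  the fitted range of zone means; it inherits all the fragility of a
  5-point log-log regression.
- The IPM assumes vital rates depend on size and cell only — no density
  dependence, no elasticities, no stochastic λ.
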