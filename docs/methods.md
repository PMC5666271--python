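# Methods

This note documents the statistical model behind `ontotraj`, the choices
made where the methodology was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Growth model and assumptions

All analyses assume power-law (log-linear) postnatal growth: for a
specimen of overall size s, measurement k is
`log10 y_k = a_k + b_k log10 s + eps_k`. A uniform growth phase is
assumed — no biphasic growth spurts and no sex-specific trajectories —
and sampling should span at least a two-fold size range so that
`var(log10 s)` dominates measurement noise. Measurements must be strictly
positive; cells may be missing.

Missing-data policy (the source methodology for this design is silent):
the multivariate stage uses only specimens complete for the analysed
variable set, because a covariance PCA needs complete vectors; the
bivariate stage uses, per variable, specimens with that variable and all
geometric-mean variables present. Within a pair both forms always use the
identical variable set (their common set), so coefficients, size proxies
and isometric baselines are commensurable.

## Multivariate stage

* Coefficients are the elements of the unit-norm first eigenvector of the
  covariance (denominator n−1) of log10 data, oriented to a positive
  element sum. Tied leading eigenvalues are an error (the axis is not
  identified).
* Jackknifing uses first-order Tukey pseudovalues
  `n*theta − (n−1)*theta_(−i)`. Every leave-one-out eigenvector is
  re-aligned to the full-sample vector by positive dot product before
  differencing; without this, arbitrary sign flips between eigendecomposition
  rounds corrupt pseudovalues.
* The confidence interval is the Student-t jackknife interval
  `mean ± t_{n'−1,(1+level)/2} sd/√n'` (default level 0.95). The
  multiplier is configurable (`two_sd` replaces the t quantile by 2) for
  sensitivity checks, since "mean and standard deviation" alone do not
  pin down an interval convention.
* Trimming removes the m largest and m smallest pseudovalues *per
  variable* (each column on its own order statistics), m = 1 by default.
  2m must leave at least 3 values.
* Mode selection (`auto`): the trimmed variant is reported iff its mean
  SD across variables is lower; on an SD tie, lower mean |bias| wins; on
  a full tie, untrimmed. SD and bias comparisons use a small relative
  tolerance (1e−9) so that noise-free data, where both variants are
  exactly degenerate, deterministically report U.
* The isometric value is `1/sqrt(p)` with p the number of variables
  *actually analysed for that series* (1/√10 for a 10-variable series),
  not a fixed global p. Sign classification uses an absolute guard of
  1e−9 around the isometric value so that zero-width intervals from
  noise-free data are not misclassified by float round-off.
* Series need ≥ 5 complete specimens (hard floor) and warn below 10;
  jackknife SDs from a handful of specimens are not meaningful.

## Divergence ("added change")

The per-variable divergence between forms is the distance between their
mode-selected confidence intervals, `max(0, lo_b − hi_a, lo_a − hi_b)`:
zero on intersection, symmetric, non-negative. Added change is its sum
over the common variable set; variables absent from a pair contribute to
neither marginal. Two forms can disagree in sign (one P, one I) while
their gap is zero; this is flagged (`sign_disagreement`) but adds
nothing. The metric is descriptive — no test is attached to it.

Note a structural coupling: because coefficients are elements of a unit
vector, perturbing one variable's growth exponent moves *all*
coefficients slightly (through the norm). Planted single-variable
divergences therefore leak small gaps into other variables once CI
widths are small relative to that coupling; tests that assert "exactly
one diverged variable" use effect sizes and noise levels where the
coupling stays inside the CIs.

## Bivariate stage

* The size proxy is the geometric mean of the (common) variable set —
  an equal-weight average of logs, hence isometric by construction. The
  dependent variable is *not* excluded from its own GM, the standard
  practice in this framework. Shapiro–Wilk on the GM is advisory: a
  warning, not a gate.
* SMA slope `sign(r) sd_y/sd_x`, intercept `mean_y − slope*mean_x`,
  slope CI from `B = F_{1,n−2}(level) (1−r²)/(n−2)`,
  limits `slope(sqrt(B+1) ∓ sqrt(B))`. An OLS estimator is available
  behind a flag for sensitivity analysis only.
* Isometry test: correlation `r_rf` between residual scores `y − b0 x`
  and fitted-axis scores `y + b0 x` at the null slope b0 = 1;
  `F = r_rf²(n−2)/(1−r_rf²)` on (1, n−2). Exact noise-free lines give
  p = 1 by convention (zero residual variance).
* Bonferroni: the per-test level divides the family-wise alpha by the
  number of regressions actually fitted for the series (0.05/14 = 0.0036
  when complete; 0.005 for a 10-variable series).

Note that SMA on a GM proxy carries a small structural bias: the GM
averages measurement noise over p variables, so its log-SD is slightly
smaller than that of any single variable, inflating slopes by a factor of
about `sqrt((var_t+sigma²)/(var_t+sigma²/p))` — roughly 0.6% under the
default synthetic conditions, negligible against the corrected alpha but
visible in very large samples.

## Trajectory comparison

* Common slope: the Bartlett-corrected likelihood-ratio profile
  `LR(b) = −sum_i (n_i − 2.5) ln(1 − r_i(b)²)`, where `r_i(b)` is the
  within-group residual/fitted-axis correlation; minimised over b by
  bounded search bracketed around the two group slopes (tolerance
  1e−10), the minimum referred to χ²(1).
* Elevation (intercept) and shift tests are Wald tests on mean residuals
  `y − b x` and mean axis scores `y + b x` respectively, with the common
  slope's sampling variance (pooled `b²(1−r²)/(n−2)` information)
  propagated through the group difference in mean x. The elevation test
  is mildly anticonservative when the two size ranges barely overlap
  (high leverage on the slope term); in the extension scenarios this
  diverts ~2–3% of cases from the shift bin into a displacement label.
* Gating: intercept is tested only on a shared slope, shift only on a
  shared line; all three tests run at the same Bonferroni-corrected
  alpha. Direction conventions: a higher domestic intercept is read as
  earlier onset (pre-displacement); a greater domestic mean axis score as
  trajectory extension (hypermorphosis). The intercept-direction
  convention is a choice — the vocabulary links intercept changes to
  onset shifts without fixing the sign — and is recorded in the output.
* Counting "heterochronic events": the per-pair summary counts variables
  whose label is not `no_change`; per-category tallies are also exposed
  so either counting convention can be reported.

## Synthetic generator

The generator emulates: per-variable power-law growth with configurable
exponents (defaults: positive allometry on facial/masticatory variables,
negative on braincase/orbit, balanced to mean exactly 1 so the 14-variable
GM is isometric to latent size), independent lognormal measurement noise
(default sd 0.02 on log10, ~5% CV), log-uniform latent sizes over a
four-fold range, and optional missing variables. It does **not** emulate
realistic craniofacial covariance (noise is independent across variables
unless the optional shared size-error term is enabled), age-structured
sampling, sexual dimorphism, or biphasic growth — so passing benchmarks
demonstrate correctness of the estimators under the stated model, not
robustness to those real-data features.

Scenario presets plant one effect each on a target variable from an
isometric baseline (n = 80, noise sd 0.05): exponent ±0.4 for rate
changes, intercept ±0.2 (log10) for displacements, a 2× size-range
translation along the shared line for extensions, a 3× multiplicative
corruption of one specimen for the outlier preset. Only the target
variable's label is asserted, because the GM proxy couples untargeted
variables weakly to the planted effect. The study fixture plants a
descending ladder of divergence levels (0.4 → 0 across pairs) along a
fixed zero-mean exponent direction; "ranking recovered" is operationalised
as rank correlation ≥ 0.8 plus correct identification of the most-diverged
pair, since adjacent ladder steps (≈ 0.033 apart at 13 pairs) are within
estimation noise while the overall ordering is not.

## Problem sizes

The test suite and the acceptance script use: 500 replicates at n = 100
for CI coverage, 1000 replicates at n = 80 per type-I calibration, 200
seeds per heterochrony scenario, and a 13-pair study at 50 specimens per
form — sizes at which every stochastic check's expected value is several
simulation standard errors from its acceptance bound. The whole suite
runs in well under a minute on one CPU.

## Known limitations

* Heterochrony labels inherit the size-as-time assumption: onset/offset
  language is a reading of intercept/extension differences on a size
  axis, not of chronological age. Intercept differences may equally
  reflect neomorphy; the pipeline does not distinguish the two.
* The added-change metric depends on CI widths, hence on n and noise;
  it is comparable across pairs only under comparable sampling.
* Jackknife CI coverage for eigenvector elements is slightly below
  nominal (~93% at the 95% level under default conditions), a known
  property of first-order jackknifes of eigenvector statistics.
* With non-overlapping size ranges the elevation Wald test's nominal
  level degrades; interpret displacement labels cautiously when one form
  was sampled at systematically different sizes.
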