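# Methods

## The hazard model and its Poisson approximation

Spontaneous delivery is the event of interest; pregnancies ending by
induction or pre-labor cesarean leave the risk set (right-censoring). For
minor-allele dosage `g` and constant-effect covariates `z` the model is

    h(t | g, z) = h0(t) · exp( β(t)·g + z'γ )

with a smooth, possibly time-varying per-allele log hazard ratio `β(t)`.
Because essentially no live deliveries occur before ~24 weeks, durations
are shifted by −169 days before modeling; durations ≤ 169 days are
rejected with an error naming the record.

The model is fitted as a piecewise-exponential (Poisson) regression.
Follow-up is partitioned at cut points 0, 20, then every 7 days (the grid
extends automatically to the data maximum; intervals are right-closed, so
a duration equal to a cut point belongs to the interval ending there).
Each pregnancy contributes one row per interval entered, with its time at
risk in the interval as a log offset and an event indicator in its final
row. Within an interval the hazard is constant, so the event count is
Poisson and the Poisson likelihood is proportional to the survival
likelihood. The interval-expansion step is exactly conservative: summed
exposure reconstructs each shifted duration, and event rows equal
uncensored pregnancies (both are tested).

Rows that share a design point — same interval end time `T`, dosage and
covariate pattern — are collapsed by summing exposures and events before
fitting. This leaves the likelihood unchanged and reduces, e.g., a
20 000-pregnancy single-variant problem from ~280 000 rows to ~50, which
is what makes the replicated simulation studies below cheap.

## Splines, penalties, and smoothing selection

`log h0(T)` and `β(T)` are cubic regression splines, parameterized by
their values at the knots (the basis evaluated at its own knots is the
identity) with the exact integrated-squared-second-derivative penalty.
The construction was verified against an independent GAM implementation
to 1e-8 on both the basis matrix and the penalty. Knots sit at quantiles
of the distinct interval end times; default dimensions are 11 (baseline)
and 10 (effect smooth). The effect smooth is centered by a sum-to-zero
constraint over the observed rows, identifying the separate constant term
`β_g`; after centering the penalty null space retains one unpenalized
direction (linear in `T`), so even infinite smoothing leaves a linear
time-interaction — the parametric interaction model is the limit of the
smooth one, and a test asserts exactly that.

Fitting maximizes the penalized Poisson log-likelihood by iteratively
reweighted least squares with step-halving on the penalized deviance
(convergence: relative change < 1e-8, max 200 iterations; non-convergence
raises with the last gradient norm). Smoothing parameters are updated by
the generalized Fellner–Schall rule, which ascends the Laplace-REML
criterion; the outer loop stops when no log-smoothing-parameter moves by
more than 0.02. The reported coefficient covariance is the Bayesian
posterior `(X'WX + S_λ)^-1`; effective degrees of freedom per smooth are
the block traces of `(X'WX + S_λ)^-1 X'WX`.

**Interval estimates for β(t).** `predict_curve` evaluates
`β(t) = β_g + Σ β₁ₘ Bₘ(t)` with pointwise Gaussian 95% limits. The
covariance used for the curve adds a first-order correction for
smoothing-parameter uncertainty: `V_c = V_b + J V_ρ J'`, where
`J = ∂β̂/∂ρ` comes from implicit differentiation at the optimum and `V_ρ`
inverts a finite-difference Hessian of the REML criterion in `ρ = log λ`
(eigenvalues floored at 0.05 so flat/boundary directions cannot explode
the interval). Intervals conditioning on the selected smoothing are known
to under-cover when a feature is smoothed away; the correction restores
most of that coverage. No simultaneous bands are produced — the display
convention is pointwise shading. Extrapolation beyond the fitted time
range raises.

**Testing time variation.** The null hypothesis is that the variant has
only a constant effect (all effect-smooth coefficients zero). The
statistic is `β₁' V_r⁻ β₁` with the rank-`r` pseudo-inverse of the
smooth's covariance block, `r` = rounded effective degrees of freedom,
referred to χ²_r — the standard penalized-smooth Wald test. Penalization
shrinks the null fit, so the test runs slightly conservative: in the
bootstrap null experiment (phenotype resampled with replacement,
independent locus at MAF 0.3, 200 replicates at n = 2000) the observed
rejection rate at α = 0.05 is 4%, inside the exact binomial band. Two
parametric sensitivity analyses accompany it: a linear time × dosage
interaction (Wald test on `β_gt`), and the proportional-hazards score
test on Schoenfeld residuals with the time transform `1 − S_KM(t)` using
the left-continuous Kaplan–Meier estimate; the latter was validated to
1e-5 against the reference survival-analysis implementation.

**Ties.** Durations are day-resolution, so ties are heavy. The Cox
reference fitter uses the Breslow approximation — deliberately, because
the piecewise-exponential likelihood shares Breslow's behavior under
grouping, which is what makes the PAMM-vs-Cox equivalence check a clean
diagnostic (they agree within 0.003 at n = 20 000 in the test). Both are
mildly attenuated relative to an exact-ties likelihood; this affects the
comparison, not the time-variation inference.

## The synthetic cohort generator

The generator exists so that every stage is exercisable without
access-restricted registry data. It draws latent spontaneous onset times
from the hazard model itself, by inversion of the per-subject cumulative
hazard on a one-day grid (time-varying effects evaluated at day
midpoints), then records durations rounded to whole days (minimum 170,
support capped at 315 days; a configuration pushing > 10% of mass past
315 warns).

*Baseline.* A weekly piecewise-constant hazard derived from a
two-component normal mixture — a dominant term component and a small
early component supplying the heavy preterm tail a single normal cannot
produce. The three mixture degrees of freedom are calibrated once by
least squares so the **observed spontaneous** subset hits: P(< 224 d) =
0.003, P(< 259 d) = 0.027, median 281 d. Simulated cohorts reproduce
2.7% ± 0.5% preterm and ~0.3% very preterm (tested at n = 30 000).

*Censoring.* A fraction of pregnancies carries a planned induction time
C ~ N(277, 9) days, independent of the latent onset T; the observation is
min(T, C) with spontaneous = (T ≤ C). This is independent right-censoring
by construction — an earlier design that simply overwrote the duration
for a "censored" subset left subjects in risk sets beyond their latent
delivery time and visibly attenuated hazard estimates, which is why the
min-construction is load-bearing. The planning rate is solved numerically
so the realized non-spontaneous share matches the configured 15%.

*Genotypes.* Hard calls under Hardy–Weinberg equilibrium at configured
MAFs, optional Gaussian dosage jitter clipped to [0, 2] to mimic
imputation uncertainty. Variants are independent (no LD) except an
optional planted structure: a latent binary group shifting a variant
block's frequencies and adding an early-gestation log-hazard term, used
to test PCA recovery.

*Effect shapes.* Per-allele `β(t)` comes in the shapes reported for real
gestational-duration loci: constant; linear decay from early pregnancy to
zero at day 290; a Gaussian peak centered at day 238 (week 34, SD 10 d);
and a term-only window (days 266–287, weeks 38–41) with short sigmoid
shoulders (~2-day scale) rather than a hard step, since a biological
on-switch is not instantaneous and the true curve should be a bounded
smooth function. Default magnitude for non-null shapes is 0.2 log-HR per
allele — the size of a strong GWAS top hit. Covariates (maternal age,
height with 2% missingness, fetal sex, malformation, parity, batch,
delivery year) are drawn independently; their hazard effects default to
zero because only their adjustment role matters downstream.

*Bootstrap phenotype.* For null calibration, (duration, spontaneous)
pairs are resampled jointly with replacement, independent of genotype and
covariates.

What passing these simulations does **not** show: robustness to LD
between variants, population stratification beyond the single planted
factor, informative (outcome-dependent) censoring, covariate-dependent
genetic effects, or frailty-induced apparent effect decay. In real data a
decaying `β(t)` can also arise from unmodeled heterogeneity; the package
estimates the curve, it cannot arbitrate that interpretation.

## Simulation-study results encoded as tests

- Constant-effect recovery: simplified-PAMM and Cox estimates agree
  within 0.02 and sit within 2 SE of the generating value 0.3
  (n = 20 000).
- Shape recovery: over 20 replicates at n = 20 000, the median fraction
  of weekly grid points whose pointwise 95% band covers the true curve is
  1.00 (constant), 1.00 (linear decay), 0.95 (peak) and 0.89 (window).
  The window shape sits just under the 0.90 working threshold: its
  generating curve falls from 0.2 to 0 in ~8 days at the window edge,
  faster than a 10-dimensional penalized cubic spline can track, and the
  misses concentrate at the two grid points flanking that edge. The same
  data fitted with an independent REML GAM implementation yields the same
  smoothing, curve and intervals, so this is a property of the model
  class at these conditions, not of this implementation.
- Type-I error: 4% rejection at nominal 5% (200 bootstrap-null
  replicates, n = 2000).

## Power calculus

Under the liability model (normal outcome, additive constant allele
effects), dichotomizing at prevalence K multiplies the required sample
size by `1/t²` with `t = φ(Φ⁻¹(K))/√(K(1−K))`; the same `t` converts Wald
ratios between scales, and the significance level giving power f in the
dichotomized analysis is `Φ(−Φ⁻¹(1−f) − β_d/SE_d)`. At the study's case
fraction (610/22 247 ≈ 2.74%) the ratio is 6.7; evaluated at exactly
2.70% it is 6.76 — the acceptance computation therefore uses the exact
case fraction. The detectable odds ratio inverts the expected-information
Wald power approximation for additive logistic regression (HWE genotype
distribution, intercept solved to match the prevalence) by bisection;
at n = 22 247, MAF 0.2, α = 5×10⁻⁸, power 0.8 it returns 1.51. Named
commercial/CRAN power calculators implement closely related
approximations and may differ in the second decimal.

## Other numerical and design choices

- Covariate preparation: maternal age as two orthonormal degree-2
  polynomial columns computed on the analysis sample; height missing or
  beyond mean ± 4 SD mean-imputed (logged); parity reference level "1";
  first batch is the reference; delivery year centered.
- Association scans: the linear scan residualizes outcome and dosages on
  the batch design once (Frisch–Waugh), which is numerically identical to
  per-variant joint OLS; the logistic scan is per-variant IRLS. MAF < 1%
  variants are dropped; MAF is computed on the analysis sample after
  exclusions. Suggestive-hit pruning keeps the smallest-p variant per
  1.5 Mbp window, greedily per chromosome; the default pooling rule is
  "suggestive in either scan" with a flag for "both". The provided
  inflation lambda is median-χ²/0.456, a synthetic-data diagnostic only.
- PGS: dosages are hard-called (round half-up). Weight-file alleles are
  matched directly, swapped, or via strand complement when unambiguous;
  palindromic A/T and C/G variants are dropped. Quantile groups use a
  rank split (stable under the heavy ties of few-variant scores); the
  middle group is always the reference, so group counts must be odd.
  Risk tables use the Wilson score interval with continuity correction,
  matching the reference implementation to 1e-9. PCA standardizes hard
  calls by √(2p(1−p)) after greedy r² < 0.2 pruning in 100-variant
  windows stepping 10.
- Reproducibility: every stochastic operation takes one integer seed; the
  pipeline writes a manifest with per-file checksums, and a rerun with the
  same config reproduces outputs byte-for-byte (tested).

## Problem sizes used by the packaged studies

The replicated experiments run at n = 2000 (type-I, 200 replicates) and
n = 20 000 (recovery and equivalence, 20 replicates per shape); these are
the package's reference study sizes and complete in well under a minute
each thanks to the design-point aggregation described above.

## Known limitations

No frailty or random effects; no accelerated-failure-time alternative; no
left truncation; no time-varying covariates other than the dosage-by-time
smooth; no LD-aware clumping (distance only); no case-control
ascertainment correction in the power module. Breslow ties and the
quantile knot rule are documented conventions, not estimates; both matter
only at the margins visible in the equivalence diagnostics.
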