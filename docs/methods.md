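# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the known limitations of the `dogaging` package.

## The trajectory model

Every trait is modelled as a continuous piecewise-linear ("broken-line")
function of age,

E[y|x] = β₀ + β₁x + Σₖ δₖ(x − ψₖ)₊,  k ∈ {1, 2},

with unknown breakpoints ψₖ. The breakpoint is the operational definition of
the *onset of decline*; per-segment slopes are the *rates*.

**Estimation.** Iterative linearization: given a working ψ, the model is
refit with an added gap regressor −1{x>ψ}; its coefficient γ measures the
discontinuity the working model would need, and ψ ← ψ + γ/δ drives γ to 0.
Two safeguards are layered on top: (i) *step-halving* — a proposed update is
accepted only if it does not increase the profile RSS, halving the step
otherwise (the raw update can oscillate around optima that sit on
data-point kinks of the profile); (ii) *global initialization* — besides the
quantile-based starts (median for one breakpoint, 33rd/66th percentiles for
two) and five jittered restarts (fixed restart seed 12345), a coarse
profile-RSS scan over 25 interior quantiles (all admissible pairs for two
breakpoints) contributes starts, and for one breakpoint the top three
candidates are polished by bounded scalar minimization. The best-RSS
solution is kept. Convergence: gap |t| < 0.01 or ψ moving < 1e-4 years;
maximum 60 iterations; non-convergence and boundary collapse are flagged,
not raised. The test suite verifies that the fitted RSS matches an
exhaustive 0.01-year grid search within 0.1% on random datasets.

**Uncertainty.** SE(ψ̂) = SE(γ̂)/|δ̂| from the final gap-augmented fit
(delta method); Wald 95% intervals. Per-segment slope SEs come from the
covariance of (β₁, δ₁, δ₂) in the final no-gap fit. Empirical coverage of
the breakpoint interval is 0.92–0.94 in the packaged simulations (n=2,000,
200 replicates) — delta-method intervals are known to be slightly
anti-conservative for weak kinks.

**Existence testing.** The slope-change t statistic is evaluated at 10
equally spaced interior quantiles of age (outer 5% trimmed) and the
supremum's two-sided p-value is bounded by
p ≤ 2(1−Φ(M)) + V·exp(−M²/2)/√(8π), where V is the total variation of the
signed statistic sequence. With a single candidate the bound reduces to the
plain two-sided p. Breakpoint-count selection runs this test sequentially
(0 vs ≥1 on the linear base; 1 vs 2 over the one-breakpoint design) with
Bonferroni correction across the two stages; p < 0.1 at a failed stage is
flagged as trend-level. Simulated type-I error at α=0.05 is ≈0.05–0.06
(within the 0.02–0.08 band the suite enforces) — the Davies bound is mildly
conservative and the normal approximation of the t statistics mildly
liberal, and they largely offset.

Group breakpoints are compared by 95% CI overlap (closed intervals: touching
endpoints do *not* differ); this mirrors the absence of a targeted test for
comparing breakpoint locations.

## Factor analysis

Principal axis factoring on the Pearson correlation matrix of
listwise-complete rows: squared-multiple-correlation priors, eigendecompose
the reduced matrix, update communalities, tolerance 1e-4 on the largest
communality change, 100 iterations, Heywood cases capped at 1 and flagged.
Varimax rotation uses the SVD-based update with Kaiser row normalization.
Retention is by the eigenvalue>1 rule on the *correlation-matrix*
eigenvalues (the printed per-factor explained-variance percentages equal
eigenvalue/item-count × 100 under this convention); items whose best rotated
loading is ≤0.4 are pruned one at a time (smallest best-loading first), with
the factor count re-evaluated after each drop. Factor scores use the
regression method (W = R⁻¹Λ), reported unscaled (variance < 1). Missing
data: listwise deletion.

## The synthetic survey generator

The generator is calibrated to a published survey population of 16,818 dogs
and emulates, per simulated dog:

* **age** — truncated normal on [0.83, 22.06] years whose *post-truncation*
  mean and SD equal 8.67 and 4.10 (the underlying parameters are solved
  numerically), reported to two decimals as owners do;
* **sex/neuter** — 22.3/13.3/25.7/38.8% intact-male/intact-female/
  neutered-male/neutered-female;
* **breed and size** — a panel of 21 synthetic-but-realistic breed entries
  (standards per sex, mean lifespan, cephalic index) spanning all six weight
  classes and all lifespan/head-shape tertiles; mixed-breed dogs (~40%) get
  lognormal weights and allometric heights h ≈ 12·w^0.45 with 6% log-scatter;
* **behaviour items** — two latent factors follow group-specific broken-line
  trajectories plus Gaussian noise, are standardized, mixed through the
  reference 9×2 loading pattern plus unique noise, affine-mapped to the 1–10
  scale (centre 5.5, scale 1.4), rounded half-up, clipped. The scale value
  matters: the liveliness latent reaches z ≈ −3 in the oldest dogs, and a
  larger scale saturates at the floor, visibly flattening the
  post-breakpoint segment and displacing the observable breakpoint early.
  The owner-sociability item is mapped with reduced dispersion (scale 0.9)
  so it carries too little variance to load — exercising the pruning path;
* **CCD symptoms** — a single latent severity trajectory emitted per item
  through loadings and four ordered cutpoints (0.6/1.1/1.8/2.5) into 1–5
  frequency ratings;
* **"is your dog old"** — a Bernoulli draw from a continuous two-change-point
  probability curve: near-flat around 20% before 5.85 y, rising ~0.11/year to
  90% at 12.17 y, near-flat after;
* **contamination** — configurable counts of exact-duplicate rows, rows with
  missing/implausible ages (NaN, >25 y, negative), and under-10-month rows,
  each labelled with provenance so tests can recover them exactly.

**Calibration policy.** Breakpoint locations per group are the published
point estimates. Slope magnitudes are *not* published; the full-sample
amplitudes were set so the simulated factor-score-on-age regressions
reproduce the published R² values (linear ≈0.31 / quadratic ≈0.34 for
Liveliness-Trainability; ≈0.26/0.32 for Severity), which also reproduces the
published breakpoint CI widths at the study sample size. Group-level slope
magnitudes were chosen so the published *qualitative* orderings — including
the published non-differences (e.g. giant vs large) — hold at the published
group sample sizes. Each simulated population drives its latent trajectories
from **one** active grouping (or the full-sample spec); the other group
labels are still assigned, but cross-grouping correlations of trajectories
are not modelled.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: country/cohort effects and recruitment bias;
correlated group memberships driving traits jointly; owner rating styles
(items are conditionally independent given the factors); real breed-name
noise (matching is exact after case/whitespace normalization); measurement
error in owner-reported age.

**A known distortion worth understanding.** The ordinal CCD mechanism has a
floor (most young dogs rate 1 on every symptom). The expected rating is
therefore a *convex* function of the latent severity over the relevant
range, so the observable severity factor-score trajectory is smoothly convex
rather than sharply kinked, and the fitted breakpoint can drift late — by
about a year for groups with small slope changes, and the two-breakpoint
selector sometimes prefers two kinks on the full sample (an early mild one
plus the real onset), exactly the pattern the sequential selector is
designed to adjudicate. The CCD-risk prevalence curve inherits the same
compression. This is a property of ordinal emission, not of the fitting
code; the breakpoint estimator itself is unbiased on directly observed
broken-line data (verified against the grid oracle and by CI coverage).

## Cleaning and grouping conventions

* Exclusion order: exact duplicates (first kept) → missing/implausible age
  (missing, non-numeric, negative, >25 y — a conservative bound above the
  maximum credible owner report) → age < 0.83 y (ten months as owners report
  ages, to two decimals). The cleaning log proves row conservation.
* Purebred size acceptance interval: [female minimum − tol, male maximum +
  tol] per dimension (5 cm / 1 kg); out-of-range or missing values are
  replaced by the sex-specific breed-standard mean.
* Weight bins for mixed-breed validation: 1-kg bins on [1,35), 5-kg bins on
  [35,60), one ≥60 bin (40 bins), plus an underflow <1 kg bin so binning is
  total. Empty bins give an "indeterminate" verdict.
* Size classes: toy <6.5 < miniature <9 ≤ medium-small <15 ≤ medium-large
  <30 ≤ large ≤40 < giant; all bins half-open except 40.0 kg, which is
  "large" (matching the printed "30–40" / ">40" notation).
* Tertile cuts: lower boundary inclusive to the middle group (11.4 y →
  medium-lived; CI 51 → mesocephalic). "auto" computes individual-level
  tertiles from the data.
* Dogs exactly at their group's breakpoint go to the *before* dataset
  (deterministic, documented).

## Slope-comparison conventions

Normality is operationalized as |skew| < 1 and |excess kurtosis| < 2 of the
OLS residuals (a reproducible stand-in for visual Q-Q inspection; the
statistics are logged). If that check or Levene's test (classical,
mean-centred) fails, the model switches to HC3 sandwich covariance and a
Wald χ² interaction test; otherwise classical covariance and an F test.
Pairwise slope contrasts are Bonferroni-adjusted within each model
(adjusted p = min(1, m·p)); effect sizes are partial η² = t²/(t²+df) for
classical fits and the exponentiated slope difference for robust fits. The
breed random-intercept replication fits the same fixed effects by REML with
a single variance component; non-convergence falls back to the fixed-effects
model, flagged.

## Problem sizes used by the packaged checks

The packaged simulations use populations of ~3,000–17,000 dogs (matching
the study's group sizes where group structure matters), 20 seeds for
parameter-recovery summaries, and 200–500 replicates for calibration
(type-I error, CI coverage). These sizes make every summary stable to well
within the tolerances asserted while keeping a full run in the minutes
range.

## Limitations

* Cross-sectional trajectories only; no longitudinal or survival modelling.
* At most two breakpoints; no nonparametric trend estimation.
* Prevalence curves are fitted on unweighted bin midpoints (bin sizes vary,
  so the implicit precision weighting of a binomial model is ignored, as in
  the procedure being reproduced).
* Delta-method breakpoint CIs undercover slightly for weak kinks.
* The breed panel is synthetic; real standards tables will have richer sex
  differences and messier names than the exact-match normalization assumes.
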