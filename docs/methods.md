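# Methods

## Problem and data model

The package validates knowledge-based DVH predictions for one organ-at-risk
at a time. All curves are cumulative DVHs with dose normalized to % of the
prescription dose and volume to % of the OAR volume, so `V(0) = 100` and
`V(D)` is non-increasing. A validation cohort pairs each plan's clinically
accepted DVH with its model-predicted DVH by plan id; optional
model-provided error-bound curves ride along under the `band_lower` /
`band_upper` roles.

Statistics are computed dosewise, so all curves are first linearly
interpolated onto a common uniform grid, by default 0–110% Rx in 1% steps.
The grid extends past prescription because clinical DVHs carry volume above
100% Rx; 1% spacing is fine enough that the boxcar-smoothed success curves
are insensitive to it. Doses beyond a curve's last tabulated point map to
volume 0, doses below its first point to 100. Linear interpolation was
chosen because cumulative DVHs are piecewise smooth and monotone; it
preserves monotonicity and is idempotent on grid-aligned curves.
Validation flags non-monotone segments, out-of-range volumes and
`V(0) ≠ 100` (tolerance 1e-6 after normalization; inputs can be rescaled
with `renormalize`). Duplicate dose values in input tables keep the last
row with a warning.

## Error statistics

With errors `e_i(D) = V_clin,i(D) − V_pred,i(D)` (positive =
underprediction), the per-dose summary reports the bias `μ`, the sample
standard deviation `σ` (N−1 denominator), the population standard deviation
`σ_pop` (N denominator) and `RMSE_pred = sqrt(mean e²)`. Both standard
deviations are kept deliberately: the quadrature decomposition
`RMSE² = μ² + σ_pop²` is an algebraic identity (checked to < 1e−9 relative
in the diagnostics), while with the sample σ the residual is exactly
`σ²/N`, bounded by `σ²/(N−1)` — the reason the decomposition is stated as
approximate. Displayed output uses the sample σ. Single-plan cohorts have
μ and RMSE but an undefined σ, reported as NaN with a warning rather than a
silent zero.

## Error-band formalisms

* **±RMSE band** — `clip(V_pred ± RMSE_pred, 0, 100)` per plan; width shared
  across the cohort. With negligible bias this is a ±1σ interval: expected
  Gaussian coverage `2Φ(1)−1 = 68.27%`.
* **IQR band** — pointwise 25th/75th percentiles of the clinical-DVH
  distribution (linear interpolation between order statistics, the numpy
  default). Nominal coverage 50% for any continuous distribution.
* **Median-split band** — the cohort is split at the median of a per-plan
  scalar feature (an anatomy surrogate; in synthetic cohorts the sigmoid
  midpoint d50). Each half contributes its mean clinical DVH; the band's
  bounds are the pointwise min/max of the two half-means, because the
  feature–value correlation can flip sign along the dose axis. For odd
  cohorts the median plan joins both halves. If every feature value ties,
  the split degenerates; halves are then formed by stable plan order and a
  warning is raised. With `feature=None` the split is performed
  independently at each dose point on the values themselves; for Gaussian
  values the half-means sit at ±√(2/π)·σ (the half-normal mean), giving
  expected coverage `2Φ(√(2/π))−1 ≈ 57.5%` — strictly between the IQR and
  ±σ bands. This generic construction approximates bands built from
  feature-split halves of a training library; it does not reproduce any
  specific vendor's internal distance-spectrum computation.
* **Model-provided band** — read from file and integrity-checked: crossing
  bounds are an error (with offending dose points listed), a prediction
  outside its own band a warning, and a `symmetric` flag records whether
  the band is an additive ± construction.

Bounds are clipped to [0, 100] but never re-monotonized — the tally is
pointwise, and re-monotonizing would silently alter coverage.

## Coverage tally

At each grid dose, a plan succeeds if its clinical volume lies inside the
band, or differs from the *prediction* (not the nearer band edge) by less
than the tolerance — 0.5% of OAR volume by default, a strict inequality,
representing clinically meaningful dose-volume granularity. The success
fraction across plans is the raw coverage curve; coverage is monotone
non-decreasing in both tolerance and pointwise band width. An 11-point
centred boxcar smooths the curve for presentation; at the edges the window
shrinks symmetrically (no padding, so no data are invented), constants are
preserved, and the smoothed curve never leaves the raw range. Dose-range
summaries (min/max/mean, in percent) are available on both raw and smoothed
series; calibration experiments use the raw series with tolerance 0.

## Synthetic cohorts

Real reference cohorts are institutional and unpublishable, so testing and
calibration use generated ones. Baseline DVHs come from a logistic sigmoid
`V(D) = 100·s(D)/s(0)`, `s(D) = 1/(1+exp((D−d50)/k))`, monotone with
`V(0) = 100` exactly. Per plan, `d50 ~ Normal(d50_mean, d50_sd)` doubles as
the anatomy feature. Defaults emulate a prostate-OAR validation exercise:
45 plans, `d50 = 55 ± 5% Rx`, falloff `k = 18% Rx` (a gradual
bladder/rectum-like curve), zero injected bias, 3% volume error spread —
the few-percent dosewise error scale reported for knowledge-based prostate
models. The generator is driven by one named PRNG (NumPy PCG64); a fixed
seed reproduces cohorts bit-identically.

Two error modes exist because additive pointwise noise breaks DVH
monotonicity:

* `pointwise_gaussian`: `clinical = clip(predicted + bias(D) + ε_i(D), 0,
  100)` with independent `ε_i(D) ~ N(0, spread(D)²)` per dose point.
  Dosewise errors are exactly Gaussian — the assumption behind every
  closed-form coverage figure — at the cost of non-monotone clinical
  curves, which the ground-truth record flags.
* `parametric`: `clinical = sigmoid(d50_i + δ_i)` with `δ_i ~
  N(shift_mean, shift_sd²)` in % Rx. Curves are physically valid DVHs and
  errors are approximately Gaussian mid-dose; used for end-to-end tests.
  Its injected dosewise moments have no closed form and are computed by
  Gauss–Hermite quadrature (40 nodes per axis) over the d50 and shift
  distributions.

Ground truth (injected μ(D), σ(D), per-plan feature) is recorded pre-clip;
`truth_report` joins it with the estimated statistics and reports maximum
discrepancies over the interior dose window.

## Calibration conditions

`run_calibration` checks the band formalisms against their Gaussian closed
forms: IQR 50%, median-split (self-split) ≈57.51%, ±RMSE 68.27%. Study
conditions, fixed once: 2000 plans, pointwise-Gaussian mode, zero bias,
3% spread, `d50_sd = 0` so each dose point's clinical values form a single
Gaussian around a common centre (the regime the closed forms describe),
tolerance 0, raw (unsmoothed) tally, averaged over the interior 20–90% Rx
window. The interior restriction and the shallow default sigmoid keep the
probability of boundary clipping below ~0.3% at the worst interior dose
point, so clipping cannot distort the Gaussian calibration. Acceptance is
±2 percentage points per band, a comfortable bound given the Monte-Carlo
standard error (~1 point per dose point, much less after averaging 71
correlated-only-through-RMSE dose points).

## What passing tests do and do not show

The synthetic generator emulates the *statistical* structure of a reference
cohort — monotone cumulative DVHs, a sparing-correlated feature, dosewise
errors with controllable bias and spread. It does not emulate real prostate
anatomy, beam geometry, multi-modal plan-quality populations, or any actual
KBP model's residual structure; dosewise errors in real cohorts are
correlated along dose and not exactly Gaussian. Passing calibration
therefore demonstrates that the estimators and tallies are correct and that
the band interpretations (σ-like vs IQR-like) hold under their stated
assumptions — not that any particular clinical model achieves them. The
package also deliberately excludes DICOM dose/structure parsing, absolute
volume (cc) DVHs, differential DVHs, DVH *prediction* itself, and
statistical tests comparing two coverage curves.

## Numerical choices

* Dose grid 0–110% / 1% steps; interior calibration window 20–90% Rx.
* Linear interpolation everywhere (resampling, percentiles).
* Tolerance comparisons: band inclusion is closed (`lower ≤ V ≤ upper`),
  the granularity rule strict (`|V − pred| < tol`).
* Monotonicity/range validation slack 1e−9; `V(0)` check 1e−6.
* Boxcar edge rule: symmetric shrinking window.
* Quadrature-identity pass threshold: 1e−9 relative with σ_pop.
* Reports are deterministic directory bundles (tables, manifest JSON with a
  config hash, optional PNGs); identical inputs and config produce
  byte-identical JSON.
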