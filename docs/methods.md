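# Methods

This note records the statistical models the package implements, the design
choices made where more than one reasonable convention exists, and what the
synthetic-data generator does and does not emulate.

## Vehicle classification and flow windows

Radar event logs carry a timestamp, speed, and length per detection.  Length
thresholds define the classes: small < 4 m, medium 4–7 m, large > 7 m.
"Trucks" are the large class; "cars" are small plus medium.  Boundary
convention: a vehicle of exactly 4 m or exactly 7 m is medium — a truck
requires length *strictly* greater than 7 m.  Radar hardware does not
document its own rounding at these boundaries, so the convention is a
package choice, stated rather than inferred.

Counts are aggregated into windows aligned to local midnight: 15 min for the
noise regressions, 3 h (eight windows per day) for the interrupted time
series.  Each window carries a coverage fraction computed from known logger
outages.  A partially covered window's flow *rate* (vehicles/h) is the count
divided by the covered duration — the count itself is never extrapolated.
Windows with coverage below `min_coverage` (default 0.8) are flagged
excluded and dropped from model fits, not imputed; the threshold is a
package default, since "adjusting" a partial window says nothing about when
a window is too empty to trust.  All timestamps are naive local clock time;
daylight-saving transitions are handled by the coverage machinery (pass the
transition hour as a gap), never by shifting clocks.  Speed is read and
preserved but used by no analysis here.

## Equivalent sound levels

The equivalent level over any set of 10-s A-weighted samples is the energy
mean Leq = 10 log₁₀((1/N) Σᵢ 10^(Lᵢ/10)).  Stratified levels (total, daytime
07:00–22:00, night 22:00–07:00, weekday, weekend) are computed over *whole
days* only: calendar days with at least 8,630 of the 8,640 expected 10-s
samples (99.9%, tolerating a few samples of logger jitter).  The
completeness floor is a package choice — whole-day counting needs *some*
rule, and 99.9% excludes any day with a real gap while ignoring clock
jitter.  Stratum membership is decided by each sample's own timestamp; day
boundaries are never shifted for the night stratum.  Limit screening uses a
strict inequality (a site at exactly 70.0 dBA does not "exceed" 70 dBA).
Per-15-min levels drop partial windows at deployment edges by default (the
choice is exposed as a flag).  No facade correction is applied to levels
measured near building faces.

## Interrupted time series for 3-h counts

One GLM per site × vehicle class × 3-h window, fitted to that window's daily
count series:

log E[N_t] = β₀ + β₁ t + β₂ X_t + β₃ DoW + β₄ LTST

* **Link.** The percent-change reporting (exp(β₂) − 1)·100 requires a
  multiplicative model, so the link is logarithmic even though the linear
  predictor is conventionally written additively.
* **t** is days since the first observed day; β₀ is reported but never
  compared across sites.
* **X_t** is 1 on the opening date itself and afterwards (inclusive lower
  bound).  Fitting demands both levels present.
* **DoW** uses Monday as reference (six contrasts).
* **LTST** is sin/cos(2πt/365.25) and sin/cos(4πt/365.25); the 12-month
  period is implemented as 365.25 days on the daily-resolution t.
* **Family.** Quasi-Poisson: IRLS point estimates at unit scale, then the
  Pearson dispersion χ²/df multiplies the covariance.  Fitting at unit scale
  and applying dispersion afterwards is numerically identical to the usual
  quasi-Poisson output and stays finite on degenerate (perfectly fitted)
  inputs.
* **CIs** are Wald on the coefficient scale with z = 1.96, then
  exponentiated.  No multiplicity adjustment is applied across the 32-model
  sweep; all intervals are reported.
* A lag-1 Pearson-residual autocorrelation is attached to each fit as a
  diagnostic.  Inference itself is plain quasi-Poisson — no
  autocorrelation-robust errors — matching the simplicity of the design it
  implements; the diagnostic lets a user judge whether that is defensible on
  their data.

**Attribution.**  For post-opening rows, the warehouse-attributable count is
prediction(X=1) − prediction(X=0) with all other covariates observed; under
the log link this is fitted·(1 − exp(−β₂)) per row.  Averages are taken
separately over weekday and weekend rows; standard errors come from the
delta method on the coefficient covariance.  Attributable changes are
converted to vehicles/h (per-3-h counts divided by 3) before any coefficient
multiplication, and the attribution layer refuses unconverted units.

## Traffic → noise regression

The 15-min intensity ratio is modelled as
I/I₀ = λ_car Q_car + λ_tr Q_tr + s(t) (segregated) or
I/I₀ = λ_tot Q_tot + s(t) (total), with Gamma errors.

* **Link: identity by default.**  The model is additive in the flows, and
  the slope formula ∂Leq/∂Q = 10 λ I₀/I presumes dI/dQ = λ I₀, which only an
  identity link satisfies.  A log link is available behind a flag for
  sensitivity analysis, but the identity link is the form under which the λ
  units (hours) and the printed slope arithmetic are coherent.
* **s(t)** is a natural cubic spline basis with 3 degrees of freedom
  spanning the deployment (the basis spans the constant, so no separate
  intercept is added).  It absorbs slow instrument drift.
* **Dispersion** is the Pearson moment estimator; standard errors scale with
  its square root.  Negative λ estimates are reported as-is, never truncated
  at zero.
* **Slopes** are reported per 100 vehicles/h at the site's *deployment-wide*
  median intensity I₅₀: slope = 10 λ (I₀/I₅₀) · 100, rounded to one decimal
  for tables.  The formula is the published convention for this quantity and
  is reproduced exactly as conventionally printed — note a strict derivative
  of 10 log₁₀(I/I₀) would carry an extra 1/ln(10); the package follows the
  printed convention, which is what the reference slope values verify.
* **Collinearity** between Q_car and Q_tr is screened with a Pearson
  correlation; an exactly rank-deficient design raises an error naming the
  collinear columns.
* ΔI/I₀ = λ_car ΔQ_car + λ_tr ΔQ_tr is exact (not merely first-order)
  because the model is linear in the flows; ΔLeq uses the median-intensity
  approximation I ≈ I₅₀ baked into the slopes.

## BC attribution

BC coefficients (α_tr, α_car, in µg/m³ per 100 vehicles/h) come from a
previously published BC–traffic regression and are consumed as inputs — the
package does not refit that model.  Although they originate from a log-BC
specification, they are applied as linear µg/m³-per-flow multipliers, which
is how the attribution procedure is defined; this is fidelity to the
procedure over fidelity to the source model, and it is accurate for the
small flow changes involved.  The headline summary is the arithmetic mean
and SD of ΔBC and ΔLeq across all site × window × day-type cells.  Diurnal
profiles default to day-type-specific output (weekday/weekend); pooled is
available.

## Synthetic data: what it emulates

The generator is the package's ground-truth instrument.  Defaults describe
the low-flow local street near the monitored facility: per-window base rates
from the observed pre-opening 3-h means, λ_tr = 138,191 h,
λ_car = 11,011 h, α_tr = 0.21, α_car = 0.06 µg/m³ per 100 vehicles/h, a
background intensity of 4.0×10⁶ placing the median 15-min level near
67 dBA, and a BC background of 1.29 µg/m³ giving period means near
1.33 µg/m³.  `site3_scenario()` switches to the high-throughput
interstate-ramp configuration (λ_tr = 60,275 h, λ_car = −1,679 h, background
2.0×10⁷, α_tr = 0.15, α_car = 0.04).  Step multipliers default to 1.0 — the
null scenario — and intervention effects are always configured explicitly.

* **Counts** are Poisson with a per-window multiplicative Gamma random
  effect of mean 1 and shape k (`count_gamma_shape`), so Var = µ + µ²/k —
  the simplest mechanism matching quasi-Poisson mean–variance inflation.
  Default k = 6, back-solved from the observed mean/SD of the ramp site's
  midnight truck counts (66.2, SD 28.1): 28.1² ≈ 66.2 + 66.2²/k.  The field
  data's true dispersion magnitude is not published, so k is a free
  parameter, not an asserted value.
* **Day-of-week and seasonality** enter the count mean multiplicatively:
  seven positive day factors (weekdays above weekends) and
  1 + a₁sin + b₁cos (annual) + a₂sin + b₂cos (semi-annual) with small
  default amplitudes (0.06/0.02, 0.02/0.01).  The generator's seasonal term
  is linear in the sines while the ITS model exponentiates its harmonics;
  for amplitudes this small the mismatch is second-order, and the recovery
  tests confirm the step coefficient stays unbiased.
* **Sound samples**: each 15-min window's intensity is the linear flow model
  plus background × drift(t), where drift is a one-cycle sinusoid of
  amplitude 0.05 standing in for slow logger drift; each of the 90 10-s
  samples multiplies the window intensity by mean-1 Gamma noise
  (`sound_gamma_shape`, default 20), so energy averaging recovers the window
  intensity in expectation.
* **Air**: period BC = background + linear flow term + Gaussian noise
  (SD 0.3 µg/m³); PM2.5 is constructed from standardized BC with target
  Pearson correlation 0.6 (the observed range is 0.40–0.89), mean 7.88 and
  SD 1.24 µg/m³.
* **Lengths** are uniform on the class ranges (2.5–4, 4–7, 7–20 m); only
  class membership matters downstream.  Speeds are clipped normal (25 ± 5
  mph) and unused.

Everything is reproducible bit-for-bit from `rng_seed`.

**What it does not emulate:** meteorology and background-pollution
variability (air noise is i.i.d. Gaussian), serial correlation in counts
beyond the window-level random effect, individual vehicle acoustics or
horn/air-brake transients, gradual facility ramp-up (the step is sharp), and
radar misclassification near the length boundaries.  Passing recovery tests
therefore show the estimators are correct *under the stated generative
model*; they do not certify robustness to confounding or drift patterns the
model lacks.

## Problem sizes and numerical choices in the test suite

The suite runs the 200-replicate CI-coverage experiment on two years of
daily counts for a single 3-h window (the scale at which the opening-effect
coverage claim is made), noise-model recovery at 9,000 15-min windows, the
likelihood-maximization oracle on 180-row fixtures, and six-replicate
null-intervention end-to-end runs on the full two-year default scenario —
sizes chosen to make Monte-Carlo tolerances meaningful while the whole suite
stays fast.  The IRLS oracle comparison uses an exact-Hessian trust-region
maximization of the Poisson log-likelihood and agrees to 10⁻⁶ relative
error.  Degenerate inputs are defined errors, not silent results: empty
sample sets, all-pre/all-post series, zero-variance correlation inputs,
non-positive intensities and lengths, and rank-deficient designs all raise.

## Known limitations

* Quasi-Poisson inference ignores residual autocorrelation; the lag-1
  diagnostic is reported but not acted on.
* The identity-link Gamma GLM can in principle predict negative intensities
  for extreme covariates; with realistic backgrounds this does not occur,
  and the fit raises on non-positive observed intensities.
* Attributable-change SEs treat truck and car fits as independent (they are
  separate models on the same days, so their errors share weather/calendar
  shocks the models omit).
* The BC α coefficients are external inputs; their uncertainty is not
  propagated into ΔBC.
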