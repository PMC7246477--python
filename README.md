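# trafficimpact

A natural-experiment analysis pipeline for quantifying how the opening of a
traffic-intensive facility (e.g. a delivery warehouse) changes traffic flow,
noise, and traffic-related air pollution in the surrounding neighborhood.
It is written for environmental-health researchers and community groups who
monitor a street with radar vehicle counters, sound-level loggers, and
filter-based particulate samplers, and who want a defensible estimate of the
facility-attributable change in exposure.

## What it computes

**Traffic.** Radar detections are classified by length (small < 4 m, medium
4–7 m, large > 7 m; large = "trucks", small + medium = "cars") and aggregated
into eight daily 3-h windows with coverage accounting.  For each window and
vehicle class an interrupted time series (ITS) model is fitted to the counts
N_t by quasi-Poisson regression with a log link:

    log E[N_t] = β₀ + β₁ t + β₂ X_t + β₃ DoW + β₄ LTST

where X_t steps from 0 to 1 at the facility opening date, DoW is a 7-level
day-of-week factor, and LTST is two sine/cosine harmonic pairs with a
12-month period.  The opening effect is reported as a percent change,
(exp(β₂) − 1)·100, with a Wald 95% CI, and as the attributable flow change
ΔQ — the average difference between the fitted prediction and the
counterfactual prediction with X_t = 0 — separately for weekdays and
weekends.

**Noise.** 10-s A-weighted logger samples are energy-averaged into
equivalent levels, Leq = 10 log₁₀((1/N) Σ 10^(L_i/10)), stratified into
total/daytime/night/weekday/weekend levels over whole days, and screened
against the EPA 70 dBA limit.  The 15-min sound-intensity ratio is regressed
on classified flows with a Gamma GLM (identity link, 3-df spline drift):

    I(t)/I₀ = λ_car Q_car(t) + λ_tr Q_tr(t) + s(t)

and the λ coefficients convert to level slopes ∂Leq/∂Q = 10 λ I₀/I₅₀ at the
site's median intensity, reported in dBA per 100 vehicles/h.

**Attribution.** Attributable flow changes multiply into predicted pollutant
increases: ΔBC = α_tr ΔQ_tr/100 + α_car ΔQ_car/100 (α in µg/m³ per 100
vehicles/h, from a previously published BC–traffic regression) and
ΔLeq = (∂Leq/∂Q_tr) ΔQ_tr/100 + (∂Leq/∂Q_car) ΔQ_car/100, summarized as
mean (SD) across site × window × day-type cells.

A synthetic-data module generates radar event streams, 10-s sound series,
and filter-period air measurements from these same generative forms with
known ground truth, so the whole pipeline is testable without the
(undeposited) field data.

## Worked example

Simulate two years of counts at a high-throughput interstate-ramp site whose
truck flow rises 31.7% in the 21:00–24:00 window after the opening, then
recover the effect:

```python
from trafficimpact import its, synthetic
from trafficimpact.noise import slope_from_lambda

cfg = synthetic.site3_scenario(rng_seed=1)
cfg.step_multipliers["large"][7] = 1.317   # trucks +31.7% in the 21:00-24:00 window
counts = synthetic.generate_window_counts(cfg)
night = counts[counts.window == 7]
design = its.build_design(night["window_start"], its.ITSSpec(opening_date=cfg.opening_date))
fit = its.fit_its(night["trucks"].to_numpy(), design)
pc = its.percent_change(fit)
print(f"trucks 21:00-24:00: {pc.estimate:.1f}% (95% CI {pc.ci_lower:.1f}, {pc.ci_upper:.1f}), "
      f"dispersion {fit.dispersion:.2f}")
change = its.attribute_flows(fit, "weekday")
print(f"attributable weekday change: {change.delta_count:.1f} trucks per 3-h window "
      f"(SE {change.se_count:.1f}, {change.delta_per_hour:.1f}/h)")
print("truck noise slope:", round(slope_from_lambda(138191.0, 67.4), 1), "dBA per 100 trucks/h")
```

prints

```
trucks 21:00-24:00: 39.9% (95% CI 23.6, 58.4), dispersion 12.36
attributable weekday change: 25.4 trucks per 3-h window (SE 4.3, 8.5/h)
truck noise slope: 25.1 dBA per 100 trucks/h
```

The estimate is one over-dispersed realization (dispersion ≈ 12); its CI
covers the configured +31.7%.  The last line converts a truck
intensity coefficient of λ_tr = 138,191 h at a site with a median 15-min
level of 67.4 dBA into the slope 25.1 dBA per 100 trucks/h.

There is also a thin CLI: `trafficimpact simulate --config scenario.yaml
--out data/ --seed 1` writes the radar/noise/air CSVs with a ground-truth
sidecar, and `trafficimpact attribute --its-results flows.csv --coeffs
coeffs.csv --out results/` converts attributable flow changes into pollutant
increases.

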