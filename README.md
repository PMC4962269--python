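# ozexpo

Spatial interpolation of ambient ozone exposure and its association with
lung function.

Epidemiological studies around industrial complexes often have only a
handful of fixed air-quality monitors but need individual-level exposure
for every cohort member. `ozexpo` implements the standard exposure-
assessment tool chain for that setting — modelled on a coastal-bay
industrial area monitored by ~10 stations with a spirometry cohort of
2283 residents in three age strata (children 9–14, adults 15–64, elderly
≥65) — and, because such monitoring and cohort data are rarely
deposited, ships a synthetic-data generator with known ground truth so
every stage is testable end to end.

## What it computes

**Daily metric.** Hourly ozone is collapsed to the regulatory-style
daily maximum 8-h moving average: the largest of the 17 in-day window
means (window starts at hours 0–16; a window is valid with ≥6 of 8 hours,
a day with ≥13 of 17 windows).

**Four exposure estimators** at each residence *s₀* from monitor values
*z(sᵢ)*:

1. *Simple averaging* — the network mean, identical for all subjects.
2. *Nearest monitor* — the closest station's value (Euclidean km).
3. *Inverse distance weighting* — ẑ(s₀) = Σ λᵢ z(sᵢ) with λᵢ ∝ 1/dᵢ
   (power 1; configurable).
4. *Ordinary kriging* — weights from the spherical semivariogram
   γ(h) = c₀ + c₁(1.5 h/a − 0.5 (h/a)³) for h ≤ a, fit by non-negative
   weighted least squares to the binned Matheron estimator, solving the
   augmented system with the unbiasedness constraint Σλᵢ = 1; the
   kriging variance is returned alongside.

**Leave-one-monitor-out cross-validation** scores each estimator with

- RMSE = √( (1/p) Σ (xᵢⱼ − xᵢₖ)² )
- COD  = √( (1/p) Σ [(xᵢⱼ − xᵢₖ)/(xᵢⱼ + xᵢₖ)]² )  ∈ [0, 1]

over measured/predicted pairs (xᵢⱼ, xᵢₖ).

**Lag assembly and regression.** Each subject receives six lagged
exposures around the lung-function test date (0d, 1d, 2d, 0–1d, 1–2d,
0–2d), and OLS of FVC and FEV₁ (litres) on exposure adjusted for age,
sex, height and weight is fit for every method × lag × age-stratum cell
(192 cells), reporting β per interquartile range of exposure with Wald
95% CI and t-test p-value.

## Worked example

```bash
ozexpo run-all --seed 1 --output-dir demo_run
```

runs simulate → metrics → interpolate → crossval → assign → associate →
report and leaves CSVs plus `report.md` and a checksummed
`manifest.json` in `demo_run/`. On the default configuration (10
monitors on a 30 km domain, 120 simulated days in the acceptance
configuration, 2283 subjects, a children-only negative ozone effect of
−0.008 L FVC per ppb) the headline numbers are:

| quantity | value |
|---|---|
| mean test-day exposure, simple averaging | 42.1 ppb |
| mean test-day exposure, kriging | 42.0 ppb |
| LOO RMSE nearest / IDW / kriging | 11.6 / 9.8 / 10.1 ppb |
| LOO COD nearest / IDW / kriging | 0.163 / 0.139 / 0.142 |
| pooled exposure IQR | 13.3 ppb |
| significant negative cells (children / adults / elderly) | 47 / 0 / 0 of 48 |
| children FVC β per IQR, kriging, lag 0–2d | −0.16 L |

The last rows are the qualitative signature the pipeline is built to
expose: an ozone effect injected only in the 9–14 stratum surfaces as
significant negative per-IQR betas concentrated in that stratum across
all methods and lags, largest at lag 0–2d, while adult and elderly
cells stay at the false-positive floor. Under smooth spatial fields with
a pooled variogram fit, leave-one-out error orders kriging ≤ IDW ≤
nearest (see `tests/test_acceptance.py`); in the noisy per-day-refit
default shown above kriging and IDW are statistically comparable.

The same analysis is scriptable:

```python
import ozexpo as oz

study = oz.simulate_study(oz.SimulationConfig(seed=1))
panel = oz.build_daily_panel(study.hourly)          # daily max-8h, ppb
cv = oz.crossval_summary(panel, study.network)      # RMSE / COD table
preds = {m: oz.predict_all(panel, study.network,
                           study.ground_truth.residences, m)
         for m in oz.METHODS}
assignments = oz.assign_all(preds, study.cohort)
effects = oz.run_full_grid(study.cohort, assignments)  # 192-row grid
```

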