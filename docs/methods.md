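# Methods

This note documents the models, numerical choices and limitations of
`ozexpo`, in the order the pipeline runs.

## Synthetic study generator

The generator emulates the statistical structure of a small coastal
industrial airshed with sparse regulatory monitoring, not its
geography, chemistry or meteorology.

**Spatial model.** Coordinates are planar kilometres on a square domain
(default 30 km side); at this scale Euclidean distance on projected
coordinates is indistinguishable from geodesic distance, so no CRS
handling exists anywhere in the package. Daily ozone at any location is

    level(s, d) = regional_mean + u(d) + Z_d(s)

where `u(d)` is a regional AR(1) anomaly (coefficient 0.6, stationary
SD 10 ppb) shared by all locations, and `Z_d` are day-independent
Gaussian random fields with spherical covariance C(h) = sill − γ(h)
(default nugget 10 ppb², partial sill 90 ppb², range 15 km). The nugget
acts as location-independent daily noise. Fields are drawn at the
monitors first and at residences *conditionally* on the monitor draw,
from separate named substreams of the master seed; this makes the
monitor series bit-identical whatever the cohort size — a property the
tests rely on.

**Hourly shaping.** Hourly values are the daily level plus a fixed
cosine diurnal profile peaking at 15:00 (amplitude 15 ppb) plus
independent N(0, 3 ppb) hourly noise, truncated at 0 ppb (ozone is
nonnegative). Nothing downstream uses within-day structure except the
daily max-8h metric, so a deterministic profile suffices; its max-8h
offset (≈0.81 × amplitude) links the latent daily level to the metric
exactly when hourly noise is zero, which several tests exploit.

**Calibration.** Defaults (regional mean 30 ppb + diurnal offset,
field SD ≈ 14 ppb) put the daily max-8h panel near mean 42 ppb, SD
15 ppb — the scale typical of summertime coastal industrial areas — and
stratum sizes default to 200/1419/664 of 2283. Anthropometrics use
stratum-plausible normal distributions (e.g. children height
145 ± 8.5 cm); they only need to be realistic enough to exercise the
covariate adjustment, and are not an accuracy surface.

**Outcomes.** FVC and FEV₁ are stratum baselines plus fixed linear
age/sex/height/weight terms plus `slope × true 0–2-day exposure` at the
residence plus N(0, 0.30 L) noise, lightly clipped so 0 < FEV₁ ≤ FVC.
The default injected effect is confined to children (−0.008 L/ppb FVC,
−0.007 L/ppb FEV₁, ≈ −0.1 to −0.16 L per exposure IQR), with zero
effect in adults and elderly: the configuration whose recovery the
end-to-end checks target. Within a stratum the generative model is
exactly linear in the regression covariates, so noiseless runs recover
slopes to machine precision; across strata baselines differ, which is
why exactness tests fit within one stratum. Test dates are uniform on
days [2, n_days−1] so lags 0–2 always exist.

**What the generator does not emulate:** terrain and land-use gradients,
NOx/VOC photochemistry, seasonal cycles, anisotropy, preferential
monitor siting, measurement drift, time–activity patterns (everyone is
exposed at home), and exposure error correlated with health status.
Passing tests therefore demonstrate correctness of the estimators and
inference machinery under the assumed stationary isotropic model, not
robustness to real-data pathologies.

## Daily max-8h metric

The 17 eight-hour windows are confined to the calendar day (starts at
hours 0–16) — the count 17 forces this reading; trailing cross-midnight
windows would give 24. Completeness follows regulatory convention:
window valid with ≥6/8 hours (mean over present hours, no imputation),
day valid with ≥13/17 windows, else missing. Missing cells propagate as
missing through every later stage.

## Interpolation

* **IDW power = 1** (weight 1/d), the weighting this tool chain is
  built around; the conventional power 2 is a config switch
  (`idw_power`). A target within 1e−9 km of a monitor receives that
  monitor's value exactly.
* **Semivariogram estimation** uses the Matheron estimator with
  equal-width bins on (0, max_lag]; defaults 6 bins, max_lag = half the
  network diameter (standard geostatistical practice). With a panel
  input, squared pair differences pool across days — a shared daily
  mean cancels in pair differences, so pooling isolates spatial
  structure.
* **Spherical fit**: for a fixed range the model is linear in (nugget,
  partial sill), so those are profiled out by non-negative weighted
  least squares (weights = pair counts) and the range is located by a
  48-point grid on (0, 2·max_lag] refined by bounded scalar
  minimization. The SSE is flat in the range beyond the largest lag,
  which defeats naive joint gradient optimization; the profiled search
  is robust and recovers noiseless forward-model parameters to 1e−4.
* **Variogram policy** for kriging a panel: `per_day` (default) refits
  from each day's cross-section and falls back to a pooled all-days fit
  when a day has too few occupied bins; `pooled` uses one fit
  throughout; `fixed` takes a given model. Ten monitors give only 45
  pairs, so daily fits are noisy — the fallback chain (daily → pooled →
  pure nugget at the panel variance) keeps the pipeline total. With a
  pure-nugget model ordinary kriging reduces to the network average by
  symmetry.
* **Ordinary kriging** solves the semivariance system augmented with
  the unbiasedness row; right-hand sides for many targets are solved in
  one factorization. A singular system gets one diagonal
  regularization of 1e−10·sill and then errors. Zero nugget makes the
  predictor an exact interpolator at monitors (variance 0). Monitors
  missing on a day are dropped from the system, never imputed; a
  single-monitor day returns that monitor's value for every method.
* Nearest-neighbour distance ties break on the lowest monitor id for
  determinism.

## Cross-validation

Leave-one-monitor-out: each monitor-day is predicted from the other
monitors; for kriging the variogram is refit from the reduced panel so
the held-out monitor cannot leak into the fit. RMSE and COD both carry
the square root (the COD of a single pair (3, 1) is 0.5); COD pairs
with zero sum are dropped with a logged count — impossible for strictly
positive ozone, defensive for truncated simulations. Statistics are
pooled over all pairs, with per-monitor rows emitted as well. Under
smooth fields (range ≈ half the network diameter, nugget 10% of sill)
the expected ranking kriging ≤ IDW ≤ nearest holds with clear margins;
with per-day refits on noisy metrics the kriging–IDW gap narrows to
statistical parity, which is why the ranking check runs under the
pooled policy.

## Lags, IQR and regression

Single-day lags require their day; multi-day lags tolerate one missing
day (≥2 of their days present). Effects are reported per IQR of
exposure, with one IQR pooled across all methods and lags by default
(mirroring the single published scale such analyses report);
`iqr_policy='per_cell'` switches to per-method-lag IQRs. The per-ppb
slope is estimated first and rescaled, so the IQR choice cannot alter
inference. Quantiles are linear-interpolation quantiles everywhere.

OLS adjusts for age, sex, height and weight — the standard spirometry
covariates; the set is configurable. Collinear designs raise an error
naming the offending columns; constant exposure raises a degenerate-
exposure error; grid cells with fewer than 10 complete cases are logged
and emitted as missing rather than aborting the 192-cell grid. No
multiple-testing correction drives the significance flags (*, ** at
p < 0.05, p < 0.001), matching the reporting convention of the tables
this grid mirrors; a Benjamini–Hochberg column is emitted for readers
who want it.

## Problem sizes

The acceptance script and end-to-end tests run 10 monitors × 120 days ×
2283 subjects — a deliberate design point that keeps a full run near
ten seconds while leaving every stratum its published size; the
cross-validation ranking uses 50 replicates of 60-day panels, and
inference calibration uses 500 null and 200 coverage replicates of an
all-adult cohort of 150 (within-stratum linearity makes that the clean
configuration for calibration).

## Known limitations

* Isotropic spherical variograms only; no universal/co-kriging,
  anisotropy or alternative kernels.
* The AR(1) regional mean induces day-to-day exposure correlation, but
  the regression treats subjects as independent (one test each), as the
  cross-sectional design implies.
* COD's [0, 1] bound assumes nonnegative series; negative inputs are
  not defended against beyond the zero-sum drop.
* The CLI exchanges CSV; very long daily-prediction tables are opt-out
  (`write_daily_predictions: false`) rather than chunked.
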