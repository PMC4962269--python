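"""Synthetic monitoring network, ozone fields and cohort.

The study this package targets — ~10 ozone monitors around a small
industrial coastal bay and a cohort of ~2283 residents in three age
strata — deposits no raw data, so every downstream stage is exercised
on simulated inputs with known ground truth.

The generator emulates the statistical structure the methods rely on:

* monitors scattered uniformly over a square planar domain (km);
* daily ozone as a regional AR(1) mean plus day-independent Gaussian
  random fields with a spherical spatial covariance (nugget = local
  independent variance), drawn jointly at monitors and residences;
* hourly values shaped by a fixed sinusoidal diurnal profile peaking
  mid-afternoon, plus independent hourly noise, truncated at 0 ppb;
* spirometry outcomes (FVC, FEV1 in litres) as stratum baselines plus
  age/sex/height/weight terms plus a configurable linear effect of the
  subject's true 0-2-day ozone exposure, plus Gaussian noise.

Randomness is split into named substreams of one master seed, so e.g.
changing the cohort size cannot perturb the ozone field at monitors
(residence fields are drawn *conditionally* on the monitor fields).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .interpolation import MonitorNetwork, VariogramModel
from .metrics import max_8h_moving_average

AGE_GROUPS = ("9-14", "15-64", ">=65")
OUTCOMES = ("fvc", "fev1")

#: Substream identifiers; the master seed plus one of these spawns an
#: independent generator, so components cannot leak randomness.
_STREAMS = {"monitors": 1, "residences": 2, "field": 3,
            "residence_field": 4, "hourly_noise": 5, "cohort": 6}

#: Fixed diurnal shape: cosine peaking at 15:00 local, unit amplitude.
DIURNAL_PROFILE = np.cos(2 * np.pi * (np.arange(24) - 15) / 24)
#: Max 8-h moving-average of the pure profile; the offset linking the
#: latent daily level to the daily metric when noise is absent.
DIURNAL_MAX8H = float(max_8h_moving_average(DIURNAL_PROFILE))


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


def _default_slopes() -> dict:
    # children-only negative ozone effect, the configuration matching the
    # study's qualitative finding; L per ppb of 0-2d exposure
    return {
        "fvc": {"9-14": -0.008, "15-64": 0.0, ">=65": 0.0},
        "fev1": {"9-14": -0.007, "15-64": 0.0, ">=65": 0.0},
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generator needs; defaults are the study conditions."""

    n_monitors: int = 10
    extent_km: float = 30.0
    n_days: int = 365
    variogram_true: VariogramModel = field(
        default_factory=lambda: VariogramModel(nugget=10.0, partial_sill=90.0,
                                               range_km=15.0))
    diurnal_amplitude: float = 15.0  # ppb
    regional_mean: float = 30.0  # ppb, level before diurnal shaping
    regional_sd: float = 10.0  # ppb, stationary sd of the AR(1) daily mean
    ar1_coefficient: float = 0.6
    hourly_noise_sd: float = 3.0  # ppb
    n_subjects: int = 2283
    age_fractions: tuple[float, float, float] = (200 / 2283, 1419 / 2283,
                                                 664 / 2283)
    effect_slopes: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_slopes)
    outcome_noise_sd: float = 0.30  # L
    start_date: str = "2009-01-01"
    singular_policy: str = "jitter"  # duplicate locations: 'jitter' | 'error'
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_monitors < 1 or self.n_days < 1 or self.n_subjects < 1:
            raise ValueError("counts must be >= 1")
        if self.extent_km <= 0:
            raise ValueError("extent_km must be > 0")
        if abs(sum(self.age_fractions) - 1.0) > 1e-9:
            raise ValueError("age_fractions must sum to 1")
        if any(f < 0 for f in self.age_fractions):
            raise ValueError("age_fractions must be nonnegative")
        if not abs(self.ar1_coefficient) < 1:
            raise ValueError("|ar1_coefficient| must be < 1")
        if self.regional_sd < 0 or self.hourly_noise_sd < 0 \
                or self.outcome_noise_sd < 0:
            raise ValueError("noise scales must be >= 0")
        if self.singular_policy not in ("jitter", "error"):
            raise ValueError("singular_policy must be 'jitter' or 'error'")
        for out in OUTCOMES:
            for g in AGE_GROUPS:
                float(self.effect_slopes[out][g])

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")


@dataclass
class GroundTruth:
    """Latent quantities the estimators are judged against."""

    #: latent daily max-8h-equivalent ozone, index = date, columns = subject id
    true_daily_exposure: pd.DataFrame
    #: latent daily max-8h-equivalent at the monitors (no hourly noise)
    monitor_daily_latent: pd.DataFrame
    #: residence coordinates, index = subject id, columns x_km / y_km
    residences: pd.DataFrame
    true_effect_slopes: Mapping[str, Mapping[str, float]]


# ---------------------------------------------------------------------------
# Monitors and residences
# ---------------------------------------------------------------------------


def generate_monitor_network(config: SimulationConfig) -> MonitorNetwork:
    """Uniformly scatter ``n_monitors`` stations over the square domain."""
    rng = _rng(config.seed, "monitors")
    coords = rng.uniform(0.0, config.extent_km, size=(config.n_monitors, 2))
    ids = tuple(f"M{i + 1:02d}" for i in range(config.n_monitors))
    return MonitorNetwork(ids=ids, coordinates=coords)


def generate_residences(config: SimulationConfig) -> pd.DataFrame:
    """Uniform residential coordinates; index is the subject id."""
    rng = _rng(config.seed, "residences")
    coords = rng.uniform(0.0, config.extent_km, size=(config.n_subjects, 2))
    ids = [f"S{i + 1:04d}" for i in range(config.n_subjects)]
    return pd.DataFrame(coords, index=pd.Index(ids, name="subject_id"),
                        columns=["x_km", "y_km"])


# ---------------------------------------------------------------------------
# Ozone fields
# ---------------------------------------------------------------------------


def _cov_matrix(coords_a: np.ndarray, coords_b: np.ndarray,
                vg: VariogramModel) -> np.ndarray:
    d = np.hypot(coords_a[:, None, 0] - coords_b[None, :, 0],
                 coords_a[:, None, 1] - coords_b[None, :, 1])
    return np.asarray(vg.covariance(d))


def _chol(cov: np.ndarray, vg: VariogramModel, policy: str) -> np.ndarray:
    scale = max(vg.sill, 1e-12)
    try:
        return np.linalg.cholesky(cov + 1e-12 * scale * np.eye(len(cov)))
    except np.linalg.LinAlgError:
        if policy == "error":
            raise
        return np.linalg.cholesky(cov + 1e-6 * scale * np.eye(len(cov)))


def simulate_ozone_field(network: MonitorNetwork,
                         residences: pd.DataFrame | None,
                         config: SimulationConfig):
    """Draw correlated daily fields and shape them into hourly ozone.

    Returns ``(hourly, ground_truth)`` where ``hourly`` is a long
    DataFrame (monitor_id, date, hour, ppb) and ``ground_truth`` holds
    the latent daily max-8h-equivalent values at residences and
    monitors. Monitor fields are drawn first and residence fields
    conditionally on them, so the monitor series are invariant to the
    number (or presence) of residences.
    """
    if len(network) < 1:
        raise ValueError("network must be non-empty")
    vg = config.variogram_true
    dates = config.dates()
    nd = config.n_days

    # regional AR(1) daily mean anomaly, stationary sd = regional_sd
    rng_f = _rng(config.seed, "field")
    u = np.empty(nd)
    if config.regional_sd > 0:
        innov_sd = config.regional_sd * np.sqrt(1 - config.ar1_coefficient**2)
        u[0] = rng_f.normal(0.0, config.regional_sd)
        eps = rng_f.normal(0.0, innov_sd, size=nd - 1) if nd > 1 else []
        for d in range(1, nd):
            u[d] = config.ar1_coefficient * u[d - 1] + eps[d - 1]
    else:
        u[:] = 0.0
        rng_f.normal(size=nd)  # keep stream alignment regardless of sd

    # spatial anomalies at monitors
    cm = _cov_matrix(network.coordinates, network.coordinates, vg)
    lm = _chol(cm, vg, config.singular_policy)
    z_mon = lm @ rng_f.standard_normal((len(network), nd))

    monitor_level = config.regional_mean + u[None, :] + z_mon  # (n_m, nd)
    monitor_latent = np.maximum(
        monitor_level + config.diurnal_amplitude * DIURNAL_MAX8H, 0.0)

    # residence anomalies, conditional on the monitor draw
    res_latent = None
    if residences is not None and len(residences):
        rc = residences[["x_km", "y_km"]].to_numpy(float)
        crm = _cov_matrix(rc, network.coordinates, vg)
        k = np.linalg.solve(cm + 1e-12 * vg.sill * np.eye(len(cm)), crm.T).T
        cond_mean = k @ z_mon
        cond_cov = _cov_matrix(rc, rc, vg) - k @ crm.T
        # symmetrize against round-off before factorization
        cond_cov = (cond_cov + cond_cov.T) / 2
        lc = _chol(cond_cov, vg, "jitter")
        rng_r = _rng(config.seed, "residence_field")
        z_res = cond_mean + lc @ rng_r.standard_normal((len(rc), nd))
        res_level = config.regional_mean + u[None, :] + z_res
        res_latent = np.maximum(
            res_level + config.diurnal_amplitude * DIURNAL_MAX8H, 0.0)

    # hourly shaping at monitors
    rng_h = _rng(config.seed, "hourly_noise")
    noise = (rng_h.normal(0.0, config.hourly_noise_sd,
                          size=(len(network), nd, 24))
             if config.hourly_noise_sd > 0
             else np.zeros((len(network), nd, 24)))
    hourly_vals = (monitor_level[:, :, None]
                   + config.diurnal_amplitude * DIURNAL_PROFILE[None, None, :]
                   + noise)
    hourly_vals = np.maximum(hourly_vals, 0.0)

    idx = pd.MultiIndex.from_product(
        [network.ids, dates, range(24)], names=["monitor_id", "date", "hour"])
    hourly = pd.DataFrame({"ppb": hourly_vals.ravel()}, index=idx).reset_index()

    gt = GroundTruth(
        true_daily_exposure=(pd.DataFrame(res_latent.T, index=dates,
                                          columns=residences.index)
                             if res_latent is not None
                             else pd.DataFrame(index=dates)),
        monitor_daily_latent=pd.DataFrame(monitor_latent.T, index=dates,
                                          columns=list(network.ids)),
        residences=(residences if residences is not None
                    else pd.DataFrame(columns=["x_km", "y_km"])),
        true_effect_slopes=config.effect_slopes,
    )
    return hourly, gt


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

# stratum-plausible anthropometrics: (mean, sd) per age group
_HEIGHT = {"9-14": (145.4, 8.5), "15-64": (162.3, 8.6), ">=65": (155.2, 8.5)}
_WEIGHT = {"9-14": (37.8, 9.9), "15-64": (57.4, 11.6), ">=65": (57.1, 9.9)}
_MALE_FRAC = {"9-14": 0.475, "15-64": 0.465, ">=65": 0.345}
_AGE_RANGE = {"9-14": (9, 14), "15-64": (15, 64), ">=65": (65, 90)}

# fixed covariate coefficients of the outcome model (L per unit)
_COEF = {
    "fvc": {"height": 0.030, "weight": 0.005, "male": 0.25,
            "age": {"9-14": 0.10, "15-64": -0.005, ">=65": -0.015},
            "base": {"9-14": 2.2, "15-64": 3.2, ">=65": 2.6}},
    "fev1": {"height": 0.024, "weight": 0.004, "male": 0.20,
             "age": {"9-14": 0.08, "15-64": -0.006, ">=65": -0.016},
             "base": {"9-14": 1.9, "15-64": 2.7, ">=65": 2.0}},
}


def _stratum_counts(n: int, fractions) -> list[int]:
    """Largest-remainder rounding so counts sum exactly to n."""
    raw = np.asarray(fractions) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base.tolist()


def age_group_of(age) -> pd.Series | str:
    """Map age in years to the study's three strata."""
    def one(a):
        if a < 9:
            raise ValueError("cohort ages start at 9")
        if a <= 14:
            return "9-14"
        if a <= 64:
            return "15-64"
        return ">=65"
    if np.isscalar(age):
        return one(age)
    return pd.Series([one(a) for a in age], index=getattr(age, "index", None))


def expected_covariate_outcome(df: pd.DataFrame, outcome: str) -> np.ndarray:
    """Deterministic part of the outcome model, before ozone and noise."""
    c = _COEF[outcome]
    out = np.empty(len(df))
    for g in AGE_GROUPS:
        m = (df["age_group"] == g).to_numpy()
        h0, _ = _HEIGHT[g]
        w0, _ = _WEIGHT[g]
        a0 = sum(_AGE_RANGE[g]) / 2
        out[m] = (c["base"][g]
                  + c["height"] * (df.loc[m, "height_cm"] - h0)
                  + c["weight"] * (df.loc[m, "weight_kg"] - w0)
                  + c["age"][g] * (df.loc[m, "age"] - a0)
                  + c["male"] * (df.loc[m, "sex"] == "male"))
    return out


def generate_cohort(config: SimulationConfig,
                    ground_truth: GroundTruth) -> pd.DataFrame:
    """Draw demographics, test dates and ozone-dependent spirometry.

    The true exposure driving the outcome is the 0-2-day average of the
    latent daily value at the subject's residence around the test date.
    Test dates are uniform over days [2, n_days-1] so lags 0-2 always
    resolve.
    """
    if config.n_days < 3:
        raise ValueError("n_days must be >= 3 so lags 0-2 exist")
    gt = ground_truth.true_daily_exposure
    if gt.shape[1] < config.n_subjects:
        raise ValueError("ground truth does not cover all subjects")
    rng = _rng(config.seed, "cohort")
    dates = config.dates()
    subjects = list(gt.columns[:config.n_subjects])

    counts = _stratum_counts(config.n_subjects, config.age_fractions)
    groups = np.repeat(AGE_GROUPS, counts)

    rows = {}
    lo = np.array([_AGE_RANGE[g][0] for g in groups])
    hi = np.array([_AGE_RANGE[g][1] for g in groups])
    rows["age"] = rng.integers(lo, hi + 1)
    rows["sex"] = np.where(
        rng.random(config.n_subjects) < [_MALE_FRAC[g] for g in groups],
        "male", "female")
    h_mu = np.array([_HEIGHT[g][0] for g in groups])
    h_sd = np.array([_HEIGHT[g][1] for g in groups])
    rows["height_cm"] = np.clip(rng.normal(h_mu, h_sd), 100.0, 210.0)
    w_mu = np.array([_WEIGHT[g][0] for g in groups])
    w_sd = np.array([_WEIGHT[g][1] for g in groups])
    rows["weight_kg"] = np.clip(rng.normal(w_mu, w_sd), 15.0, 140.0)
    day_idx = rng.integers(2, config.n_days, size=config.n_subjects)
    rows["test_date"] = dates[day_idx]

    df = pd.DataFrame(rows, index=pd.Index(subjects, name="subject_id"))
    df["age_group"] = groups
    df[["x_km", "y_km"]] = ground_truth.residences.loc[subjects,
                                                       ["x_km", "y_km"]]

    # true 0-2d exposure at the residence
    gt_arr = gt.to_numpy()
    col = np.arange(config.n_subjects)
    expo = (gt_arr[day_idx, col] + gt_arr[day_idx - 1, col]
            + gt_arr[day_idx - 2, col]) / 3.0
    df["true_exposure_0_2d"] = expo

    for outcome in OUTCOMES:
        slope = np.array([config.effect_slopes[outcome][g] for g in groups])
        noise = (rng.normal(0.0, config.outcome_noise_sd, config.n_subjects)
                 if config.outcome_noise_sd > 0 else 0.0)
        df[outcome + "_l"] = (expected_covariate_outcome(df, outcome)
                              + slope * expo + noise)
    # physiological sanity: 0 < FEV1 <= FVC
    df["fvc_l"] = np.maximum(df["fvc_l"], 0.2)
    df["fev1_l"] = np.clip(df["fev1_l"], 0.1, df["fvc_l"] - 1e-6)
    return df.reset_index()


# ---------------------------------------------------------------------------
# One-call study generator
# ---------------------------------------------------------------------------


@dataclass
class StudyData:
    config: SimulationConfig
    network: MonitorNetwork
    hourly: pd.DataFrame
    ground_truth: GroundTruth
    cohort: pd.DataFrame


def simulate_study(config: SimulationConfig) -> StudyData:
    """Monitors, hourly ozone and cohort from one config in one call."""
    network = generate_monitor_network(config)
    residences = generate_residences(config)
    hourly, gt = simulate_ozone_field(network, residences, config)
    cohort = generate_cohort(config, gt)
    return StudyData(config=config, network=network, hourly=hourly,
                     ground_truth=gt, cohort=cohort)
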