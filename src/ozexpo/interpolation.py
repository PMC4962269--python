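"""Spatial interpolation of daily ozone at unmonitored locations.

Implements the four exposure-estimation methods used to assign ambient
ozone to residential addresses from a sparse monitor network:

* ``simple_average`` — network mean, identical everywhere;
* ``nearest_neighbor`` — value of the closest monitor;
* ``idw`` — inverse-distance weighting with weight ``1/d`` (power 1);
* ``ordinary_kriging`` — best linear unbiased predictor with weights
  derived from a spherical semivariogram.

All coordinates are planar kilometres; distances are Euclidean. The
study domain (a small coastal bay) is far below the scale where map
projection curvature matters, so no geographic CRS handling is done.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar, nnls

logger = logging.getLogger(__name__)

METHODS = ("simple_average", "nearest", "idw", "kriging")

#: Points closer than this to a monitor are treated as coincident (km).
COINCIDENT_TOL_KM = 1e-9


class NoDataError(ValueError):
    """No non-missing monitor value is available for the request."""


class InsufficientDataError(ValueError):
    """Too few monitors/bins for the requested estimator."""


class DegenerateGeometryError(ValueError):
    """Kriging system remained singular after regularization."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MonitorNetwork:
    """Monitor station ids and planar coordinates (km)."""

    ids: tuple[str, ...]
    coordinates: np.ndarray  # shape (n, 2), km

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("monitor ids must be unique")
        if coords.ndim != 2 or coords.shape != (len(self.ids), 2):
            raise ValueError("coordinates must have shape (n_monitors, 2)")
        if len(self.ids) < 1:
            raise ValueError("network needs at least one monitor")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.ids)

    def distances_to(self, point: Sequence[float]) -> np.ndarray:
        p = np.asarray(point, dtype=float)
        return np.hypot(*(self.coordinates - p).T)

    def pairwise_distances(self) -> np.ndarray:
        d = self.coordinates[:, None, :] - self.coordinates[None, :, :]
        return np.hypot(d[..., 0], d[..., 1])

    def diameter(self) -> float:
        return float(self.pairwise_distances().max())

    def subset(self, keep: Iterable[str]) -> "MonitorNetwork":
        keep = set(keep)
        idx = [i for i, m in enumerate(self.ids) if m in keep]
        return MonitorNetwork(
            ids=tuple(self.ids[i] for i in idx),
            coordinates=self.coordinates[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids,
             "x_km": self.coordinates[:, 0],
             "y_km": self.coordinates[:, 1]}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MonitorNetwork":
        return cls(ids=tuple(df["id"].astype(str)),
                   coordinates=df[["x_km", "y_km"]].to_numpy(float))


@dataclass(frozen=True)
class VariogramModel:
    """Spherical semivariogram: nugget + partial sill rising to a range.

    gamma(h) = c0 + c1 * (1.5 h/a - 0.5 (h/a)^3) for 0 < h <= a,
    gamma(h) = c0 + c1 for h > a, gamma(0) = 0.
    """

    nugget: float  # c0, ppb^2
    partial_sill: float  # c1, ppb^2
    range_km: float  # a, km
    model_form: str = "spherical"

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial sill must be >= 0")
        if self.range_km <= 0:
            raise ValueError("range must be > 0")
        if self.model_form != "spherical":
            raise ValueError(f"unsupported model form {self.model_form!r}")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def __call__(self, h: np.ndarray | float) -> np.ndarray | float:
        h = np.asarray(h, dtype=float)
        r = np.clip(h / self.range_km, 0.0, 1.0)
        g = self.nugget + self.partial_sill * (1.5 * r - 0.5 * r**3)
        g = np.where(h <= 0, 0.0, g)
        return g if g.ndim else float(g)

    def covariance(self, h: np.ndarray | float) -> np.ndarray | float:
        """Stationary covariance C(h) = sill - gamma(h) (nugget at h=0 only)."""
        h = np.asarray(h, dtype=float)
        c = np.where(h <= 0, self.sill, self.sill - self(h))
        return c if c.ndim else float(c)


@dataclass(frozen=True)
class Prediction:
    """A single interpolated value (ppb) at a target location."""

    value: float
    method: str
    n_monitors_used: int
    variance: float | None = None  # kriging variance, ppb^2

    def __post_init__(self) -> None:
        if self.variance is not None and self.variance < -1e-9:
            raise ValueError("kriging variance must be >= 0")


def _clean_day(panel_day: pd.Series) -> pd.Series:
    """Drop missing monitors; raise if nothing is left."""
    vals = pd.Series(panel_day, dtype=float).dropna()
    if vals.empty:
        raise NoDataError("all monitor values missing for this day")
    return vals


# ---------------------------------------------------------------------------
# Method 1 & 2: simple average and nearest monitor
# ---------------------------------------------------------------------------


def simple_average(panel_day: pd.Series) -> Prediction:
    """Mean of all available monitors; the same value at every location."""
    vals = _clean_day(panel_day)
    return Prediction(value=float(vals.mean()), method="simple_average",
                      n_monitors_used=len(vals))


def nearest_neighbor(panel_day: pd.Series, network: MonitorNetwork,
                     point: Sequence[float]) -> Prediction:
    """Value of the closest monitor with data; ties broken by lowest id."""
    vals = _clean_day(panel_day)
    sub = network.subset(vals.index)
    d = sub.distances_to(point)
    # stable tie-break on monitor id
    order = sorted(range(len(sub)), key=lambda i: (d[i], sub.ids[i]))
    chosen = sub.ids[order[0]]
    return Prediction(value=float(vals[chosen]), method="nearest",
                      n_monitors_used=1)


# ---------------------------------------------------------------------------
# Method 3: inverse distance weighting, weight = 1/d (power 1)
# ---------------------------------------------------------------------------


def idw(panel_day: pd.Series, network: MonitorNetwork,
        point: Sequence[float], power: float = 1.0) -> Prediction:
    """Inverse-distance-weighted mean, w_i proportional to d_i**-power.

    The default power of 1 matches the weighting factor 1/d used for
    this study; the conventional choice elsewhere is 2.
    """
    vals = _clean_day(panel_day)
    sub = network.subset(vals.index)
    z = vals[list(sub.ids)].to_numpy(float)
    d = sub.distances_to(point)
    hit = d < COINCIDENT_TOL_KM
    if hit.any():
        i = int(np.argmax(hit))
        return Prediction(value=float(z[i]), method="idw", n_monitors_used=1)
    w = d ** (-power)
    w /= w.sum()
    return Prediction(value=float(w @ z), method="idw",
                      n_monitors_used=len(z))


# ---------------------------------------------------------------------------
# Method 4: ordinary kriging with a spherical semivariogram
# ---------------------------------------------------------------------------


def empirical_semivariogram(values, network: MonitorNetwork,
                            n_bins: int = 6,
                            max_lag: float | None = None) -> pd.DataFrame:
    """Binned Matheron estimator of the semivariogram.

    ``values`` may be a Series (one day, indexed by monitor id) or a
    DataFrame (days x monitor ids); with a DataFrame the squared pair
    differences are pooled across days, which is how a short panel from
    few monitors accumulates enough pairs for a stable fit. A common
    day-level mean shift cancels in the pair differences, so the pooled
    estimate reflects purely spatial structure.

    Returns a DataFrame with columns ``lag_km`` (mean pair distance in
    the bin), ``gamma`` (ppb^2) and ``n_pairs``; empty bins are dropped.
    """
    if isinstance(values, pd.Series):
        frame = values.to_frame().T
    else:
        frame = pd.DataFrame(values)
    frame = frame.dropna(axis=1, how="all")
    monitors = [m for m in frame.columns if m in set(network.ids)]
    if len(monitors) < 2:
        raise InsufficientDataError("semivariogram needs >= 2 monitors")
    sub = network.subset(monitors)
    dmat = sub.pairwise_distances()
    if max_lag is None:
        max_lag = sub.diameter() / 2 if len(sub) > 2 else sub.diameter()
    if max_lag <= 0:
        raise InsufficientDataError("degenerate network: all monitors coincide")

    z = frame[list(sub.ids)].to_numpy(float)  # (days, monitors)
    iu, ju = np.triu_indices(len(sub), k=1)
    d_pairs = dmat[iu, ju]
    sq = (z[:, iu] - z[:, ju]) ** 2  # (days, pairs); NaN where either missing
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    rows = []
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        in_bin = (d_pairs > lo) & (d_pairs <= hi)
        if not in_bin.any():
            continue
        vals = sq[:, in_bin].ravel()
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        dsel = np.broadcast_to(d_pairs[in_bin], sq[:, in_bin].shape).ravel()
        dsel = dsel[np.isfinite(sq[:, in_bin]).ravel()]
        rows.append({"lag_km": float(dsel.mean()),
                     "gamma": float(vals.mean() / 2.0),
                     "n_pairs": int(vals.size)})
    return pd.DataFrame(rows, columns=["lag_km", "gamma", "n_pairs"])


def _spherical(h, c0, c1, a):
    r = np.clip(h / a, 0.0, 1.0)
    return c0 + c1 * (1.5 * r - 0.5 * r**3)


def _profiled_sse(a: float, h: np.ndarray, g: np.ndarray,
                  sqw: np.ndarray) -> tuple[float, float, float]:
    """For fixed range a, solve the WLS in (c0, c1) with c0, c1 >= 0."""
    X = np.column_stack([np.ones_like(h), _spherical(h, 0.0, 1.0, a)])
    coef, rnorm = nnls(X * sqw[:, None], g * sqw)
    return float(rnorm**2), float(coef[0]), float(coef[1])


def fit_spherical_variogram(bins: pd.DataFrame) -> VariogramModel:
    """Weighted least squares fit of the spherical model to binned gamma.

    Weights are pair counts. For a fixed range the model is linear in
    (nugget, partial sill), so those are profiled out by non-negative
    WLS and the range is found by a grid search over (0, 2*max_lag]
    refined with a bounded scalar minimization — the loss surface in
    the range is flat past the largest lag, which defeats naive joint
    optimization. Degenerate all-zero input collapses to a flat model
    (c0 = c1 = 0, nominal range).
    """
    if bins is None or len(bins) < 3:
        raise InsufficientDataError("variogram fit needs >= 3 non-empty bins")
    h = bins["lag_km"].to_numpy(float)
    g = bins["gamma"].to_numpy(float)
    w = bins["n_pairs"].to_numpy(float)
    max_lag = float(h.max())
    if np.allclose(g, 0.0):
        return VariogramModel(nugget=0.0, partial_sill=0.0, range_km=max_lag)

    sqw = np.sqrt(w)
    grid = np.linspace(0.05 * max_lag, 2.0 * max_lag, 48)
    sses = [_profiled_sse(a, h, g, sqw)[0] for a in grid]
    i = int(np.argmin(sses))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(lambda a: _profiled_sse(a, h, g, sqw)[0],
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8 * max_lag})
    a_best = float(res.x) if res.success else float(grid[i])
    _, c0, c1 = _profiled_sse(a_best, h, g, sqw)
    return VariogramModel(nugget=c0, partial_sill=c1, range_km=a_best)


def _kriging_system(sub: MonitorNetwork, variogram: VariogramModel,
                    points: np.ndarray):
    """Assemble and solve the ordinary-kriging system for many points.

    Returns (weights (n_monitors, n_points), lagrange (n_points,),
    gamma0 (n_monitors, n_points)).
    """
    n = len(sub)
    dmat = sub.pairwise_distances()
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = variogram(dmat)
    A[n, :] = 1.0
    A[:, n] = 1.0
    A[n, n] = 0.0
    d0 = np.hypot(
        sub.coordinates[:, None, 0] - points[None, :, 0],
        sub.coordinates[:, None, 1] - points[None, :, 1],
    )  # (n, m)
    B = np.empty((n + 1, d0.shape[1]))
    B[:n] = variogram(d0)
    B[n] = 1.0
    try:
        sol = np.linalg.solve(A, B)
    except np.linalg.LinAlgError:
        A2 = A.copy()
        A2[np.diag_indices(n)] += 1e-10 * max(variogram.sill, 1.0)
        try:
            sol = np.linalg.solve(A2, B)
        except np.linalg.LinAlgError as exc:
            raise DegenerateGeometryError(
                "kriging system singular after regularization") from exc
    return sol[:n], sol[n], B[:n]


def ordinary_kriging(panel_day: pd.Series, network: MonitorNetwork,
                     variogram: VariogramModel,
                     point: Sequence[float]) -> Prediction:
    """Ordinary-kriging prediction and variance at one target point.

    Solves the augmented system (semivariances among monitors plus the
    unbiasedness constraint sum(lambda) = 1); the kriging variance is
    sum(lambda_i gamma_i0) + mu. With a zero nugget the predictor
    interpolates exactly at monitor locations.
    """
    vals = _clean_day(panel_day)
    if len(vals) < 2:
        raise InsufficientDataError("ordinary kriging needs >= 2 monitors")
    sub = network.subset(vals.index)
    pt = np.asarray(point, dtype=float)[None, :]
    if variogram.nugget == 0:
        d = sub.distances_to(pt[0])
        hit = d < COINCIDENT_TOL_KM
        if hit.any():
            i = int(np.argmax(hit))
            return Prediction(value=float(vals[sub.ids[i]]), method="kriging",
                              n_monitors_used=1, variance=0.0)
    lam, mu, g0 = _kriging_system(sub, variogram, pt)
    z = vals[list(sub.ids)].to_numpy(float)
    value = float(lam[:, 0] @ z)
    var = float(lam[:, 0] @ g0[:, 0] + mu[0])
    return Prediction(value=value, method="kriging",
                      n_monitors_used=len(z), variance=max(var, 0.0))


# ---------------------------------------------------------------------------
# Panel-wide prediction
# ---------------------------------------------------------------------------


@dataclass
class VariogramPolicy:
    """How kriging obtains its variogram for each day of a panel.

    mode='per_day': refit from that day's available monitors, falling
    back to a pooled all-days fit (and finally a pure nugget at the
    panel variance) when the daily fit is impossible or fails.
    mode='pooled': one pooled fit shared by all days.
    mode='fixed': use ``fixed`` as given.
    """

    mode: str = "per_day"
    n_bins: int = 6
    max_lag: float | None = None
    fixed: VariogramModel | None = None
    n_fallbacks: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        if self.mode not in ("per_day", "pooled", "fixed"):
            raise ValueError(f"unknown variogram policy mode {self.mode!r}")
        if self.mode == "fixed" and self.fixed is None:
            raise ValueError("fixed policy requires a variogram")


def _pooled_variogram(panel: pd.DataFrame, network: MonitorNetwork,
                      policy: VariogramPolicy) -> VariogramModel:
    # small networks can leave < 3 occupied bins at the default lag cut;
    # retry with coarser bins out to the full diameter before giving up
    attempts = [(policy.n_bins, policy.max_lag)]
    if len(network) >= 2:
        attempts.append((max(policy.n_bins - 2, 3), network.diameter()))
    for n_bins, max_lag in attempts:
        try:
            bins = empirical_semivariogram(panel, network, n_bins=n_bins,
                                           max_lag=max_lag)
            return fit_spherical_variogram(bins)
        except InsufficientDataError:
            continue
    var = float(np.nanvar(panel.to_numpy(float)))
    logger.warning("pooled variogram fit impossible; pure nugget used")
    return VariogramModel(nugget=max(var, 1e-12), partial_sill=0.0,
                          range_km=1.0)


def resolve_variograms(panel: pd.DataFrame, network: MonitorNetwork,
                       policy: VariogramPolicy) -> dict:
    """Return {date: VariogramModel} for every row of the panel."""
    if policy.mode == "fixed":
        return {d: policy.fixed for d in panel.index}
    pooled = _pooled_variogram(panel, network, policy)
    if policy.mode == "pooled":
        return {d: pooled for d in panel.index}
    out = {}
    for d in panel.index:
        day = panel.loc[d].dropna()
        try:
            bins = empirical_semivariogram(day, network, n_bins=policy.n_bins,
                                           max_lag=policy.max_lag)
            out[d] = fit_spherical_variogram(bins)
        except InsufficientDataError:
            policy.n_fallbacks += 1
            out[d] = pooled
    return out


def predict_all(panel: pd.DataFrame, network: MonitorNetwork,
                locations: pd.DataFrame, method: str,
                variogram_policy: VariogramPolicy | None = None,
                idw_power: float = 1.0,
                return_variance: bool = False):
    """Predict daily ozone for every (location, day) of the panel.

    ``panel``: DataFrame of daily metric values, index = date, columns =
    monitor ids, NaN where a monitor-day failed completeness.
    ``locations``: DataFrame with index = location/subject id and columns
    x_km, y_km.

    Returns a DataFrame (index = date, columns = location id) of ppb; if
    ``return_variance`` and method='kriging', a (values, variances) pair.
    Days where every monitor is missing propagate as NaN rows.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    pts = locations[["x_km", "y_km"]].to_numpy(float)
    out = pd.DataFrame(np.nan, index=panel.index, columns=locations.index)
    var_out = pd.DataFrame(np.nan, index=panel.index, columns=locations.index)

    variograms = None
    if method == "kriging":
        policy = variogram_policy or VariogramPolicy()
        variograms = resolve_variograms(panel, network, policy)

    for d in panel.index:
        day = panel.loc[d].dropna()
        if day.empty:
            continue
        sub = network.subset(day.index)
        z = day[list(sub.ids)].to_numpy(float)
        if len(sub) == 1:
            # every method degenerates to the lone monitor's value
            out.loc[d] = z[0]
            var_out.loc[d] = 0.0
            continue
        if method == "simple_average":
            out.loc[d] = float(z.mean())
            continue
        dists = np.hypot(
            sub.coordinates[:, None, 0] - pts[None, :, 0],
            sub.coordinates[:, None, 1] - pts[None, :, 1],
        )  # (n_monitors, n_points)
        if method == "nearest":
            # argmin over distance with rows id-sorted, so exact distance
            # ties resolve to the lowest monitor id
            idsort = np.argsort(np.array(sub.ids))
            d_sorted = dists[idsort]
            pick = idsort[np.argmin(d_sorted, axis=0)]
            out.loc[d] = z[pick]
        elif method == "idw":
            w = dists ** (-idw_power)
            coincident = dists < COINCIDENT_TOL_KM
            pred = np.empty(dists.shape[1])
            reg = ~coincident.any(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                wr = w[:, reg]
                pred_reg = (wr * z[:, None]).sum(0) / wr.sum(0)
            pred[reg] = pred_reg
            for j in np.nonzero(~reg)[0]:
                pred[j] = z[int(np.argmax(coincident[:, j]))]
            out.loc[d] = pred
        elif method == "kriging":
            vg = variograms[d]
            lam, mu, g0 = _kriging_system(sub, vg, pts)
            pred = lam.T @ z
            kvar = np.maximum((lam * g0).sum(0) + mu, 0.0)
            if vg.nugget == 0:
                hit = dists < COINCIDENT_TOL_KM
                for j in np.nonzero(hit.any(axis=0))[0]:
                    pred[j] = z[int(np.argmax(hit[:, j]))]
                    kvar[j] = 0.0
            out.loc[d] = pred
            var_out.loc[d] = kvar
    if return_variance and method == "kriging":
        return out, var_out
    return out
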