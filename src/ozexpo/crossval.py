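"""Leave-one-monitor-out cross-validation of the interpolation methods.

Each monitor's value is excluded in turn and predicted from the rest of
the network; predictions are scored against measurements with RMSE and
the coefficient of divergence (COD):

    RMSE = sqrt( (1/p) * sum (x_meas - x_pred)^2 )
    COD  = sqrt( (1/p) * sum [ (x_meas - x_pred) / (x_meas + x_pred) ]^2 )

COD is scale-free and bounded in [0, 1] for nonnegative series; 0 means
the two series agree exactly, values near 1 maximal divergence.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .interpolation import (
    InsufficientDataError,
    MonitorNetwork,
    VariogramPolicy,
    predict_all,
)

logger = logging.getLogger(__name__)


def rmse(measured, predicted) -> float:
    """Root mean square error between paired series (ppb)."""
    x = np.asarray(measured, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape:
        raise ValueError("measured and predicted must have equal length")
    if x.size == 0:
        raise InsufficientDataError("RMSE of an empty series")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def cod(measured, predicted) -> float:
    """Coefficient of divergence between paired nonnegative series.

    Pairs whose sum is zero (ratio undefined) are dropped with a logged
    count; they cannot occur for strictly positive ozone.
    """
    x = np.asarray(measured, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape:
        raise ValueError("measured and predicted must have equal length")
    if x.size == 0:
        raise InsufficientDataError("COD of an empty series")
    s = x + y
    keep = s > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("COD: dropped %d zero-sum pairs", dropped)
    if not keep.any():
        raise InsufficientDataError("COD: all pairs had zero sum")
    r = (x[keep] - y[keep]) / s[keep]
    return float(np.sqrt(np.mean(r**2)))


def loo_predict(panel: pd.DataFrame, network: MonitorNetwork, method: str,
                variogram_policy: VariogramPolicy | None = None,
                idw_power: float = 1.0) -> pd.DataFrame:
    """Leave-one-out predictions at every monitor with data.

    For each monitor m, its column is removed from the panel and the
    chosen method predicts at m's location from the remaining monitors
    — for kriging the variogram is refit from the reduced panel so the
    held-out monitor cannot leak into the fit. ``simple_average`` is
    permitted (mean of the others) though it ignores location entirely.

    Returns a long DataFrame (monitor_id, date, measured, predicted).
    """
    if len(network) < 2:
        raise InsufficientDataError("LOO needs >= 2 monitors")
    frames = []
    for m in network.ids:
        if m not in panel.columns:
            continue
        reduced = panel.drop(columns=m)
        rest = network.subset(reduced.columns)
        loc = pd.DataFrame(
            [network.coordinates[network.ids.index(m)]],
            index=pd.Index([m], name="location"), columns=["x_km", "y_km"])
        policy = None
        if method == "kriging" and variogram_policy is not None:
            policy = VariogramPolicy(mode=variogram_policy.mode,
                                     n_bins=variogram_policy.n_bins,
                                     max_lag=variogram_policy.max_lag,
                                     fixed=variogram_policy.fixed)
        pred = predict_all(reduced, rest, loc, method,
                           variogram_policy=policy, idw_power=idw_power)
        out = pd.DataFrame({
            "monitor_id": m,
            "date": panel.index,
            "measured": panel[m].to_numpy(float),
            "predicted": pred[m].to_numpy(float),
        })
        frames.append(out)
    res = pd.concat(frames, ignore_index=True)
    return res.dropna(subset=["measured", "predicted"]).reset_index(drop=True)


def crossval_summary(panel: pd.DataFrame, network: MonitorNetwork,
                     methods=("nearest", "idw", "kriging"),
                     variogram_policy: VariogramPolicy | None = None,
                     idw_power: float = 1.0,
                     per_monitor: bool = True) -> pd.DataFrame:
    """RMSE/COD table over LOO pairs, pooled and (optionally) per monitor."""
    rows = []
    for method in methods:
        pairs = loo_predict(panel, network, method,
                            variogram_policy=variogram_policy,
                            idw_power=idw_power)
        rows.append({"method": method, "monitor_id": "ALL",
                     "n_pairs": len(pairs),
                     "rmse_ppb": rmse(pairs["measured"], pairs["predicted"]),
                     "cod": cod(pairs["measured"], pairs["predicted"])})
        if per_monitor:
            for m, grp in pairs.groupby("monitor_id", sort=True):
                rows.append({"method": method, "monitor_id": m,
                             "n_pairs": len(grp),
                             "rmse_ppb": rmse(grp["measured"],
                                              grp["predicted"]),
                             "cod": cod(grp["measured"], grp["predicted"])})
    return pd.DataFrame(rows)
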