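"""Daily maximum 8-hour moving-average ozone metric.

The regulatory-style daily exposure metric: within each calendar day
there are 17 eight-hour windows (starting hours 0..16); each window's
mean is computed, and the day's metric is the maximum over them.
Completeness rules follow the usual regulatory convention: a window is
valid with at least 6 of its 8 hours present (mean over present hours),
and a day is valid with at least 13 of the 17 windows valid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: 8-hour windows confined to the calendar day: starts 0..16.
N_WINDOWS = 17
WINDOW_HOURS = 8
MIN_HOURS_PER_WINDOW = 6
MIN_VALID_WINDOWS = 13


def max_8h_moving_average(day_values, return_n_valid: bool = False):
    """Daily max 8-h moving average of a 24-slot hourly vector.

    Parameters
    ----------
    day_values : sequence of 24 floats, NaN for missing hours.
    return_n_valid : also return the number of valid windows.

    Returns NaN when fewer than 13 of the 17 windows are valid.
    """
    v = np.asarray(day_values, dtype=float)
    if v.shape != (24,):
        raise ValueError(f"expected 24 hourly slots, got shape {v.shape}")
    present = np.isfinite(v)
    # sliding window sums over present hours
    means = np.full(N_WINDOWS, np.nan)
    for s in range(N_WINDOWS):
        w = v[s:s + WINDOW_HOURS]
        m = present[s:s + WINDOW_HOURS]
        if m.sum() >= MIN_HOURS_PER_WINDOW:
            means[s] = w[m].mean()
    n_valid = int(np.isfinite(means).sum())
    out = float(np.nanmax(means)) if n_valid >= MIN_VALID_WINDOWS else float("nan")
    if return_n_valid:
        return out, n_valid
    return out


def daily_mean(day_values, return_n_valid: bool = False):
    """Plain daily mean over present hours (>= 18 of 24 required).

    A secondary metric used for sanity checks; the pipeline default is
    the max 8-h moving average.
    """
    v = np.asarray(day_values, dtype=float)
    if v.shape != (24,):
        raise ValueError(f"expected 24 hourly slots, got shape {v.shape}")
    present = np.isfinite(v)
    out = float(v[present].mean()) if present.sum() >= 18 else float("nan")
    if return_n_valid:
        return out, int(present.sum())
    return out


_METRICS = {"max8h": max_8h_moving_average, "daily_mean": daily_mean}


def build_daily_panel(hourly: pd.DataFrame, metric: str = "max8h",
                      with_window_counts: bool = False):
    """Collapse long-format hourly ozone into a daily metric panel.

    Parameters
    ----------
    hourly : DataFrame with columns monitor_id, date, hour, ppb
        (hour in 0..23; ppb NaN or absent rows for missing hours).
    metric : 'max8h' (default) or 'daily_mean'.

    Returns
    -------
    DataFrame indexed by date with one column per monitor_id; cells are
    ppb, NaN where the day failed the completeness rule. With
    ``with_window_counts`` a second long DataFrame of per-cell valid
    window (or hour) counts is returned too.
    """
    if hourly is None or len(hourly) == 0:
        raise ValueError("hourly input is empty")
    required = {"monitor_id", "date", "hour", "ppb"}
    missing = required - set(hourly.columns)
    if missing:
        raise ValueError(f"hourly input missing columns {sorted(missing)}")
    if hourly.duplicated(["monitor_id", "date", "hour"]).any():
        raise ValueError("duplicate (monitor, date, hour) rows")
    bad_hours = ~hourly["hour"].between(0, 23)
    if bad_hours.any():
        raise ValueError("hour values must be in 0..23")
    fn = _METRICS[metric]

    wide = hourly.pivot_table(index=["monitor_id", "date"], columns="hour",
                              values="ppb", dropna=False)
    wide = wide.reindex(columns=range(24))
    arr = wide.to_numpy(float)
    vals = np.empty(arr.shape[0])
    counts = np.empty(arr.shape[0], dtype=int)
    for i in range(arr.shape[0]):
        vals[i], counts[i] = fn(arr[i], return_n_valid=True)
    res = pd.Series(vals, index=wide.index, name="ppb")
    panel = res.unstack("monitor_id").sort_index()
    panel.columns = panel.columns.astype(str)
    if with_window_counts:
        cdf = pd.DataFrame({"ppb": vals, "n_valid_windows": counts},
                           index=wide.index).reset_index()
        return panel, cdf
    return panel
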