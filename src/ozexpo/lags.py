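"""Lag-structured exposure assembly.

Each subject's assigned ozone exposure is built from their predicted
daily values relative to the lung-function test date, under six lag
definitions: the test day (0d), one and two days before (1d, 2d), and
the averages 0-1d, 1-2d and 0-2d. Regression effects downstream are
scaled per interquartile range (IQR) of exposure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .interpolation import InsufficientDataError

#: label -> day offsets before the test date
LAG_SPECS: dict[str, tuple[int, ...]] = {
    "0d": (0,),
    "1d": (1,),
    "2d": (2,),
    "0-1d": (0, 1),
    "1-2d": (1, 2),
    "0-2d": (0, 1, 2),
}
LAG_LABELS = tuple(LAG_SPECS)


def _min_required(offsets: tuple[int, ...]) -> int:
    # single-day lags need their day; multi-day averages tolerate one
    # missing day (>= 2 of their days present)
    return 1 if len(offsets) == 1 else 2


def assign_exposure(predictions: pd.DataFrame, cohort: pd.DataFrame,
                    lag: str) -> pd.Series:
    """Per-subject lagged exposure from a daily prediction table.

    ``predictions``: DataFrame indexed by date with one column per
    subject id (the output of ``interpolation.predict_all``).
    ``cohort``: must carry subject_id and test_date.

    Returns a float Series indexed by subject_id (NaN where the lag's
    completeness rule fails).
    """
    if lag not in LAG_SPECS:
        raise ValueError(f"unknown lag {lag!r}; expected one of {LAG_LABELS}")
    offsets = LAG_SPECS[lag]
    subjects = cohort["subject_id"].astype(str)
    missing = set(subjects) - set(map(str, predictions.columns))
    if missing:
        raise KeyError(
            f"{len(missing)} subjects absent from predictions, "
            f"e.g. {sorted(missing)[:3]}")
    dates = pd.DatetimeIndex(predictions.index)
    test = pd.DatetimeIndex(cohort["test_date"])
    col_pos = predictions.columns.get_indexer(subjects)
    arr = predictions.to_numpy(float)

    stacked = np.full((len(offsets), len(cohort)), np.nan)
    for k, off in enumerate(offsets):
        want = test - pd.Timedelta(days=off)
        row_pos = dates.get_indexer(want)
        ok = row_pos >= 0
        stacked[k, ok] = arr[row_pos[ok], col_pos[ok]]
    n_present = np.isfinite(stacked).sum(axis=0)
    vals = np.nansum(stacked, axis=0) / np.maximum(n_present, 1)
    vals[n_present < _min_required(offsets)] = np.nan
    return pd.Series(vals, index=pd.Index(subjects, name="subject_id"),
                     name=lag)


def assign_all(predictions_by_method: dict[str, pd.DataFrame],
               cohort: pd.DataFrame,
               lags=LAG_LABELS) -> pd.DataFrame:
    """Long table of assignments: subject_id, method, lag, ppb."""
    frames = []
    for method, preds in predictions_by_method.items():
        for lag in lags:
            s = assign_exposure(preds, cohort, lag)
            frames.append(pd.DataFrame({
                "subject_id": s.index, "method": method, "lag": lag,
                "ppb": s.to_numpy()}))
    return pd.concat(frames, ignore_index=True)


def exposure_iqr(values) -> float:
    """Interquartile range (75th - 25th percentile, linear interpolation).

    The single scale used to report regression effects per-IQR.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        raise InsufficientDataError("IQR needs >= 4 non-missing values")
    q25, q75 = np.percentile(v, [25, 75])
    return float(q75 - q25)


def pooled_iqr(assignments: pd.DataFrame) -> float:
    """IQR pooled over all methods and lags — one scale for every cell.

    The study reports a single IQR for ozone despite estimating
    exposure under four methods and six lags, so pooling is the default;
    per-(method, lag) IQRs remain available via ``exposure_iqr`` on a
    filtered table.
    """
    return exposure_iqr(assignments["ppb"])
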