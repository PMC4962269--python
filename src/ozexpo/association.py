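"""Age-stratified regression of lung function on assigned ozone.

For each combination of outcome (FVC, FEV1), exposure-estimation
method, lag and age stratum (children 9-14, adults 15-64, elderly >=65,
plus All), an ordinary least squares model

    outcome ~ exposure + age + sex + height + weight

is fit; the exposure slope (L per ppb) is rescaled to L per IQR of
exposure and reported with a Wald 95% CI and two-sided t-test p-value.
Significance is flagged at p < 0.05 (*) and p < 0.001 (**); a
Benjamini-Hochberg adjusted p-value is emitted alongside but does not
drive the flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .lags import LAG_LABELS, pooled_iqr
from .synthetic import AGE_GROUPS

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex", "height_cm", "weight_kg")
OUTCOME_COLUMNS = {"fvc": "fvc_l", "fev1": "fev1_l"}


class RankDeficiencyError(ValueError):
    """The design matrix is collinear; message names the columns."""


class DegenerateExposureError(ValueError):
    """Exposure has no variation in the analysis subset."""


@dataclass(frozen=True)
class EffectEstimate:
    """Per-IQR ozone effect on a spirometric outcome."""

    outcome: str
    method: str
    lag: str
    age_group: str  # one of AGE_GROUPS or 'All'
    beta_per_iqr: float  # L per IQR ppb
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    beta_per_ppb: float
    se_per_iqr: float
    iqr_ppb: float

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-12 <= self.beta_per_iqr
                <= self.ci_high + 1e-12):
            raise ValueError("CI must bracket the point estimate")


def _design(df: pd.DataFrame, covariates) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    X["exposure"] = df["exposure"].astype(float)
    for c in covariates:
        if c == "sex":
            X["sex_male"] = (df["sex"] == "male").astype(float)
        else:
            X[c] = df[c].astype(float)
    return sm.add_constant(X, has_constant="add")


def fit_association(cohort: pd.DataFrame, exposure: pd.Series, outcome: str,
                    iqr_ppb: float,
                    covariates=DEFAULT_COVARIATES,
                    method: str = "", lag: str = "",
                    age_group: str = "All") -> EffectEstimate:
    """OLS of one outcome on exposure plus covariates for one stratum.

    ``exposure`` is indexed by subject_id in ppb; ``iqr_ppb`` is the
    scale for per-IQR reporting (estimated per-ppb first, rescaled
    after, so the choice of IQR cannot alter inference).
    """
    ycol = OUTCOME_COLUMNS[outcome]
    df = cohort.set_index("subject_id") if "subject_id" in cohort else cohort
    df = df.copy()
    df["exposure"] = exposure.reindex(df.index).astype(float)
    if age_group != "All":
        df = df[df["age_group"] == age_group]
    df = df.dropna(subset=["exposure", ycol, *[c for c in covariates
                                               if c != "sex"]])
    n = len(df)
    if n < 10:
        raise ValueError(f"only {n} complete cases; need >= 10")
    if np.ptp(df["exposure"].to_numpy(float)) == 0:
        raise DegenerateExposureError("exposure is constant in this stratum")
    X = _design(df, covariates)
    rank = np.linalg.matrix_rank(X.to_numpy(float))
    if rank < X.shape[1]:
        # name columns whose removal restores full rank
        bad = [c for c in X.columns if c != "const" and
               np.linalg.matrix_rank(X.drop(columns=c).to_numpy(float)) == rank]
        raise RankDeficiencyError(f"collinear design; offending: {bad}")
    res = sm.OLS(df[ycol].astype(float), X).fit()
    beta = float(res.params["exposure"])
    se = float(res.bse["exposure"])
    ci = res.conf_int(alpha=0.05).loc["exposure"]
    return EffectEstimate(
        outcome=outcome, method=method, lag=lag, age_group=age_group,
        beta_per_iqr=beta * iqr_ppb,
        ci_low=float(ci[0]) * iqr_ppb, ci_high=float(ci[1]) * iqr_ppb,
        p_value=float(res.pvalues["exposure"]), n=n,
        beta_per_ppb=beta, se_per_iqr=se * iqr_ppb, iqr_ppb=iqr_ppb)


def _sig_flag(p: float) -> str:
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def run_full_grid(cohort: pd.DataFrame, assignments: pd.DataFrame,
                  covariates=DEFAULT_COVARIATES,
                  iqr_policy: str = "pooled",
                  methods=None, lags=LAG_LABELS) -> pd.DataFrame:
    """Fit every (outcome, method, lag, age group) cell of the grid.

    ``assignments``: long table (subject_id, method, lag, ppb). With 4
    methods and 6 lags the grid is 2 outcomes x 4 x 6 x 4 groups = 192
    rows. Per-cell failures (too few cases, degenerate exposure) are
    logged and emitted as rows with missing estimates rather than
    aborting the grid.

    ``iqr_policy``: 'pooled' (one IQR across all methods and lags, the
    default) or 'per_cell' (IQR of each method-lag distribution).
    """
    if iqr_policy not in ("pooled", "per_cell"):
        raise ValueError("iqr_policy must be 'pooled' or 'per_cell'")
    if methods is None:
        methods = list(dict.fromkeys(assignments["method"]))
    iqr_all = pooled_iqr(assignments)
    rows = []
    groups = list(AGE_GROUPS) + ["All"]
    for outcome in OUTCOME_COLUMNS:
        for method in methods:
            for lag in lags:
                sub = assignments[(assignments["method"] == method)
                                  & (assignments["lag"] == lag)]
                expo = sub.set_index("subject_id")["ppb"]
                iqr = (iqr_all if iqr_policy == "pooled"
                       else float(np.nanpercentile(expo, 75)
                                  - np.nanpercentile(expo, 25)))
                for grp in groups:
                    base = {"outcome": outcome, "method": method, "lag": lag,
                            "age_group": grp}
                    try:
                        est = fit_association(
                            cohort, expo, outcome, iqr, covariates=covariates,
                            method=method, lag=lag, age_group=grp)
                    except (ValueError, KeyError) as exc:
                        logger.warning("grid cell %s failed: %s", base, exc)
                        rows.append({**base, "n": np.nan,
                                     "beta_per_iqr": np.nan,
                                     "ci_low": np.nan, "ci_high": np.nan,
                                     "p": np.nan, "sig_flag": "",
                                     "beta_per_ppb": np.nan,
                                     "iqr_ppb": iqr})
                        continue
                    rows.append({**base, "n": est.n,
                                 "beta_per_iqr": est.beta_per_iqr,
                                 "ci_low": est.ci_low,
                                 "ci_high": est.ci_high,
                                 "p": est.p_value,
                                 "sig_flag": _sig_flag(est.p_value),
                                 "beta_per_ppb": est.beta_per_ppb,
                                 "iqr_ppb": est.iqr_ppb})
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["p_bh"] = np.nan
    if ok.any():
        out.loc[ok, "p_bh"] = multipletests(out.loc[ok, "p"],
                                            method="fdr_bh")[1]
    return out
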