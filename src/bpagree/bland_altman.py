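"""Bland-Altman agreement analysis and the ISO criterion-1 check.

Sign convention (package-wide): the difference is **reference minus
test**, so a positive mean difference means the test device reads low.
Three variants are provided:

* :func:`classic_ba` - mean difference, SD and 1.96-SD limits of
  agreement, plus an OLS slope of difference on average whose t-test
  flags proportional bias;
* :func:`log_ba` - the same on natural-log-transformed readings (a
  purely multiplicative bias becomes a constant log-difference);
* :func:`regression_ba` - regression-based limits of agreement
  ``Diff = a + b * Avg +- 1.96 * resid_sd``, for when the difference
  varies with the underlying level.

:func:`iso_criterion_check` applies the sphygmomanometer accuracy
criterion (|mean difference| <= 5 mmHg and SD <= 8 mmHg).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

LOA_MULTIPLIER = 1.96


@dataclasses.dataclass(frozen=True)
class BAStats:
    """Classic Bland-Altman summary (difference = reference - test)."""

    variable: str
    scale: str  # "mmHg" or "log"
    n_pairs: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    slope: float
    slope_p: float
    pearson_r: float


@dataclasses.dataclass(frozen=True)
class RegressionLoA:
    """Regression-based limits of agreement: Diff = intercept + slope * Avg."""

    variable: str
    n_pairs: int
    intercept: float
    slope: float
    resid_sd: float
    multiplier: float = LOA_MULTIPLIER

    def center(self, avg):
        return self.intercept + self.slope * np.asarray(avg, dtype=float)

    def loa_low(self, avg):
        return self.center(avg) - self.multiplier * self.resid_sd

    def loa_high(self, avg):
        return self.center(avg) + self.multiplier * self.resid_sd


@dataclasses.dataclass(frozen=True)
class ISOCriterion:
    """Criterion-1 check: |mean| <= mean_limit and SD <= sd_limit."""

    mean_diff: float
    sd_diff: float
    mean_limit: float
    sd_limit: float
    mean_ok: bool
    sd_ok: bool
    overall_pass: bool


def _diff_avg(pairs: pd.DataFrame, variable: str):
    ref = pairs[f"{variable}_ref"].to_numpy(float)
    test = pairs[f"{variable}_test"].to_numpy(float)
    return ref - test, (ref + test) / 2.0


def _slope_test(avg: np.ndarray, diff: np.ndarray):
    """OLS slope of difference on average with its two-sided t-test p."""
    if np.ptp(avg) <= 0:
        return float("nan"), float("nan"), float("nan")
    if np.ptp(diff) <= 0:
        return 0.0, float("nan"), 0.0
    res = sps.linregress(avg, diff)
    return float(res.slope), float(res.pvalue), float(res.rvalue)


def classic_ba(
    pairs: pd.DataFrame, variable: str = "sbp", multiplier: float = LOA_MULTIPLIER
) -> BAStats:
    """Classic Bland-Altman on coupled readings (needs >= 3 pairs)."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs for Bland-Altman")
    diff, avg = _diff_avg(pairs, variable)
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    slope, slope_p, r = _slope_test(avg, diff)
    return BAStats(
        variable=variable,
        scale="mmHg",
        n_pairs=len(pairs),
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - multiplier * sd_diff,
        loa_high=mean_diff + multiplier * sd_diff,
        slope=slope,
        slope_p=slope_p,
        pearson_r=r,
    )


def log_ba(
    pairs: pd.DataFrame, variable: str = "sbp", multiplier: float = LOA_MULTIPLIER
) -> BAStats:
    """Classic Bland-Altman on natural-log readings.

    The reported slope shows whether the log transform removed the
    difference-vs-level association.  All readings must be positive.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs for Bland-Altman")
    ref = pairs[f"{variable}_ref"].to_numpy(float)
    test = pairs[f"{variable}_test"].to_numpy(float)
    if (ref <= 0).any() or (test <= 0).any():
        raise ValueError("log transform requires strictly positive readings")
    logged = pd.DataFrame(
        {f"{variable}_ref": np.log(ref), f"{variable}_test": np.log(test)}
    )
    out = classic_ba(logged, variable, multiplier)
    return dataclasses.replace(out, scale="log")


def regression_ba(
    pairs: pd.DataFrame, variable: str = "sbp", multiplier: float = LOA_MULTIPLIER
) -> RegressionLoA:
    """Regression-of-difference-on-average limits of agreement.

    Needs >= 4 pairs with non-constant averages.  The residual SD uses
    the n - 2 denominator; limits are V-shaped bands around the fitted
    line when the slope is nonzero.
    """
    if len(pairs) < 4:
        raise ValueError("need at least 4 pairs for regression-based LoA")
    diff, avg = _diff_avg(pairs, variable)
    if np.ptp(avg) <= 0:
        raise ValueError("averages are constant; regression LoA undefined")
    slope, intercept = np.polyfit(avg, diff, 1)
    resid = diff - (intercept + slope * avg)
    resid_sd = float(np.sqrt((resid**2).sum() / (len(diff) - 2)))
    return RegressionLoA(
        variable=variable,
        n_pairs=len(pairs),
        intercept=float(intercept),
        slope=float(slope),
        resid_sd=resid_sd,
        multiplier=multiplier,
    )


def iso_criterion_check(
    mean_diff: float,
    sd_diff: float,
    mean_limit: float = 5.0,
    sd_limit: float = 8.0,
) -> ISOCriterion:
    """Accuracy criterion for non-invasive sphygmomanometers.

    Passes iff |mean_diff| <= 5 mmHg and sd_diff <= 8 mmHg (both limits
    configurable).
    """
    if sd_diff < 0:
        raise ValueError("sd_diff must be >= 0")
    mean_ok = abs(mean_diff) <= mean_limit
    sd_ok = sd_diff <= sd_limit
    return ISOCriterion(
        mean_diff=float(mean_diff),
        sd_diff=float(sd_diff),
        mean_limit=mean_limit,
        sd_limit=sd_limit,
        mean_ok=bool(mean_ok),
        sd_ok=bool(sd_ok),
        overall_pass=bool(mean_ok and sd_ok),
    )


def per_patient_ba(pairs: pd.DataFrame, variable: str = "sbp") -> pd.DataFrame:
    """Per-patient mean difference and SD, to expose clustering effects."""
    diff, _ = _diff_avg(pairs, variable)
    df = pd.DataFrame({"patient_id": pairs["patient_id"], "diff": diff})
    out = df.groupby("patient_id")["diff"].agg(["size", "mean", "std"])
    out.columns = ["n_pairs", "mean_diff", "sd_diff"]
    return out.reset_index()


def ba_plot_data(pairs: pd.DataFrame, variable: str = "sbp") -> pd.DataFrame:
    """Tidy scatter/BA panel data: readings, averages, differences, lines."""
    diff, avg = _diff_avg(pairs, variable)
    stats = classic_ba(pairs, variable)
    reg = regression_ba(pairs, variable) if len(pairs) >= 4 and np.ptp(avg) > 0 else None
    return pd.DataFrame(
        {
            "patient_id": pairs["patient_id"],
            "ref": pairs[f"{variable}_ref"],
            "test": pairs[f"{variable}_test"],
            "avg": avg,
            "diff": diff,
            "mean_diff": stats.mean_diff,
            "loa_low": stats.loa_low,
            "loa_high": stats.loa_high,
            "reg_center": reg.center(avg) if reg else np.nan,
            "reg_low": reg.loa_low(avg) if reg else np.nan,
            "reg_high": reg.loa_high(avg) if reg else np.nan,
        }
    )


class BlandAltman(BaseEstimator):
    """Sklearn-style wrapper bundling the three agreement analyses.

    ``fit`` takes the pair table from
    :func:`bpagree.core_data.pair_measurements` and exposes
    ``classic_``, ``log_``, ``regression_`` and ``iso_`` results.
    """

    def __init__(self, variable: str = "sbp", multiplier: float = LOA_MULTIPLIER):
        self.variable = variable
        self.multiplier = multiplier

    def fit(self, X, y=None):
        pairs = X.pairs if hasattr(X, "pairs") else X
        self.classic_ = classic_ba(pairs, self.variable, self.multiplier)
        try:
            self.log_ = log_ba(pairs, self.variable, self.multiplier)
        except ValueError:
            self.log_ = None
        try:
            self.regression_ = regression_ba(pairs, self.variable, self.multiplier)
        except ValueError:
            self.regression_ = None
        self.iso_ = iso_criterion_check(self.classic_.mean_diff, self.classic_.sd_diff)
        self.mean_diff_ = self.classic_.mean_diff
        self.sd_diff_ = self.classic_.sd_diff
        self.loa_ = (self.classic_.loa_low, self.classic_.loa_high)
        return self

    def transform(self, X):
        """Return the tidy plot-data table for the fitted variable."""
        check_is_fitted(self, "classic_")
        pairs = X.pairs if hasattr(X, "pairs") else X
        return ba_plot_data(pairs, self.variable)
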