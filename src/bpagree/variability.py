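"""Blood-pressure variability indices and paired device comparisons.

Per patient, device and channel the module computes the daytime and
night-time SD, the duration-weighted SD (SD_w, 16 h day / 8 h night),
the average real variability (ARV: mean absolute successive difference,
computed within each period so no difference spans the day/night
boundary), and the daytime coefficient of variation (CV).  Night-time
indices are reported as missing when a series has <= 2 night readings,
and device comparisons use a paired t-test across patients with
pairwise-complete exclusion - suppressed (never fabricated) when fewer
than 3 complete pairs remain or the differences are degenerate.

A calibration-anchored test device (proportional bias < 1) shows up
here as systematically *lower* SD, ARV and CV than the reference.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_data import DAY, NIGHT, REFERENCE, TEST, CohortData, assign_periods

HOURS_DAY = 16.0
HOURS_NIGHT = 8.0
#: Night-time indices need more than this many readings.
MIN_NIGHT_READINGS = 3
_INDEX_COLUMNS = (
    "mean_day",
    "sd_day",
    "sd_night",
    "sd_w",
    "arv_day",
    "arv_night",
    "cv_day",
)


@dataclasses.dataclass(frozen=True)
class TTestResult:
    """Paired t-test outcome with an explicit suppression status.

    ``status`` is ``"ok"``, ``"degenerate"`` (all differences equal, no
    spread to test against) or ``"not_calculated"`` (< 3 complete pairs).
    """

    mean_difference: float
    t_statistic: float
    df: int
    p_value: float
    n: int
    status: str


def arv(series) -> float:
    """Average real variability: mean |successive difference|, time order.

    Shift-invariant; returns NaN for fewer than 2 values.
    """
    v = np.asarray(series, dtype=float)
    if len(v) < 2:
        return float("nan")
    return float(np.abs(np.diff(v)).mean())


def weighted_sd(
    sd_day: float,
    sd_night: float,
    hours_day: float = HOURS_DAY,
    hours_night: float = HOURS_NIGHT,
) -> float:
    """Duration-weighted SD: (sd_day*h_day + sd_night*h_night)/(h_day+h_night).

    NaN inputs propagate, mirroring sparse night-time data.
    """
    return (sd_day * hours_day + sd_night * hours_night) / (hours_day + hours_night)


def cv_day(series) -> float:
    """Coefficient of variation 100*SD/mean on daytime readings (%).

    NaN when the mean is not positive or there are fewer than 2 values.
    """
    v = np.asarray(series, dtype=float)
    if len(v) < 2:
        return float("nan")
    m = v.mean()
    if m <= 0:
        return float("nan")
    return float(100.0 * v.std(ddof=1) / m)


def paired_t_test(values_a, values_b) -> TTestResult:
    """Paired t on per-patient index pairs with pairwise-complete exclusion."""
    a = pd.Series(values_a, dtype=float)
    b = pd.Series(values_b, dtype=float)
    if isinstance(values_a, pd.Series) and isinstance(values_b, pd.Series):
        a, b = a.align(b, join="inner")
    d = (a - b).dropna().to_numpy()
    n = len(d)
    nan = float("nan")
    if n < 3:
        return TTestResult(nan, nan, max(n - 1, 0), nan, n, "not_calculated")
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if sd_d == 0:
        return TTestResult(mean_d, nan, n - 1, nan, n, "degenerate")
    t = mean_d / (sd_d / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return TTestResult(mean_d, float(t), n - 1, p, n, "ok")


def _series_indices(day: np.ndarray, night: np.ndarray) -> dict[str, float]:
    nan = float("nan")
    n_day, n_night = len(day), len(night)
    sd_day = float(np.std(day, ddof=1)) if n_day >= 2 else nan
    if n_night >= MIN_NIGHT_READINGS:
        sd_night = float(np.std(night, ddof=1))
        arv_night = arv(night)
    else:
        sd_night = nan
        arv_night = nan
    return {
        "n_day": n_day,
        "n_night": n_night,
        "mean_day": float(day.mean()) if n_day else nan,
        "sd_day": sd_day,
        "sd_night": sd_night,
        "sd_w": weighted_sd(sd_day, sd_night),
        "arv_day": arv(day),
        "arv_night": arv_night,
        "cv_day": cv_day(day),
    }


def patient_variability(cohort: CohortData) -> pd.DataFrame:
    """Tidy per-(patient, device, variable) variability index table."""
    rows = []
    df = cohort.frame.copy()
    df["period"] = assign_periods(df["time"])
    for (pid, device), sub in df.groupby(["patient_id", "device"], sort=True):
        sub = sub.sort_values("time", kind="stable")
        for variable in ("sbp", "dbp"):
            day = sub.loc[sub["period"] == DAY, variable].to_numpy(float)
            night = sub.loc[sub["period"] == NIGHT, variable].to_numpy(float)
            row = {"patient_id": pid, "device": device, "variable": variable}
            row.update(_series_indices(day, night))
            rows.append(row)
    return pd.DataFrame(rows)


def cohort_variability_table(cohort: CohortData) -> pd.DataFrame:
    """Across-patient summary per index and channel, with paired p-values.

    One row per (variable, index): mean and SD across patients for each
    device, the number of pairwise-complete patients and the paired
    t-test p (status shows when it was suppressed under the sparse-night
    rule).
    """
    per = patient_variability(cohort)
    rows = []
    for variable in ("sbp", "dbp"):
        sub = per[per["variable"] == variable]
        ref = sub[sub["device"] == REFERENCE].set_index("patient_id")
        test = sub[sub["device"] == TEST].set_index("patient_id")
        for index in _INDEX_COLUMNS:
            r = ref[index]
            t = test[index].reindex(r.index)
            tt = paired_t_test(r, t)
            rows.append(
                {
                    "variable": variable,
                    "index": index,
                    "mean_test": float(t.mean()),
                    "sd_test": float(t.std(ddof=1)),
                    "mean_ref": float(r.mean()),
                    "sd_ref": float(r.std(ddof=1)),
                    "n_pairs": tt.n,
                    "mean_difference": tt.mean_difference,
                    "p_value": tt.p_value,
                    "status": tt.status,
                }
            )
    return pd.DataFrame(rows)


@dataclasses.dataclass(frozen=True)
class PulsePressureStats:
    """Pulse pressure (sbp - dbp) summaries per device.

    ``per_patient`` has one row per (patient, device) with the mean PP;
    ``cohort_mean`` maps device to the mean of per-measurement PP;
    ``ttest`` compares per-patient means between devices.
    """

    per_patient: pd.DataFrame
    cohort_mean: dict[str, float]
    ttest: TTestResult


def pulse_pressure_stats(cohort: CohortData) -> PulsePressureStats:
    """Per-measurement PP, per-patient means and the paired device test."""
    df = cohort.frame.copy()
    df["pp"] = df["sbp"] - df["dbp"]
    per_patient = (
        df.groupby(["patient_id", "device"])["pp"].mean().rename("mean_pp").reset_index()
    )
    cohort_mean = {
        device: float(df.loc[df["device"] == device, "pp"].mean())
        for device in (REFERENCE, TEST)
        if (df["device"] == device).any()
    }
    wide = per_patient.pivot(index="patient_id", columns="device", values="mean_pp")
    if REFERENCE in wide.columns and TEST in wide.columns:
        ttest = paired_t_test(wide[REFERENCE], wide[TEST])
    else:
        nan = float("nan")
        ttest = TTestResult(nan, nan, 0, nan, 0, "not_calculated")
    return PulsePressureStats(
        per_patient=per_patient, cohort_mean=cohort_mean, ttest=ttest
    )
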