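"""Core data model for two-device ambulatory blood-pressure cohorts.

A cohort is a long-format table of timestamped readings taken on the same
patients by two devices: a cuff-based *reference* (a 24-h ambulatory
blood-pressure monitor, ABPM) and a *test* device (e.g. a cuffless
smartwatch).  Every analysis module in this package consumes the
:class:`CohortData` container defined here.

Conventions
-----------
* Timestamps are naive local clock times at minute resolution.
* The daytime window is ``[08:00, 24:00)`` and night-time is
  ``[00:00, 08:00)``; the two windows partition the 24-h clock.
* Valid readings satisfy ``40 <= dbp < sbp <= 300`` (mmHg).
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import Counter

import numpy as np
import pandas as pd

REFERENCE = "reference"
TEST = "test"
DEVICES = (REFERENCE, TEST)

DAY = "day"
NIGHT = "night"
#: First daytime clock hour; earlier clock times belong to the night window.
DAY_START_HOUR = 8

REQUIRED_COLUMNS = ("patient_id", "device", "timestamp", "sbp", "dbp")
TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M"

_SBP_MAX = 300.0
_DBP_MIN = 40.0


@dataclasses.dataclass(frozen=True)
class LoadReport:
    """Row accounting attached to a cohort loaded from disk."""

    rows_read: int
    rows_kept: int
    dropped: dict[str, int] = dataclasses.field(default_factory=dict)

    @property
    def rows_dropped(self) -> int:
        return sum(self.dropped.values())


def assign_period(time) -> str:
    """Return ``"day"`` or ``"night"`` from the clock time only.

    08:00 is the first daytime minute; 07:59 is still night.  The date is
    ignored.
    """
    return DAY if pd.Timestamp(time).hour >= DAY_START_HOUR else NIGHT


def assign_periods(times: pd.Series) -> np.ndarray:
    """Vectorised :func:`assign_period` over a datetime series."""
    hours = pd.DatetimeIndex(times).hour
    return np.where(hours >= DAY_START_HOUR, DAY, NIGHT)


class CohortData:
    """Timestamped per-patient, per-device BP readings.

    Parameters
    ----------
    frame:
        DataFrame with columns ``patient_id``, ``device`` (``reference`` or
        ``test``), ``time`` (datetime-like, floored to the minute), ``sbp``
        and ``dbp`` in mmHg.  Rows must already satisfy the measurement
        invariants; use :func:`read_measurements` for forgiving CSV intake.
    load_report:
        Optional :class:`LoadReport` describing how the frame was obtained.
    """

    def __init__(self, frame: pd.DataFrame, load_report: LoadReport | None = None):
        frame = frame.copy()
        missing = {"patient_id", "device", "time", "sbp", "dbp"} - set(frame.columns)
        if missing:
            raise ValueError(f"cohort frame is missing columns: {sorted(missing)}")
        frame["patient_id"] = frame["patient_id"].astype(str)
        frame["device"] = frame["device"].astype(str)
        bad_device = ~frame["device"].isin(DEVICES)
        if bad_device.any():
            raise ValueError(
                f"unknown device labels: {sorted(frame.loc[bad_device, 'device'].unique())}"
            )
        frame["time"] = pd.to_datetime(frame["time"]).dt.floor("min")
        frame["sbp"] = frame["sbp"].astype(float)
        frame["dbp"] = frame["dbp"].astype(float)
        ok = (
            (frame["dbp"] >= _DBP_MIN)
            & (frame["dbp"] < frame["sbp"])
            & (frame["sbp"] <= _SBP_MAX)
        )
        if not ok.all():
            raise ValueError(
                f"{int((~ok).sum())} rows violate 40 <= dbp < sbp <= 300"
            )
        frame = frame.sort_values(
            ["patient_id", "device", "time"], kind="stable", ignore_index=True
        )
        with_ref = set(frame.loc[frame["device"] == REFERENCE, "patient_id"])
        without_ref = set(frame["patient_id"]) - with_ref
        if without_ref:
            raise ValueError(
                f"patients without any reference measurement: {sorted(without_ref)}"
            )
        self._frame = frame
        self.load_report = load_report

    # -- accessors ---------------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        """The underlying long-format table (treat as read-only)."""
        return self._frame

    @property
    def patients(self) -> list[str]:
        return sorted(self._frame["patient_id"].unique())

    @property
    def patients_without_test(self) -> list[str]:
        """Patients retained despite having zero test-device readings."""
        with_test = set(self._frame.loc[self._frame["device"] == TEST, "patient_id"])
        return sorted(set(self._frame["patient_id"]) - with_test)

    def select(
        self,
        patient: str | None = None,
        device: str | None = None,
        period: str | None = None,
    ) -> pd.DataFrame:
        """Subset of readings, optionally by patient, device and period."""
        df = self._frame
        if patient is not None:
            df = df[df["patient_id"] == str(patient)]
        if device is not None:
            if device not in DEVICES:
                raise ValueError(f"device must be one of {DEVICES}, got {device!r}")
            df = df[df["device"] == device]
        if period is not None:
            if period not in (DAY, NIGHT):
                raise ValueError(f"period must be 'day' or 'night', got {period!r}")
            df = df[assign_periods(df["time"]) == period]
        return df

    def __len__(self) -> int:
        return len(self._frame)

    def equals(self, other: "CohortData") -> bool:
        return self._frame.equals(other._frame)


def read_measurements(path) -> CohortData:
    """Read a measurement CSV, dropping and counting invalid rows.

    The CSV must have a header with columns
    ``patient_id,device,timestamp,sbp,dbp``; timestamps are ISO-8601
    ``YYYY-MM-DDTHH:MM``.  Rows violating the measurement invariants are
    dropped and tallied in the attached :class:`LoadReport`; a missing
    column, an unparseable file or an empty result is fatal.
    """
    raw = pd.read_csv(
        path, dtype={"patient_id": str, "device": str}, float_precision="round_trip"
    )
    missing = set(REQUIRED_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    rows_read = len(raw)
    dropped: Counter[str] = Counter()

    df = pd.DataFrame(
        {
            "patient_id": raw["patient_id"].astype(str),
            "device": raw["device"].astype(str),
            "time": pd.to_datetime(raw["timestamp"], errors="coerce").dt.floor("min"),
            "sbp": pd.to_numeric(raw["sbp"], errors="coerce"),
            "dbp": pd.to_numeric(raw["dbp"], errors="coerce"),
        }
    )

    unparseable = df["time"].isna() | df["sbp"].isna() | df["dbp"].isna()
    dropped["unparseable"] = int(unparseable.sum())
    df = df[~unparseable]

    bad_device = ~df["device"].isin(DEVICES)
    dropped["bad_device"] = int(bad_device.sum())
    df = df[~bad_device]

    out_of_range = ~(
        (df["dbp"] >= _DBP_MIN) & (df["dbp"] < df["sbp"]) & (df["sbp"] <= _SBP_MAX)
    )
    dropped["out_of_range"] = int(out_of_range.sum())
    df = df[~out_of_range]

    dup = df.duplicated()
    dropped["duplicate_row"] = int(dup.sum())
    df = df[~dup]

    conflict = df.duplicated(subset=["patient_id", "device", "time"], keep="first")
    dropped["conflicting_reading"] = int(conflict.sum())
    if conflict.any():
        warnings.warn(
            f"{int(conflict.sum())} conflicting readings at a shared "
            "(patient, device, minute); keeping the first occurrence",
            stacklevel=2,
        )
    df = df[~conflict]

    with_ref = set(df.loc[df["device"] == REFERENCE, "patient_id"])
    orphan = ~df["patient_id"].isin(with_ref)
    dropped["no_reference_patient"] = int(orphan.sum())
    if orphan.any():
        warnings.warn(
            f"dropping {int(orphan.sum())} rows from patients with no reference "
            "measurements",
            stacklevel=2,
        )
    df = df[~orphan]

    if df.empty:
        raise ValueError("no valid measurements remain after filtering")

    dropped = {k: v for k, v in dropped.items() if v}
    report = LoadReport(rows_read=rows_read, rows_kept=len(df), dropped=dropped)
    return CohortData(df, load_report=report)


def write_measurements(cohort: CohortData, path) -> None:
    """Write a cohort back to the measurement CSV format."""
    df = cohort.frame
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "device": df["device"],
            "timestamp": df["time"].dt.strftime(TIMESTAMP_FORMAT),
            "sbp": df["sbp"],
            "dbp": df["dbp"],
        }
    )
    out.to_csv(path, index=False)


_PAIR_COLUMNS = (
    "patient_id",
    "ref_time",
    "test_time",
    "lag_s",
    "period",
    "sbp_ref",
    "dbp_ref",
    "sbp_test",
    "dbp_test",
)


@dataclasses.dataclass(frozen=True)
class PairResult:
    """Outcome of reference/test pairing.

    ``pairs`` holds one row per matched (reference, test) couple;
    ``unpaired_test`` holds test readings that found no admissible
    reference.  Unpaired readings are reported, never an error.
    """

    pairs: pd.DataFrame
    unpaired_test: pd.DataFrame
    n_test_total: int

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_unpaired_test(self) -> int:
        return len(self.unpaired_test)


def pair_measurements(cohort: CohortData, tolerance: float = 600.0) -> PairResult:
    """Couple each test reading with the latest preceding reference reading.

    Greedy in time order and one-to-one: a test reading pairs with the
    latest same-patient reference reading whose lag ``test.time - ref.time``
    is in ``[0, tolerance]`` seconds and that has not already been consumed.
    """
    if tolerance <= 0:
        raise ValueError("pairing tolerance must be positive")
    pair_rows: list[dict] = []
    unpaired_rows: list[pd.Series] = []
    n_test_total = 0
    for pid in cohort.patients:
        refs = cohort.select(patient=pid, device=REFERENCE).reset_index(drop=True)
        tests = cohort.select(patient=pid, device=TEST).reset_index(drop=True)
        n_test_total += len(tests)
        ref_times = refs["time"].to_numpy()
        used = np.zeros(len(refs), dtype=bool)
        for k in range(len(tests)):
            t = tests["time"].to_numpy()[k]
            j = int(np.searchsorted(ref_times, t, side="right")) - 1
            while j >= 0 and used[j]:
                j -= 1
            lag = (t - ref_times[j]) / np.timedelta64(1, "s") if j >= 0 else np.inf
            if j >= 0 and lag <= tolerance:
                used[j] = True
                pair_rows.append(
                    {
                        "patient_id": pid,
                        "ref_time": refs["time"].iloc[j],
                        "test_time": tests["time"].iloc[k],
                        "lag_s": float(lag),
                        "period": assign_period(refs["time"].iloc[j]),
                        "sbp_ref": refs["sbp"].iloc[j],
                        "dbp_ref": refs["dbp"].iloc[j],
                        "sbp_test": tests["sbp"].iloc[k],
                        "dbp_test": tests["dbp"].iloc[k],
                    }
                )
            else:
                unpaired_rows.append(tests.iloc[k])
    pairs = pd.DataFrame(pair_rows, columns=list(_PAIR_COLUMNS))
    unpaired = (
        pd.DataFrame(unpaired_rows).reset_index(drop=True)
        if unpaired_rows
        else cohort.frame.iloc[0:0].copy()
    )
    return PairResult(pairs=pairs, unpaired_test=unpaired, n_test_total=n_test_total)


def patient_period_mean(
    cohort: CohortData, patient: str, device: str, period: str, variable: str
) -> float:
    """Arithmetic mean of one patient's readings in a day/night window.

    Returns NaN for an empty selection so downstream metrics can exclude
    the patient explicitly rather than fail.
    """
    if variable not in ("sbp", "dbp"):
        raise ValueError(f"variable must be 'sbp' or 'dbp', got {variable!r}")
    values = cohort.select(patient=patient, device=device, period=period)[variable]
    return float(values.mean()) if len(values) else float("nan")


def period_means(
    cohort: CohortData, device: str, variable: str, period: str = DAY
) -> pd.Series:
    """Per-patient period means for one device; NaN where a patient has none."""
    df = cohort.select(device=device, period=period)
    means = df.groupby("patient_id")[variable].mean()
    return means.reindex(cohort.patients)
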