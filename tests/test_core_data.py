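"""Data model, CSV I/O, day/night windowing and measurement pairing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bpagree import (
    CohortData,
    SimConfig,
    assign_period,
    pair_measurements,
    patient_period_mean,
    read_measurements,
    simulate_cohort,
    write_measurements,
)
from conftest import make_cohort

CSV_HEADER = "patient_id,device,timestamp,sbp,dbp\n"


def _write(tmp_path, body, name="data.csv"):
    path = tmp_path / name
    path.write_text(CSV_HEADER + body)
    return path


class TestReadMeasurements:
    def test_well_formed_rows_all_kept(self, tmp_path):
        path = _write(
            tmp_path,
            "A,reference,2022-03-01T10:00,120,80\n"
            "A,reference,2022-03-01T10:15,125,82\n"
            "A,test,2022-03-01T10:02,118,79\n",
        )
        cohort = read_measurements(path)
        assert len(cohort) == 3
        assert cohort.load_report.rows_read == 3
        assert cohort.load_report.rows_dropped == 0

    def test_out_of_range_row_dropped_and_counted(self, tmp_path):
        path = _write(
            tmp_path,
            "A,reference,2022-03-01T10:00,120,80\n"
            "A,reference,2022-03-01T10:15,30,20\n",  # sbp=30 violates invariant
        )
        cohort = read_measurements(path)
        assert len(cohort) == 1
        assert cohort.load_report.dropped["out_of_range"] == 1

    def test_missing_column_is_fatal(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("patient_id,device,timestamp,sbp\nA,reference,2022-03-01T10:00,120\n")
        with pytest.raises(ValueError, match="missing required columns"):
            read_measurements(path)

    def test_empty_after_filtering_is_fatal(self, tmp_path):
        path = _write(tmp_path, "A,reference,2022-03-01T10:00,30,20\n")
        with pytest.raises(ValueError, match="no valid measurements"):
            read_measurements(path)

    def test_conflicting_reading_keeps_first_with_warning(self, tmp_path):
        path = _write(
            tmp_path,
            "A,reference,2022-03-01T10:00,120,80\n"
            "A,reference,2022-03-01T10:00,140,90\n"
            "A,reference,2022-03-01T10:15,125,82\n",
        )
        with pytest.warns(UserWarning, match="conflicting"):
            cohort = read_measurements(path)
        kept = cohort.select(patient="A")
        assert kept.loc[kept["time"] == pd.Timestamp("2022-03-01T10:00"), "sbp"].item() == 120
        assert cohort.load_report.dropped["conflicting_reading"] == 1

    def test_patient_without_reference_dropped(self, tmp_path):
        path = _write(
            tmp_path,
            "A,reference,2022-03-01T10:00,120,80\n"
            "B,test,2022-03-01T10:00,118,78\n",
        )
        with pytest.warns(UserWarning, match="no reference"):
            cohort = read_measurements(path)
        assert cohort.patients == ["A"]

    def test_round_trip_through_write_is_identical(self, tmp_path):
        cohort, _ = simulate_cohort(SimConfig(seed=5, n_patients=6))
        p1 = tmp_path / "a.csv"
        p2 = tmp_path / "b.csv"
        write_measurements(cohort, p1)
        back = read_measurements(p1)
        assert cohort.equals(back)
        write_measurements(back, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestAssignPeriod:
    @pytest.mark.parametrize(
        "clock,expected",
        [("08:00", "day"), ("07:59", "night"), ("23:59", "day"), ("00:00", "night")],
    )
    def test_window_boundaries(self, clock, expected):
        assert assign_period(pd.Timestamp(f"2022-03-01 {clock}")) == expected

    @given(minute_of_day=st.integers(min_value=0, max_value=24 * 60 - 1))
    def test_partition_of_the_clock(self, minute_of_day):
        t = pd.Timestamp("2022-03-01") + pd.Timedelta(minutes=minute_of_day)
        period = assign_period(t)
        assert period in ("day", "night")
        assert (period == "day") == (minute_of_day >= 8 * 60)


class TestPairing:
    def test_single_candidate_pairs_with_lag(self):
        cohort = make_cohort(
            [("A", "reference", "10:00", 120, 80), ("A", "test", "10:03", 118, 78)]
        )
        res = pair_measurements(cohort, tolerance=600)
        assert res.n_pairs == 1
        assert res.pairs["lag_s"].item() == 180.0

    def test_latest_preceding_reference_wins(self):
        cohort = make_cohort(
            [
                ("A", "reference", "10:00", 120, 80),
                ("A", "reference", "10:15", 130, 85),
                ("A", "test", "10:16", 118, 78),
            ]
        )
        res = pair_measurements(cohort, tolerance=600)
        assert res.n_pairs == 1
        assert res.pairs["ref_time"].item() == pd.Timestamp("2022-03-01T10:15")

    def test_one_to_one_greedy_consumption(self):
        # two tests chase one reference: the earlier test wins, the later is unpaired
        cohort = make_cohort(
            [
                ("A", "reference", "10:00", 120, 80),
                ("A", "test", "10:03", 118, 78),
                ("A", "test", "10:05", 119, 79),
            ]
        )
        res = pair_measurements(cohort, tolerance=600)
        assert res.n_pairs == 1
        assert res.pairs["test_time"].item() == pd.Timestamp("2022-03-01T10:03")
        assert res.n_unpaired_test == 1

    def test_out_of_window_reference_not_used(self):
        cohort = make_cohort(
            [("A", "reference", "10:00", 120, 80), ("A", "test", "10:30", 118, 78)]
        )
        assert pair_measurements(cohort, tolerance=600).n_pairs == 0

    def test_conservation_and_idempotence(self, default_cohort):
        cohort, _ = default_cohort
        res1 = pair_measurements(cohort)
        res2 = pair_measurements(cohort)
        assert res1.n_pairs + res1.n_unpaired_test == res1.n_test_total
        assert res1.n_test_total == len(cohort.select(device="test"))
        pd.testing.assert_frame_equal(res1.pairs, res2.pairs)

    def test_references_used_at_most_once(self, default_cohort):
        cohort, _ = default_cohort
        pairs = pair_measurements(cohort).pairs
        assert not pairs.duplicated(subset=["patient_id", "ref_time"]).any()

    def test_invalid_tolerance(self, default_cohort):
        cohort, _ = default_cohort
        with pytest.raises(ValueError):
            pair_measurements(cohort, tolerance=0)


class TestPatientPeriodMean:
    def test_two_point_mean_and_identity(self):
        cohort = make_cohort(
            [
                ("A", "reference", "09:00", 120, 80),
                ("A", "reference", "10:00", 130, 84),
                ("A", "reference", "02:00", 140, 90),
            ]
        )
        assert patient_period_mean(cohort, "A", "reference", "day", "sbp") == 125.0
        assert patient_period_mean(cohort, "A", "reference", "night", "sbp") == 140.0

    def test_empty_selection_is_nan(self):
        cohort = make_cohort([("A", "reference", "09:00", 120, 80)])
        assert np.isnan(patient_period_mean(cohort, "A", "test", "day", "sbp"))

    def test_sample_mean_tracks_latent_mean(self, default_cohort):
        # CLT bound: daytime reference mean within 3 sigma/sqrt(n) of the
        # latent daytime level for every patient
        cohort, truth = default_cohort
        levels = truth.patients.set_index("patient_id")["mean_sbp"]
        for pid in cohort.patients:
            day = cohort.select(patient=pid, device="reference", period="day")["sbp"]
            bound = 3 * np.hypot(19.1, 4.0) / np.sqrt(len(day))
            assert abs(day.mean() - levels[pid]) < bound


class TestCohortData:
    def test_rejects_invariant_violations(self):
        df = pd.DataFrame(
            {
                "patient_id": ["A"],
                "device": ["reference"],
                "time": [pd.Timestamp("2022-03-01 10:00")],
                "sbp": [80.0],
                "dbp": [90.0],  # dbp >= sbp
            }
        )
        with pytest.raises(ValueError, match="violate"):
            CohortData(df)

    def test_flags_patients_without_test_readings(self):
        cohort = make_cohort(
            [
                ("A", "reference", "10:00", 120, 80),
                ("A", "test", "10:05", 118, 78),
                ("B", "reference", "10:00", 125, 82),
            ]
        )
        assert cohort.patients_without_test == ["B"]
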