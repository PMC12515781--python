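"""Ingestion, grid regularisation, wear accounting and windowing."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cgmdev.cgm_data import (
    CgmDataError,
    CgmTrace,
    IneligibleSubjectError,
    MissingColumnError,
    Period,
    parse_cgm_table,
    read_cgm_csv,
    read_covariates_csv,
    select_window,
    split_periods,
    wear_fraction,
    write_cgm_csv,
)
from conftest import make_trace

D0 = dt.date(2024, 3, 4)


def _df(rows):
    return pd.DataFrame(rows, columns=["subject_id", "timestamp", "glucose_mgdl"])


class TestParsing:
    def test_three_clean_rows_give_one_trace(self):
        df = _df(
            [
                ("A", "2024-03-04 00:00", 100),
                ("A", "2024-03-04 00:05", 105),
                ("A", "2024-03-04 00:10", 110),
            ]
        )
        traces, report = parse_cgm_table(df)
        assert list(traces) == ["A"]
        assert len(traces["A"]) == 3
        assert report.rows_read == 3 and report.duplicates == 0 and report.clipped == 0
        np.testing.assert_array_equal(traces["A"].glucose, [100, 105, 110])

    def test_out_of_span_values_clipped_and_counted(self):
        df = _df([("A", "2024-03-04 00:00", 420), ("A", "2024-03-04 00:05", 35)])
        traces, report = parse_cgm_table(df)
        np.testing.assert_array_equal(traces["A"].glucose, [400, 40])
        assert report.clipped == 2

    def test_duplicate_timestamp_first_wins(self):
        df = _df(
            [
                ("A", "2024-03-04 00:00", 100),
                ("A", "2024-03-04 00:05", 105),
                ("A", "2024-03-04 00:05", 999),
            ]
        )
        traces, report = parse_cgm_table(df)
        assert len(traces["A"]) == 2
        assert report.duplicates == 1
        assert traces["A"].glucose[1] == 105

    def test_timestamps_snapped_to_grid(self):
        df = _df([("A", "2024-03-04 00:01:40", 100), ("A", "2024-03-04 00:06:10", 110)])
        traces, _ = parse_cgm_table(df)
        assert list(traces["A"].times) == [
            pd.Timestamp("2024-03-04 00:00"),
            pd.Timestamp("2024-03-04 00:05"),
        ]

    def test_missing_column_fails_with_name(self):
        with pytest.raises(MissingColumnError, match="glucose_mgdl"):
            parse_cgm_table(pd.DataFrame({"subject_id": [], "timestamp": []}))

    def test_minority_of_bad_rows_dropped_majority_fails(self):
        ok = [("A", f"2024-03-04 00:{5*i:02d}", 100) for i in range(6)]
        bad = [("A", "not-a-time", 100)] * 4
        traces, report = parse_cgm_table(_df(ok + bad))
        assert report.rows_bad_timestamp == 4 and len(traces["A"]) == 6
        with pytest.raises(CgmDataError, match=">50%"):
            parse_cgm_table(_df(ok[:2] + bad))

    def test_round_trip_of_synthetic_traces(self, matched_cohorts, tmp_path):
        originals = [matched_cohorts["RYGB"].records[i].trace for i in range(3)]
        path = tmp_path / "cgm.csv"
        write_cgm_csv(originals, path)
        traces, _ = read_cgm_csv(path)
        for orig in originals:
            got = traces[orig.subject_id]
            assert (got.times == orig.times).all()
            np.testing.assert_array_equal(got.glucose, orig.glucose)

    def test_covariate_join_builds_records(self, tmp_path):
        cgm = tmp_path / "cgm.csv"
        cov = tmp_path / "cov.csv"
        _df([("A", "2024-03-04 00:00", 100)]).to_csv(cgm, index=False)
        pd.DataFrame(
            {
                "subject_id": ["A"],
                "age_years": [50],
                "sex": ["F"],
                "bmi": [26.0],
                "cohort": ["RYGB"],
            }
        ).to_csv(cov, index=False)
        records, _ = read_cgm_csv(cgm, cov)
        (rec,) = records
        assert rec.sex == 1 and rec.cohort == "RYGB" and rec.age == 50


class TestTraceInvariants:
    def test_non_monotone_times_rejected(self):
        times = pd.DatetimeIndex(["2024-03-04 00:05", "2024-03-04 00:00"])
        with pytest.raises(CgmDataError, match="increasing"):
            CgmTrace("A", times, [100, 100])

    def test_off_grid_times_rejected(self):
        times = pd.DatetimeIndex(["2024-03-04 00:00", "2024-03-04 00:07"])
        with pytest.raises(CgmDataError, match="grid"):
            CgmTrace("A", times, [100, 100])


class TestWearFraction:
    def test_complete_ten_days_is_one(self):
        trace = make_trace(np.full(2880, 100.0))
        assert wear_fraction(trace, D0, 10) == 1.0

    def test_seventy_percent_is_inclusive_at_threshold(self):
        # 2016 of 2880 expected readings = exactly 0.70, spread over 10 days
        times = pd.date_range("2024-03-04", periods=2880, freq="5min")
        keep = (np.arange(2880) % 10) < 7
        trace = make_trace(np.full(int(keep.sum()), 100.0), times=times[keep])
        assert wear_fraction(trace, D0, 10) == pytest.approx(0.70)
        window = select_window(trace, 10, 0.7)
        assert window.wear_fraction == pytest.approx(0.70)

    def test_disjoint_window_returns_zero(self):
        trace = make_trace(np.full(288, 100.0))
        assert wear_fraction(trace, dt.date(2030, 1, 1), 10) == 0.0

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(min_value=1, max_value=2879))
    def test_adding_readings_never_decreases_wear(self, n):
        full = np.full(2880, 100.0)
        partial = make_trace(full[:n])
        extended = make_trace(full[: n + 1])
        assert wear_fraction(extended, D0, 10) >= wear_fraction(partial, D0, 10)


class TestSelectWindow:
    def test_complete_twelve_days_selects_earliest(self):
        trace = make_trace(np.full(12 * 288, 100.0))
        w = select_window(trace, 10, 0.7)
        assert w.start_date == D0 and w.wear_fraction == 1.0

    def test_one_missing_day_still_qualifies(self):
        glucose = np.full(12 * 288, 100.0)
        times = pd.date_range("2024-03-04", periods=12 * 288, freq="5min")
        keep = ~((times >= pd.Timestamp("2024-03-05")) & (times < pd.Timestamp("2024-03-06")))
        trace = make_trace(glucose[keep], times=times[keep])
        w = select_window(trace, 10, 0.7)
        assert w.start_date == D0
        assert w.wear_fraction == pytest.approx(0.9)

    def test_short_trace_is_ineligible(self):
        trace = make_trace(np.full(5 * 288, 100.0))
        with pytest.raises(IneligibleSubjectError):
            select_window(trace, 10, 0.7)

    def test_error_carries_best_achievable_wear(self):
        # 10 days span but only 30% of slots present
        times = pd.date_range("2024-03-04", periods=2880, freq="5min")[::4]
        trace = make_trace(np.full(len(times), 100.0), times=times)
        with pytest.raises(IneligibleSubjectError) as exc:
            select_window(trace, 10, 0.7)
        assert 0 < exc.value.best_wear < 0.7


class TestSplitPeriods:
    def test_clock_boundaries(self):
        times = pd.DatetimeIndex(
            ["2024-03-04 06:00", "2024-03-04 23:55", "2024-03-05 00:00"]
        )
        trace = make_trace([100, 100, 100], times=times)
        w = select_window(make_trace(np.full(2880, 100.0)), 10, 0.7)
        parts = split_periods(trace, w)
        assert len(parts[Period.DAY]) == 2  # 06:00 and 23:55
        assert len(parts[Period.NIGHT]) == 1  # 00:00

    def test_complete_day_has_216_day_and_72_night_slots(self):
        trace = make_trace(np.full(288, 100.0))
        w = select_window(make_trace(np.full(2880, 100.0)), 10, 0.7)
        parts = split_periods(trace, w)
        assert len(parts[Period.DAY]) == 216
        assert len(parts[Period.NIGHT]) == 72

    def test_day_night_partition_is_exact(self, matched_cohorts):
        rec = matched_cohorts["T1D"].records[0]
        w = select_window(rec.trace)
        parts = split_periods(rec.trace, w)
        assert len(parts[Period.DAY]) + len(parts[Period.NIGHT]) == len(
            parts[Period.OVERALL]
        )
        merged = parts[Period.DAY].times.union(parts[Period.NIGHT].times)
        assert (merged == parts[Period.OVERALL].times).all()
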