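"""Band times, variability, GMI and consecutive-reading event detection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cgmdev.cgm_data import Period, select_window
from cgmdev.metrics import (
    EventKind,
    InsufficientDataError,
    MetricConfig,
    NoDataError,
    band_times,
    cv,
    detect_events,
    event_summary,
    gmi,
    metric_panel,
)
from conftest import make_trace


# --- independent oracle: run-scan with short-recovery merging --------------


def oracle_events(beyond, min_event=3, min_recovery=3):
    """Enumerate maximal beyond-threshold runs; an event starts at the first
    run of length >= min_event and absorbs later runs separated by fewer
    than min_recovery recovered readings. Returns (start, last) index pairs."""
    runs = []
    i = 0
    n = len(beyond)
    while i < n:
        if beyond[i]:
            j = i
            while j + 1 < n and beyond[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    events = []
    k = 0
    while k < len(runs):
        s, e = runs[k]
        if e - s + 1 < min_event:
            k += 1
            continue
        while k + 1 < len(runs) and runs[k + 1][0] - e - 1 < min_recovery:
            e = runs[k + 1][1]
            k += 1
        events.append((s, e))
        k += 1
    return events


def detect_simple(values, config=None):
    trace = make_trace(values)
    return detect_events(trace.times, trace.glucose, EventKind.HYPO_L1, config)


class TestBandTimes:
    def test_constant_in_band(self):
        b = band_times(np.full(10, 100.0))
        assert (b.tir, b.titr, b.tar, b.tbr) == (100.0, 100.0, 0.0, 0.0)

    def test_half_above_range(self):
        b = band_times(np.array([200.0] * 5 + [100.0] * 5))
        assert b.tar == 50.0 and b.tir == 50.0

    @pytest.mark.parametrize(
        "value, checks",
        [
            (54.0, {"time_l1": 100.0, "time_l2": 0.0, "tbr": 100.0}),
            (70.0, {"tir": 100.0, "tbr": 0.0, "time_l1": 0.0}),
            (180.0, {"tir": 100.0, "tar": 0.0}),
            (140.0, {"titr": 100.0}),
            (53.9, {"time_l2": 100.0, "time_l1": 0.0}),
            (180.1, {"tar": 100.0, "tir": 0.0}),
        ],
    )
    def test_threshold_boundaries(self, value, checks):
        b = band_times(np.full(4, value))._asdict()
        for key, expected in checks.items():
            assert b[key] == expected, key

    def test_empty_period_is_an_error_not_zero(self):
        with pytest.raises(NoDataError):
            band_times(np.array([]))

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=40, max_value=400), min_size=1, max_size=200)
    )
    def test_conservation_identities(self, values):
        b = band_times(np.asarray(values))
        assert b.tir + b.tar + b.tbr == pytest.approx(100.0, abs=1e-9)
        assert b.tbr == pytest.approx(b.time_l1 + b.time_l2, abs=1e-9)
        assert b.titr <= b.tir + 1e-12


class TestCv:
    def test_constant_series_is_zero(self):
        assert cv(np.full(5, 123.0)) == 0.0

    def test_two_point_closed_form(self):
        assert cv(np.array([80.0, 120.0])) == pytest.approx(28.2842712, abs=1e-6)

    def test_scale_invariance(self):
        x = np.array([90.0, 110.0, 95.0, 140.0])
        assert cv(3.7 * x) == pytest.approx(cv(x))

    def test_single_reading_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            cv(np.array([100.0]))


class TestGmi:
    def test_published_linear_formula(self):
        assert gmi(139.1) == pytest.approx(6.64, abs=0.005)
        assert gmi(100.0) == pytest.approx(5.70, abs=0.005)

    def test_strictly_increasing(self):
        means = np.linspace(50, 300, 40)
        values = [gmi(m) for m in means]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(Exception):
            gmi(0.0)


class TestDetectEvents:
    def test_three_consecutive_below_start_an_event(self):
        (event,) = detect_simple([65, 65, 60])
        assert event.duration_min == 15 and event.extremum == 60

    def test_interrupted_run_is_no_event(self):
        assert detect_simple([65, 75, 65, 65]) == []

    def test_single_recovery_point_does_not_terminate(self):
        (event,) = detect_simple([60, 60, 60, 72, 60, 60, 60])
        assert event.n_readings == 7 and event.duration_min == 35

    def test_three_recovered_readings_terminate(self):
        events = detect_simple([60, 60, 60, 75, 75, 75, 60, 60, 60])
        assert [e.duration_min for e in events] == [15, 15]

    def test_trailing_recovery_not_counted_in_duration(self):
        (event,) = detect_simple([60, 60, 60, 60, 75, 75])
        assert event.duration_min == 20

    def test_gap_terminates_event(self):
        times = pd.DatetimeIndex(
            [
                "2024-03-04 00:00",
                "2024-03-04 00:05",
                "2024-03-04 00:10",
                # 10-min gap
                "2024-03-04 00:25",
                "2024-03-04 00:30",
                "2024-03-04 00:35",
            ]
        )
        trace = make_trace([60] * 6, times=times)
        events = detect_events(trace.times, trace.glucose, EventKind.HYPO_L1)
        assert [e.duration_min for e in events] == [15, 15]

    def test_gap_in_band_never_creates_event(self):
        times = pd.date_range("2024-03-04", periods=40, freq="5min")
        keep = np.ones(40, bool)
        keep[10:20] = False
        trace = make_trace(np.full(30, 100.0), times=times[keep])
        assert detect_events(trace.times, trace.glucose, EventKind.HYPO_L1) == []

    def test_hyper_uses_strictly_above_threshold(self):
        trace = make_trace([181, 181, 181])
        events = detect_events(trace.times, trace.glucose, EventKind.HYPER)
        assert len(events) == 1 and events[0].extremum == 181
        trace = make_trace([180, 180, 180])
        assert detect_events(trace.times, trace.glucose, EventKind.HYPER) == []

    def test_matches_bruteforce_oracle_on_random_series(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            n = rng.integers(3, 40)
            values = rng.choice([50.0, 60.0, 68.0, 75.0, 100.0], size=n)
            got = detect_simple(values)
            expected = oracle_events(values < 70.0)
            assert [(e.n_readings) for e in got] == [b - a + 1 for a, b in expected]

    def test_l2_event_spans_nested_in_l1(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            values = rng.choice([45.0, 50.0, 60.0, 66.0, 80.0, 120.0], size=50)
            trace = make_trace(values)
            l1 = detect_events(trace.times, trace.glucose, EventKind.HYPO_L1)
            l2 = detect_events(trace.times, trace.glucose, EventKind.HYPO_L2)
            for e2 in l2:
                assert any(e1.start <= e2.start and e2.end <= e1.end for e1 in l1)


class TestEventSummary:
    def test_empty_list_has_missing_duration(self):
        count, dur = event_summary([])
        assert count == 0 and math.isnan(dur)

    def test_mean_duration(self):
        events = detect_simple([60] * 3 + [100] * 3 + [60] * 5)
        count, dur = event_summary(events)
        assert count == 2 and dur == 20.0


class TestMetricPanel:
    def _window(self, trace):
        return select_window(trace, 10, 0.7)

    def test_constant_trace_panel(self):
        trace = make_trace(np.full(2880, 100.0))
        panel = metric_panel(trace, self._window(trace))
        pm = panel[Period.OVERALL]
        assert pm.mean_glucose == 100.0 and pm.cv == 0.0 and pm.tir == 100.0
        assert pm.n_l1_events == pm.n_l2_events == pm.n_hyper_events == 0
        assert math.isnan(pm.mean_l1_duration)
        assert pm.gmi == pytest.approx(gmi(100.0))

    def test_nocturnal_dip_counts_in_night_for_both_levels(self):
        glucose = np.full(2880, 100.0)
        glucose[24:28] = 50.0  # 02:00-02:15, below 54 hence also below 70
        trace = make_trace(glucose)
        panel = metric_panel(trace, self._window(trace))
        assert panel[Period.NIGHT].n_l2_events == 1
        assert panel[Period.NIGHT].n_l1_events == 1
        assert panel[Period.DAY].n_l1_events == 0
        assert panel[Period.OVERALL].n_l1_events == 1

    def test_overall_tbr_is_weighted_mean_of_periods(self, matched_cohorts):
        rec = matched_cohorts["RYGB"].records[3]
        panel = metric_panel(rec.trace, select_window(rec.trace))
        day, night, overall = (
            panel[Period.DAY],
            panel[Period.NIGHT],
            panel[Period.OVERALL],
        )
        weighted = (
            day.tbr * day.n_readings + night.tbr * night.n_readings
        ) / (day.n_readings + night.n_readings)
        assert overall.tbr == pytest.approx(weighted, abs=1e-9)
        assert min(day.tbr, night.tbr) <= overall.tbr <= max(day.tbr, night.tbr)

    def test_event_assigned_to_period_of_start_reading(self):
        glucose = np.full(2880, 100.0)
        glucose[70:76] = 60.0  # starts 05:50 (night), runs into 06:15 (day)
        trace = make_trace(glucose)
        panel = metric_panel(trace, self._window(trace))
        assert panel[Period.NIGHT].n_l1_events == 1
        assert panel[Period.DAY].n_l1_events == 0
        assert panel[Period.NIGHT].mean_l1_duration == 30.0
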