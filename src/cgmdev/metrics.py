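"""Consensus CGM metric panel: band times, variability, events, GMI.

Implements the international-consensus glycaemic metrics on a 5-min
sensor grid: time in range 70-180 mg/dL (TIR), time in tight range
70-140 (TITR), time above 180 (TAR), time below 70 (TBR) split into the
level-1 (54-70) and level-2 (<54) hypoglycaemic ranges, coefficient of
variation, the glucose management indicator, and excursion events
defined by at least three consecutive readings beyond a threshold.

Band boundary convention: TIR and TITR are closed bands (70 <= g <= 180
and 70 <= g <= 140), TBR is strict (g < 70), the L1 range is
54 <= g < 70, L2 strict (g < 54) and TAR strict (g > 180).  This keeps
TIR + TAR + TBR = 100 and TBR = L1 + L2 exact identities.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .cgm_data import AnalysisWindow, CgmTrace, Period, split_periods

# GMI: published linear regression of laboratory HbA1c on mean CGM
# glucose, percent HbA1c-equivalent.
GMI_INTERCEPT = 3.31
GMI_SLOPE = 0.02392


class MetricsError(Exception):
    pass


class NoDataError(MetricsError):
    """A period contains no readings; metrics are undefined, not zero."""


class InsufficientDataError(MetricsError):
    pass


@dataclass(frozen=True)
class MetricConfig:
    """Thresholds (mg/dL) and run-length rules for the metric panel."""

    tir_lo: float = 70.0
    tir_hi: float = 180.0
    titr_hi: float = 140.0
    l1_threshold: float = 70.0
    l2_threshold: float = 54.0
    hyper_threshold: float = 180.0
    min_event_points: int = 3
    min_recovery_points: int = 3

    def __post_init__(self) -> None:
        if not self.l2_threshold < self.l1_threshold < self.hyper_threshold:
            raise ValueError("thresholds must satisfy l2 < l1 < hyper")
        if self.min_event_points < 1:
            raise ValueError("min_event_points must be >= 1")


class EventKind(str, enum.Enum):
    HYPO_L1 = "hypo_l1"
    HYPO_L2 = "hypo_l2"
    HYPER = "hyper"


@dataclass(frozen=True)
class GlycemicEvent:
    """A maximal contiguous excursion beyond a threshold.

    ``duration_min`` counts in-event readings times the grid interval,
    so gaps never inflate an event's length; ``extremum`` is the nadir
    for hypoglycaemic events and the peak for hyperglycaemic ones.
    """

    kind: EventKind
    start: pd.Timestamp
    end: pd.Timestamp
    n_readings: int
    duration_min: float
    extremum: float


class BandTimes(NamedTuple):
    tir: float
    titr: float
    tar: float
    tbr: float
    time_l1: float
    time_l2: float


@dataclass
class PeriodMetrics:
    """The full metric panel for one subject and one time period."""

    period: Period
    n_readings: int
    mean_glucose: float
    cv: float
    tir: float
    titr: float
    tar: float
    tbr: float
    time_l1: float
    time_l2: float
    n_l1_events: int
    mean_l1_duration: float
    n_l2_events: int
    mean_l2_duration: float
    n_hyper_events: int
    mean_hyper_duration: float
    gmi: float


#: Table-style report rows, in panel order.
PANEL_METRICS = [
    "mean_glucose",
    "tir",
    "titr",
    "tar",
    "tbr",
    "cv",
    "n_l1_events",
    "mean_l1_duration",
    "n_l2_events",
    "mean_l2_duration",
    "n_hyper_events",
    "mean_hyper_duration",
    "time_l1",
    "time_l2",
]


def band_times(glucose: np.ndarray, config: MetricConfig | None = None) -> BandTimes:
    """Percent of non-missing readings in each consensus glucose band."""
    config = config or MetricConfig()
    g = np.asarray(glucose, dtype=float)
    if g.size == 0:
        raise NoDataError("no readings in period")
    n = g.size
    pct = lambda mask: 100.0 * np.count_nonzero(mask) / n
    return BandTimes(
        tir=pct((g >= config.tir_lo) & (g <= config.tir_hi)),
        titr=pct((g >= config.tir_lo) & (g <= config.titr_hi)),
        tar=pct(g > config.tir_hi),
        tbr=pct(g < config.l1_threshold),
        time_l1=pct((g >= config.l2_threshold) & (g < config.l1_threshold)),
        time_l2=pct(g < config.l2_threshold),
    )


def cv(glucose: np.ndarray) -> float:
    """Coefficient of variation: sample SD / mean, in percent."""
    g = np.asarray(glucose, dtype=float)
    if g.size < 2:
        raise InsufficientDataError("cv requires at least 2 readings")
    return float(np.std(g, ddof=1) / np.mean(g) * 100.0)


def gmi(mean_glucose: float) -> float:
    """Glucose management indicator (% HbA1c-equivalent) from mean glucose."""
    if not mean_glucose > 0:
        raise MetricsError("mean glucose must be positive")
    return GMI_INTERCEPT + GMI_SLOPE * mean_glucose


def _beyond(glucose: np.ndarray, kind: EventKind, config: MetricConfig) -> np.ndarray:
    if kind is EventKind.HYPO_L1:
        return glucose < config.l1_threshold
    if kind is EventKind.HYPO_L2:
        return glucose < config.l2_threshold
    return glucose > config.hyper_threshold


def _segments(times: pd.DatetimeIndex, interval: int) -> list[slice]:
    """Maximal runs of consecutive (no missing slot) readings."""
    if len(times) == 0:
        return []
    step = pd.Timedelta(minutes=interval).value
    breaks = np.flatnonzero(np.diff(times.asi8) > step) + 1
    bounds = [0, *breaks.tolist(), len(times)]
    return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]


def detect_events(
    times: pd.DatetimeIndex,
    glucose: np.ndarray,
    kind: EventKind,
    config: MetricConfig | None = None,
    interval: int = 5,
) -> list[GlycemicEvent]:
    """Detect excursion events of one kind in a sorted series.

    An event starts at the first of at least ``min_event_points``
    consecutive readings beyond the threshold (strictly below for the
    hypoglycaemic kinds, strictly above for hyperglycaemia).  An ongoing
    event ends once ``min_recovery_points`` consecutive readings have
    recovered, or at a data gap (any missing grid slot), or at the end
    of the series; shorter interludes at or within the threshold remain
    part of the event.  Events are maximal and non-overlapping, and the
    trailing recovered readings are not counted in the duration.
    """
    config = config or MetricConfig()
    glucose = np.asarray(glucose, dtype=float)
    events: list[GlycemicEvent] = []
    for seg in _segments(times, interval):
        beyond = _beyond(glucose[seg], kind, config)
        t = times[seg]
        g = glucose[seg]
        n = len(g)
        i = 0
        run = 0  # consecutive beyond-threshold readings ending at i-1
        start = -1  # first index of the current event, -1 if none
        last_beyond = -1
        recovery = 0
        in_event = False
        while i < n:
            if beyond[i]:
                if in_event:
                    last_beyond = i
                    recovery = 0
                else:
                    run += 1
                    if run >= config.min_event_points:
                        in_event = True
                        start = i - run + 1
                        last_beyond = i
                        recovery = 0
            else:
                run = 0
                if in_event:
                    recovery += 1
                    if recovery >= config.min_recovery_points:
                        events.append(
                            _make_event(kind, t, g, start, last_beyond, interval)
                        )
                        in_event = False
                        start = last_beyond = -1
                        recovery = 0
            i += 1
        if in_event:
            events.append(_make_event(kind, t, g, start, last_beyond, interval))
    return events


def _make_event(kind, times, glucose, start, last, interval) -> GlycemicEvent:
    chunk = glucose[start : last + 1]
    extremum = float(chunk.max() if kind is EventKind.HYPER else chunk.min())
    n = last - start + 1
    return GlycemicEvent(
        kind=kind,
        start=times[start],
        end=times[last],
        n_readings=n,
        duration_min=n * interval,
        extremum=extremum,
    )


def event_summary(events: Sequence[GlycemicEvent]) -> tuple[int, float]:
    """Event count and mean duration in minutes (NaN when no events)."""
    if not events:
        return 0, math.nan
    return len(events), float(np.mean([e.duration_min for e in events]))


def metric_panel(
    trace: CgmTrace,
    window: AnalysisWindow,
    config: MetricConfig | None = None,
) -> dict[Period, PeriodMetrics]:
    """Compute the full panel for the overall, daytime and nighttime periods.

    Events are detected once on the whole window and assigned to the
    period containing their first reading, with the full duration
    credited to that period; band times and variability use each
    period's own readings.
    """
    config = config or MetricConfig()
    periods = split_periods(trace, window)
    overall = periods[Period.OVERALL]
    events_by_kind = {
        kind: detect_events(
            overall.times, overall.glucose, kind, config, overall.nominal_interval
        )
        for kind in EventKind
    }

    out: dict[Period, PeriodMetrics] = {}
    for period, sub in periods.items():
        if len(sub) == 0:
            raise NoDataError(
                f"subject {trace.subject_id!r}: no readings in period {period.value}"
            )
        bands = band_times(sub.glucose, config)
        mean_g = float(np.mean(sub.glucose))

        def _in_period(ev: GlycemicEvent) -> bool:
            if period is Period.OVERALL:
                return True
            is_day = ev.start.hour >= 6
            return is_day == (period is Period.DAY)

        summaries = {
            kind: event_summary([e for e in evs if _in_period(e)])
            for kind, evs in events_by_kind.items()
        }
        n_l1, d_l1 = summaries[EventKind.HYPO_L1]
        n_l2, d_l2 = summaries[EventKind.HYPO_L2]
        n_hy, d_hy = summaries[EventKind.HYPER]
        out[period] = PeriodMetrics(
            period=period,
            n_readings=len(sub),
            mean_glucose=mean_g,
            cv=cv(sub.glucose),
            tir=bands.tir,
            titr=bands.titr,
            tar=bands.tar,
            tbr=bands.tbr,
            time_l1=bands.time_l1,
            time_l2=bands.time_l2,
            n_l1_events=n_l1,
            mean_l1_duration=d_l1,
            n_l2_events=n_l2,
            mean_l2_duration=d_l2,
            n_hyper_events=n_hy,
            mean_hyper_duration=d_hy,
            gmi=gmi(mean_g),
        )
    return out


def panel_frame(
    panels: dict[str, dict[Period, PeriodMetrics]]
) -> pd.DataFrame:
    """Long frame (one row per subject x period) from per-subject panels."""
    rows = []
    for sid, by_period in panels.items():
        for period, pm in by_period.items():
            row = {"subject_id": sid, "period": period.value}
            row.update(
                {
                    k: getattr(pm, k)
                    for k in (
                        "n_readings",
                        *PANEL_METRICS,
                        "gmi",
                    )
                }
            )
            rows.append(row)
    return pd.DataFrame(rows)


def events_frame(
    events_by_subject: dict[str, Sequence[GlycemicEvent]]
) -> pd.DataFrame:
    rows = [
        {
            "subject_id": sid,
            "kind": e.kind.value,
            "start": e.start,
            "end": e.end,
            "duration_min": e.duration_min,
            "extremum": e.extremum,
        }
        for sid, evs in events_by_subject.items()
        for e in evs
    ]
    return pd.DataFrame(
        rows, columns=["subject_id", "kind", "start", "end", "duration_min", "extremum"]
    )
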