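"""Data model and I/O for continuous glucose monitoring traces.

A CGM sensor reports interstitial glucose every 5 minutes on a nominal
grid; real exports contain gaps (sensor warm-up, signal loss, removed
sensors), occasional duplicate transmissions and out-of-range flags.
This module regularises long-format CSV exports onto the grid, accounts
for sensor wear time and selects the consecutive-day analysis window
used for all downstream metrics.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Reportable sensor span in mg/dL; values outside are clipped on ingest.
SENSOR_SPAN = (40.0, 400.0)

#: Minutes between consecutive readings on the nominal device grid.
DEFAULT_INTERVAL_MIN = 5

MINUTES_PER_DAY = 1440


class CgmDataError(Exception):
    """Base class for ingestion and windowing errors."""


class MissingColumnError(CgmDataError):
    """A required CSV column is absent."""


class IneligibleSubjectError(CgmDataError):
    """No analysis window satisfies the wear-time requirement.

    Carries the best achievable wear fraction so callers can report how
    far the subject fell short.
    """

    def __init__(self, subject_id: str, best_wear: float, n_days: int):
        self.subject_id = subject_id
        self.best_wear = best_wear
        self.n_days = n_days
        super().__init__(
            f"subject {subject_id!r}: no {n_days}-day window meets the wear "
            f"requirement (best achievable wear fraction {best_wear:.3f})"
        )


class Period(str, enum.Enum):
    """Time-of-day stratum for metric computation."""

    OVERALL = "overall"
    DAY = "day"
    NIGHT = "night"


#: Daytime clock interval [06:00, 24:00); nighttime is [00:00, 06:00).
#: Half-open on both sides so the two strata partition every day exactly.
DAY_START_HOUR = 6


class GlucoseReading(tuple):
    """A single (timestamp, glucose mg/dL) pair."""

    __slots__ = ()

    def __new__(cls, timestamp: pd.Timestamp, glucose: float):
        return tuple.__new__(cls, (timestamp, glucose))

    @property
    def timestamp(self) -> pd.Timestamp:
        return self[0]

    @property
    def glucose(self) -> float:
        return self[1]


@dataclass
class CgmTrace:
    """One subject's glucose series on the nominal grid, gaps implicit.

    Readings are stored vectorised (``times``/``glucose``); timestamps are
    strictly increasing and separated by integer multiples of
    ``nominal_interval`` minutes, a multiple greater than one being a gap.
    """

    subject_id: str
    times: pd.DatetimeIndex
    glucose: np.ndarray
    nominal_interval: int = DEFAULT_INTERVAL_MIN

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.glucose = np.asarray(self.glucose, dtype=float)
        if len(self.times) != len(self.glucose):
            raise CgmDataError("times and glucose lengths differ")
        if len(self.times) > 1:
            step = pd.Timedelta(minutes=self.nominal_interval)
            deltas = np.diff(self.times.asi8)
            if (deltas <= 0).any():
                raise CgmDataError(
                    f"subject {self.subject_id!r}: timestamps not strictly increasing"
                )
            if (deltas % step.value != 0).any():
                raise CgmDataError(
                    f"subject {self.subject_id!r}: timestamps off the "
                    f"{self.nominal_interval}-min grid"
                )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def readings(self) -> Iterator[GlucoseReading]:
        for t, g in zip(self.times, self.glucose):
            yield GlucoseReading(t, float(g))

    @property
    def start(self) -> pd.Timestamp:
        return self.times[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.times[-1]

    def span_days(self) -> int:
        """Number of distinct calendar days touched by the trace."""
        if len(self) == 0:
            return 0
        return (self.times[-1].normalize() - self.times[0].normalize()).days + 1

    def restrict(self, start: pd.Timestamp, end: pd.Timestamp) -> "CgmTrace":
        """Readings with ``start <= t < end``."""
        mask = (self.times >= start) & (self.times < end)
        return CgmTrace(
            self.subject_id, self.times[mask], self.glucose[mask], self.nominal_interval
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "timestamp": self.times,
                "glucose_mgdl": self.glucose,
            }
        )


@dataclass
class SubjectRecord:
    """A trace together with the matching covariates."""

    trace: CgmTrace
    age: float
    sex: int  # female=1, male=0
    bmi: float
    cohort: str

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise CgmDataError(f"subject {self.trace.subject_id!r}: age must be > 0")
        if not self.bmi > 0:
            raise CgmDataError(f"subject {self.trace.subject_id!r}: bmi must be > 0")
        if self.sex not in (0, 1):
            raise CgmDataError(
                f"subject {self.trace.subject_id!r}: sex must be 0 (male) or 1 (female)"
            )

    @property
    def subject_id(self) -> str:
        return self.trace.subject_id


@dataclass(frozen=True)
class AnalysisWindow:
    """A consecutive-calendar-day window with its wear fraction."""

    start_date: dt.date
    n_days: int
    wear_fraction: float

    @property
    def start(self) -> pd.Timestamp:
        return pd.Timestamp(self.start_date)

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(days=self.n_days)


@dataclass
class ParseReport:
    """Row-level accounting for one ingest call."""

    rows_read: int = 0
    rows_bad_timestamp: int = 0
    rows_bad_glucose: int = 0
    duplicates: int = 0
    clipped: int = 0
    n_subjects: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


DEFAULT_SCHEMA = {
    "subject_id": "subject_id",
    "timestamp": "timestamp",
    "glucose": "glucose_mgdl",
}

COVARIATE_SCHEMA = {
    "subject_id": "subject_id",
    "age": "age_years",
    "sex": "sex",
    "bmi": "bmi",
    "cohort": "cohort",
}

_SEX_CODES = {"F": 1, "FEMALE": 1, "1": 1, "M": 0, "MALE": 0, "0": 0}


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing required column(s) {missing}")


def parse_cgm_table(
    df: pd.DataFrame,
    schema: Mapping[str, str] | None = None,
    interval: int = DEFAULT_INTERVAL_MIN,
    source: str = "<table>",
) -> tuple[dict[str, CgmTrace], ParseReport]:
    """Regularise a long-format reading table into per-subject traces.

    Timestamps are snapped to the nearest grid slot, duplicate slots are
    collapsed (first occurrence wins) and glucose is clipped to the
    reportable sensor span.  Unparseable rows are dropped and counted;
    the whole call fails only when a majority of rows is unusable.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    cols = [schema["subject_id"], schema["timestamp"], schema["glucose"]]
    _require_columns(df, cols, source)
    report = ParseReport(rows_read=len(df))

    ts = pd.to_datetime(df[schema["timestamp"]], errors="coerce", format="mixed")
    glu = pd.to_numeric(df[schema["glucose"]], errors="coerce")
    bad_ts = ts.isna()
    bad_glu = glu.isna() & ~bad_ts
    report.rows_bad_timestamp = int(bad_ts.sum())
    report.rows_bad_glucose = int(bad_glu.sum())
    n_bad = report.rows_bad_timestamp + report.rows_bad_glucose
    if len(df) > 0 and n_bad > 0.5 * len(df):
        raise CgmDataError(
            f"{source}: {n_bad} of {len(df)} rows unparseable (>50%); aborting"
        )

    keep = ~(bad_ts | bad_glu)
    work = pd.DataFrame(
        {
            "subject_id": df.loc[keep, schema["subject_id"]].astype(str),
            "timestamp": ts[keep].dt.round(f"{interval}min"),
            "glucose": glu[keep].astype(float),
        }
    )

    lo, hi = SENSOR_SPAN
    out_of_span = (work["glucose"] < lo) | (work["glucose"] > hi)
    report.clipped = int(out_of_span.sum())
    work["glucose"] = work["glucose"].clip(lo, hi)

    traces: dict[str, CgmTrace] = {}
    for sid, grp in work.groupby("subject_id", sort=True):
        grp = grp.sort_values("timestamp", kind="stable")
        deduped = grp.drop_duplicates("timestamp", keep="first")
        report.duplicates += len(grp) - len(deduped)
        traces[sid] = CgmTrace(
            sid,
            pd.DatetimeIndex(deduped["timestamp"]),
            deduped["glucose"].to_numpy(),
            interval,
        )
    report.n_subjects = len(traces)
    return traces, report


def read_covariates_csv(
    path, schema: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read the covariate table; returns a frame indexed by subject id.

    Sex is recoded to the binary convention female=1, male=0.
    """
    schema = {**COVARIATE_SCHEMA, **(schema or {})}
    df = pd.read_csv(path)
    _require_columns(df, list(schema.values()), path)
    out = pd.DataFrame(
        {
            "age": pd.to_numeric(df[schema["age"]]).to_numpy(),
            "sex": df[schema["sex"]]
            .astype(str)
            .str.upper()
            .map(_SEX_CODES)
            .to_numpy(),
            "bmi": pd.to_numeric(df[schema["bmi"]]).to_numpy(),
            "cohort": df[schema["cohort"]].astype(str).to_numpy(),
        },
        index=pd.Index(df[schema["subject_id"]].astype(str), name="subject_id"),
    )
    if out["sex"].isna().any():
        bad = df.loc[out["sex"].isna().to_numpy(), schema["sex"]].unique()
        raise CgmDataError(f"{path}: unrecognised sex codes {list(bad)}")
    return out


def read_cgm_csv(
    cgm_path,
    covariates_path=None,
    schema: Mapping[str, str] | None = None,
    interval: int = DEFAULT_INTERVAL_MIN,
) -> tuple[list[SubjectRecord] | dict[str, CgmTrace], ParseReport]:
    """Ingest a long-format CGM CSV, optionally joining covariates.

    With ``covariates_path`` the result is a list of
    :class:`SubjectRecord`; without it a dict of bare traces is returned
    (covariates are required for matching but not for metric work).
    """
    df = pd.read_csv(cgm_path)
    traces, report = parse_cgm_table(df, schema, interval, source=str(cgm_path))
    if covariates_path is None:
        return traces, report
    cov = read_covariates_csv(covariates_path)
    missing = [sid for sid in traces if sid not in cov.index]
    if missing:
        raise CgmDataError(
            f"{covariates_path}: no covariates for subject(s) {missing[:5]}"
        )
    records = [
        SubjectRecord(
            trace=tr,
            age=float(cov.at[sid, "age"]),
            sex=int(cov.at[sid, "sex"]),
            bmi=float(cov.at[sid, "bmi"]),
            cohort=str(cov.at[sid, "cohort"]),
        )
        for sid, tr in traces.items()
    ]
    return records, report


def write_cgm_csv(traces: Sequence[CgmTrace], path) -> None:
    frames = [t.to_frame() for t in traces]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["subject_id", "timestamp", "glucose_mgdl"]
    )
    out.to_csv(path, index=False)


def wear_fraction(
    trace: CgmTrace, start_date: dt.date, n_days: int
) -> float:
    """Observed readings over expected grid slots inside the window.

    A window entirely outside the trace simply yields 0.
    """
    if n_days <= 0:
        raise ValueError("n_days must be positive")
    start = pd.Timestamp(start_date)
    end = start + pd.Timedelta(days=n_days)
    expected = n_days * MINUTES_PER_DAY // trace.nominal_interval
    observed = int(((trace.times >= start) & (trace.times < end)).sum())
    return observed / expected


def select_window(
    trace: CgmTrace, n_days: int = 10, min_wear: float = 0.7
) -> AnalysisWindow:
    """Earliest ``n_days`` consecutive-day window with wear >= ``min_wear``.

    The wear comparison is inclusive (a subject at exactly the threshold
    qualifies).  Raises :class:`IneligibleSubjectError` when no window
    qualifies, carrying the best achievable wear fraction.
    """
    if trace.span_days() < n_days:
        raise IneligibleSubjectError(trace.subject_id, 0.0, n_days)
    first = trace.times[0].normalize().date()
    last = trace.times[-1].normalize().date()
    best = 0.0
    d = first
    while d <= last - dt.timedelta(days=n_days - 1):
        wf = wear_fraction(trace, d, n_days)
        if wf >= min_wear:
            return AnalysisWindow(d, n_days, wf)
        best = max(best, wf)
        d += dt.timedelta(days=1)
    raise IneligibleSubjectError(trace.subject_id, best, n_days)


def period_of(times: pd.DatetimeIndex) -> np.ndarray:
    """Day/night stratum per timestamp by local clock hour."""
    is_day = times.hour >= DAY_START_HOUR
    return np.where(is_day, Period.DAY.value, Period.NIGHT.value)


def split_periods(
    trace: CgmTrace, window: AnalysisWindow
) -> dict[Period, CgmTrace]:
    """Partition the window's readings into overall / daytime / nighttime.

    Daytime is clock time in [06:00, 24:00), nighttime [00:00, 06:00);
    the two subsets are disjoint and their union is the overall set.
    """
    inside = trace.restrict(window.start, window.end)
    day_mask = inside.times.hour >= DAY_START_HOUR
    return {
        Period.OVERALL: inside,
        Period.DAY: CgmTrace(
            inside.subject_id,
            inside.times[day_mask],
            inside.glucose[day_mask],
            inside.nominal_interval,
        ),
        Period.NIGHT: CgmTrace(
            inside.subject_id,
            inside.times[~day_mask],
            inside.glucose[~day_mask],
            inside.nominal_interval,
        ),
    }
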