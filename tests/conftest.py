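"""Shared fixtures: trace builders and one full-size simulated cohort set."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cgmdev.cgm_data import CgmTrace, Period, select_window
from cgmdev.metrics import metric_panel
from cgmdev.synthetic import SimConfig, simulate_cohorts


def make_trace(
    glucose,
    start="2024-03-04 00:00",
    subject_id="S001",
    interval=5,
    times=None,
) -> CgmTrace:
    """Build a trace from a glucose list on a regular grid (or given times)."""
    glucose = np.asarray(glucose, dtype=float)
    if times is None:
        times = pd.date_range(start, periods=len(glucose), freq=f"{interval}min")
    return CgmTrace(subject_id, pd.DatetimeIndex(times), glucose, interval)


@pytest.fixture(scope="session")
def matched_cohorts():
    """Full-size (45 x 3) matched-scenario simulation at the default seed."""
    return simulate_cohorts(SimConfig(seed=1))


@pytest.fixture(scope="session")
def cohort_panels(matched_cohorts):
    """Per-subject overall/day/night metric panels plus window per cohort."""
    out = {}
    for cohort, ds in matched_cohorts.items():
        panels = {}
        for rec in ds.records:
            window = select_window(rec.trace)
            panels[rec.subject_id] = metric_panel(rec.trace, window)
        out[cohort] = panels
    return out


def cohort_overall_values(panels: dict, metric: str) -> np.ndarray:
    return np.array(
        [getattr(p[Period.OVERALL], metric) for p in panels.values()], dtype=float
    )
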