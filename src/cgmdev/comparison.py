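"""Cohort-level summaries, hypothesis tests and the daily glucose profile.

Per-subject metric distributions are summarised as median (IQR).
Two-group comparisons are normality-gated: when both samples pass
Shapiro-Wilk at alpha = 0.05 an unequal-variance (Welch) t test is
used, otherwise the Mann-Whitney U test (exact when sample sizes are
small and tie-free, tie-corrected normal approximation otherwise).
Effect sizes are absolute standardized mean differences flagged at the
>0.2 (moderate) and >0.5 (large) conventions.  The daily profile pools
all readings by 5-minute clock bin across subjects and days and reports
the median and the 5th-95th percentile band per bin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cgm_data import CgmTrace, Period
from .matching import DegenerateCovariateError, smd
from .metrics import PANEL_METRICS

ALPHA = 0.05
MODERATE_SMD = 0.2
LARGE_SMD = 0.5

#: Display labels for the report rows, in panel order.
METRIC_LABELS = {
    "mean_glucose": "Mean glucose level (mg/dL)",
    "tir": "TIR (%) [70-180 mg/dL]",
    "titr": "TITR (%) [70-140 mg/dL]",
    "tar": "TAR (%) [>180 mg/dL]",
    "tbr": "TBR (%) [<70 mg/dL]",
    "cv": "CV (%)",
    "n_l1_events": "L1 hypoglycaemic events",
    "mean_l1_duration": "L1 hypoglycaemic events duration (min)",
    "n_l2_events": "L2 hypoglycaemic events",
    "mean_l2_duration": "L2 hypoglycaemic events duration (min)",
    "n_hyper_events": "Hyperglycaemic events",
    "mean_hyper_duration": "Hyperglycaemic events duration (min)",
    "time_l1": "Time in L1 hypoglycaemic range (%)",
    "time_l2": "Time in L2 hypoglycaemic range (%)",
}


class ComparisonError(Exception):
    pass


@dataclass(frozen=True)
class MetricSummary:
    median: float
    iqr: float
    q1: float
    q3: float


@dataclass(frozen=True)
class TestResult:
    test_used: str  # "t" or "mann_whitney"
    statistic: float
    p_value: float
    significant: bool
    warning: str | None = None


@dataclass(frozen=True)
class EffectFlag:
    abs_smd: float
    band: str  # "none", "moderate", "large"


def summarize(values: Sequence[float]) -> MetricSummary:
    """Median and interquartile range (linear-interpolation quantiles)."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ComparisonError("no values to summarise")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return MetricSummary(median=float(med), iqr=float(q3 - q1), q1=float(q1), q3=float(q3))


def choose_and_test(
    sample_a: Sequence[float], sample_b: Sequence[float], alpha: float = ALPHA
) -> TestResult:
    """Two-sided two-group test with a normality gate.

    Both samples normal by Shapiro-Wilk -> Welch t test; otherwise
    Mann-Whitney U.  Below 8 values per sample the normality test has
    essentially no power, so the nonparametric branch is always taken
    (and the U distribution is evaluated exactly there).  Constant
    samples never pass the gate; two identical constant samples yield
    p = 1 with a warning.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 3 or b.size < 3:
        raise ComparisonError("each sample needs at least 3 values")
    if np.ptp(np.concatenate([a, b])) == 0:
        return TestResult("mann_whitney", np.nan, 1.0, False, "all values identical")

    def normal(x: np.ndarray) -> bool:
        if x.size < 8 or np.ptp(x) == 0:
            return False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return stats.shapiro(x).pvalue > alpha

    if normal(a) and normal(b):
        res = stats.ttest_ind(a, b, equal_var=False)
        return TestResult("t", float(res.statistic), float(res.pvalue), res.pvalue < alpha)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestResult(
        "mann_whitney", float(res.statistic), float(res.pvalue), res.pvalue < alpha
    )


def effect_flags(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> EffectFlag:
    """Absolute SMD between per-subject metric values, banded.

    Two degenerate samples at different constants are an unbounded
    effect and flagged large.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    try:
        value = abs(smd(a, b, "continuous"))
    except DegenerateCovariateError:
        value = math.inf
    if value > LARGE_SMD:
        band = "large"
    elif value > MODERATE_SMD:
        band = "moderate"
    else:
        band = "none"
    return EffectFlag(abs_smd=value, band=band)


def daily_profile(traces: Sequence[CgmTrace], interval: int = 5) -> pd.DataFrame:
    """Pooled ambulatory-style profile: per clock bin, median and p5/p95.

    All readings of all subjects and days are pooled by 5-min time-of-day
    bin (288 bins); bins with no readings carry NaN.
    """
    if not traces:
        raise ComparisonError("no traces")
    n_bins = 1440 // interval
    minutes = np.concatenate(
        [t.times.hour.to_numpy() * 60 + t.times.minute.to_numpy() for t in traces]
    )
    glucose = np.concatenate([t.glucose for t in traces])
    bins = minutes // interval
    rows = []
    for b in range(n_bins):
        vals = glucose[bins == b]
        if vals.size:
            p5, med, p95 = np.percentile(vals, [5, 50, 95])
        else:
            p5 = med = p95 = np.nan
        rows.append(
            {
                "bin_minute": b * interval,
                "clock": f"{(b * interval) // 60:02d}:{(b * interval) % 60:02d}",
                "median": med,
                "p5": p5,
                "p95": p95,
                "n": vals.size,
            }
        )
    return pd.DataFrame(rows)


def _flag_marks(band: str, symbols: tuple[str, str]) -> str:
    return {"none": "", "moderate": symbols[0], "large": symbols[1]}[band]


def build_report(
    metrics: pd.DataFrame,
    reference: str = "RYGB",
    versus: Sequence[str] = ("HEALTHY", "T1D"),
    metric_names: Sequence[str] = tuple(PANEL_METRICS),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort comparison table in the panel's row layout.

    ``metrics`` is long-format with columns subject_id, cohort, period
    and one column per metric.  Returns (report, tests): ``report`` has
    one row per metric with median (IQR) cells per cohort x period,
    effect flags of the reference against each comparator (* / ** for
    the first, + / ++ for the second, at |SMD| > 0.2 and > 0.5);
    ``tests`` carries the companion p-values.
    """
    cohorts = [reference, *versus]
    present = set(metrics["cohort"].unique())
    missing = [c for c in cohorts if c not in present]
    if missing:
        raise ComparisonError(f"missing cohort(s) in metrics table: {missing}")
    periods = [Period.OVERALL.value, Period.DAY.value, Period.NIGHT.value]
    symbol_sets = [("*", "**"), ("+", "++")]

    report_rows, test_rows = [], []
    for metric in metric_names:
        row: dict[str, object] = {"metric": METRIC_LABELS.get(metric, metric)}
        for period in periods:
            sub = metrics[metrics["period"] == period]
            samples = {
                c: sub.loc[sub["cohort"] == c, metric].to_numpy() for c in cohorts
            }
            for c in cohorts:
                values = samples[c]
                if np.isnan(values).all():
                    # e.g. a mean event duration in a cohort without events
                    row[f"{c}_{period}"] = "NA"
                    continue
                s = summarize(values)
                marks = ""
                if c != reference:
                    idx = versus.index(c)
                    ref_vals = samples[reference]
                    comp = samples[c]
                    n_ref = int((~np.isnan(ref_vals)).sum())
                    n_comp = int((~np.isnan(comp)).sum())
                    if n_ref >= 2 and n_comp >= 2:
                        flag = effect_flags(ref_vals, comp)
                        marks = _flag_marks(flag.band, symbol_sets[idx])
                        if n_ref >= 3 and n_comp >= 3:
                            test = choose_and_test(ref_vals, comp)
                            test_rows.append(
                                {
                                    "metric": metric,
                                    "period": period,
                                    "comparison": f"{reference} vs {c}",
                                    "test": test.test_used,
                                    "statistic": test.statistic,
                                    "p_value": test.p_value,
                                    "significant": test.significant,
                                    "abs_smd": flag.abs_smd,
                                }
                            )
                row[f"{c}_{period}"] = f"{s.median:.1f} ({s.iqr:.1f}){marks}"
        report_rows.append(row)
    return pd.DataFrame(report_rows), pd.DataFrame(test_rows)


def report_markdown(report: pd.DataFrame) -> str:
    """Markdown rendering with identical numbers to the CSV form."""
    cols = list(report.columns)
    lines = ["| " + " | ".join(cols) + " |", "|" + "---|" * len(cols)]
    for _, row in report.iterrows():
        lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
    lines.append("")
    lines.append(
        "Note: * / ** flag |SMD| > 0.2 / > 0.5 vs the first comparator; "
        "+ / ++ the same vs the second. Cells are median (IQR). "
        "p-values are reported per metric without multiplicity correction."
    )
    return "\n".join(lines)


def plot_daily_profiles(
    profiles: Mapping[str, pd.DataFrame], path, colors: Mapping[str, str] | None = None
) -> None:
    """Banded daily-profile figure: median line, 5th-95th percentile area."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 5))
    for name, prof in profiles.items():
        hours = prof["bin_minute"] / 60.0
        color = (colors or {}).get(name)
        (line,) = ax.plot(hours, prof["median"], label=name, color=color)
        ax.fill_between(hours, prof["p5"], prof["p95"], alpha=0.2, color=line.get_color())
    ax.set_xlabel("Time of day (h)")
    ax.set_ylabel("Sensor glucose (mg/dL)")
    ax.set_xlim(0, 24)
    ax.axhspan(70, 180, color="0.9", zorder=0)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
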