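"""End-to-end orchestration: simulate/ingest -> eligibility -> match ->
metrics -> compare, with a reproducibility manifest.

Every stage consumes the previous stage's in-memory objects and writes
its artefacts to the output directory; a failure aborts with the stage
name.  The subject counts in the manifest are non-increasing along
ingest -> eligible -> matched, and re-running the same configuration
and seed reproduces identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cgm_data import (
    AnalysisWindow,
    CgmTrace,
    IneligibleSubjectError,
    SubjectRecord,
    read_cgm_csv,
    select_window,
    write_cgm_csv,
)
from .comparison import (
    build_report,
    daily_profile,
    plot_daily_profiles,
    report_markdown,
)
from .matching import match_cohort
from .metrics import EventKind, MetricConfig, detect_events, events_frame, metric_panel, panel_frame
from .synthetic import SimConfig, covariates_frame, simulate_cohorts

log = logging.getLogger("cgmdev")

COHORTS = ("RYGB", "HEALTHY", "T1D")
REFERENCE = "RYGB"


class PipelineError(Exception):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    mode: str = "simulate"  # "simulate" or "files"
    sim: SimConfig = field(default_factory=SimConfig)
    cgm_path: str | None = None
    covariates_path: str | None = None
    n_days: int = 10
    min_wear: float = 0.7
    metric_config: MetricConfig = field(default_factory=MetricConfig)
    caliper: float | str | None = "auto"
    make_plot: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        # one global seed fans out to the simulator
        self.sim.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        metric = MetricConfig(**raw.pop("metric_config", {}))
        return cls(sim=sim, metric_config=metric, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return d


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    n_ingested: dict
    n_eligible: dict
    n_matched: dict
    window_convention: str = "earliest qualifying window"
    matching_convention: str = "independent pairwise vs RYGB reference"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _eligible(
    records: list[SubjectRecord], n_days: int, min_wear: float
) -> tuple[dict[str, tuple[SubjectRecord, AnalysisWindow]], list[str]]:
    kept: dict[str, tuple[SubjectRecord, AnalysisWindow]] = {}
    dropped: list[str] = []
    for rec in records:
        try:
            window = select_window(rec.trace, n_days, min_wear)
        except IneligibleSubjectError as exc:
            log.info("ineligible: %s", exc)
            dropped.append(rec.subject_id)
            continue
        kept[rec.subject_id] = (rec, window)
    return kept, dropped


def run(config: PipelineConfig, out_dir) -> RunManifest:
    """Execute the full pipeline; returns the manifest (also written)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- stage: acquire ----------------------------------------------------
    if config.mode == "simulate":
        datasets = simulate_cohorts(config.sim)
        by_cohort = {c: list(d.records) for c, d in datasets.items()}
        covariates_frame(datasets).to_csv(out / "covariates.csv")
        write_cgm_csv([r.trace for recs in by_cohort.values() for r in recs], out / "cgm.csv")
    elif config.mode == "files":
        if not config.cgm_path or not config.covariates_path:
            raise PipelineError("acquire", "files mode needs cgm_path and covariates_path")
        records, report = read_cgm_csv(config.cgm_path, config.covariates_path)
        (out / "parse_report.json").write_text(report.to_json())
        by_cohort = {c: [] for c in COHORTS}
        for rec in records:
            if rec.cohort not in by_cohort:
                raise PipelineError("acquire", f"unknown cohort label {rec.cohort!r}")
            by_cohort[rec.cohort].append(rec)
    else:
        raise PipelineError("acquire", f"unknown mode {config.mode!r}")
    n_ingested = {c: len(v) for c, v in by_cohort.items()}

    # -- stage: eligibility ------------------------------------------------
    eligible: dict[str, dict[str, tuple[SubjectRecord, AnalysisWindow]]] = {}
    for cohort, recs in by_cohort.items():
        kept, dropped = _eligible(recs, config.n_days, config.min_wear)
        if not kept:
            raise PipelineError("eligibility", f"no eligible subjects in cohort {cohort}")
        eligible[cohort] = kept
    n_eligible = {c: len(v) for c, v in eligible.items()}

    # -- stage: matching ---------------------------------------------------
    ref_cov = _cov_frame(eligible[REFERENCE])
    selected: dict[str, dict[str, tuple[SubjectRecord, AnalysisWindow]]] = {
        REFERENCE: eligible[REFERENCE]
    }
    balance = {}
    for cohort in COHORTS:
        if cohort == REFERENCE:
            continue
        pool_cov = _cov_frame(eligible[cohort])
        try:
            result, report, model = match_cohort(
                ref_cov, pool_cov, caliper=config.caliper
            )
        except Exception as exc:
            raise PipelineError("matching", f"{REFERENCE} vs {cohort}: {exc}") from exc
        pd.DataFrame(
            result.pairs, columns=["reference_id", "matched_id", "logit_distance"]
        ).to_csv(out / f"pairs_{cohort}.csv", index=False)
        balance[cohort] = json.loads(report.to_json())
        selected[cohort] = {
            sid: eligible[cohort][sid] for sid in result.matched_ids
        }
    (out / "balance.json").write_text(json.dumps(balance, indent=2))
    n_matched = {c: len(v) for c, v in selected.items()}

    # -- stage: metrics ----------------------------------------------------
    panels = {}
    all_events = {}
    cohort_of = {}
    windowed: dict[str, list[CgmTrace]] = {c: [] for c in COHORTS}
    for cohort, subjects in selected.items():
        for sid, (rec, window) in subjects.items():
            try:
                panels[sid] = metric_panel(rec.trace, window, config.metric_config)
            except Exception as exc:
                raise PipelineError("metrics", f"subject {sid}: {exc}") from exc
            inside = rec.trace.restrict(window.start, window.end)
            windowed[cohort].append(inside)
            all_events[sid] = [
                e
                for kind in EventKind
                for e in detect_events(
                    inside.times, inside.glucose, kind, config.metric_config,
                    inside.nominal_interval,
                )
            ]
            cohort_of[sid] = cohort
    metrics_df = panel_frame(panels)
    metrics_df.insert(1, "cohort", metrics_df["subject_id"].map(cohort_of))
    metrics_df.to_csv(out / "metrics.csv", index=False)
    events_frame(all_events).to_csv(out / "events.csv", index=False)

    # -- stage: comparison -------------------------------------------------
    try:
        report_df, tests_df = build_report(metrics_df, REFERENCE, ("HEALTHY", "T1D"))
    except Exception as exc:
        raise PipelineError("comparison", str(exc)) from exc
    report_df.to_csv(out / "report.csv", index=False)
    (out / "report.md").write_text(report_markdown(report_df))
    tests_df.to_csv(out / "tests.csv", index=False)
    profiles = {c: daily_profile(tr) for c, tr in windowed.items() if tr}
    prof_frames = []
    for cohort, prof in profiles.items():
        p = prof.copy()
        p.insert(0, "cohort", cohort)
        prof_frames.append(p)
    pd.concat(prof_frames, ignore_index=True).to_csv(out / "profile.csv", index=False)
    if config.make_plot:
        plot_daily_profiles(profiles, out / "profile.png")

    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        seed=config.seed,
        version=__version__,
        n_ingested=n_ingested,
        n_eligible=n_eligible,
        n_matched=n_matched,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _cov_frame(subjects: dict[str, tuple[SubjectRecord, AnalysisWindow]]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": [rec.age for rec, _ in subjects.values()],
            "sex": [rec.sex for rec, _ in subjects.values()],
            "bmi": [rec.bmi for rec, _ in subjects.values()],
        },
        index=pd.Index(list(subjects.keys()), name="subject_id"),
    )
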