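"""Synthetic three-archetype CGM cohort simulator.

Generates cohorts of sensor traces whose metric structure mimics three
clinical archetypes:

* ``RYGB`` — post-gastric-bypass subjects with reactive (post-bariatric)
  hypoglycaemia: near-normal basal glucose, sharp fast meal excursions
  followed by a delayed undershoot that frequently dips below 70 and
  sometimes below 54 mg/dL, with quiet nights (strong day/night
  variability asymmetry).
* ``T1D`` — insulin-pump-treated type 1 diabetes: elevated basal
  glucose, large slow meal excursions and substantial glucose wander at
  all hours, including nocturnally.
* ``HEALTHY`` — non-diabetic controls: tight regulation, modest meal
  responses, low variability.

The latent (true) glucose is a circadian baseline plus bi-exponential
meal-excursion kernels (with an optional delayed negative kernel for
the reactive undershoot) modulated by a smooth log-scale AR(1)
physiological wander, passed through a soft saturation that keeps it
strictly inside the reportable span.  The sensor trace adds
multiplicative AR(1) noise scaled to a target mean absolute relative
difference (MARD) and integer-quantises, emulating device output.
Default archetype parameters are frozen after calibration of the
cohort-median metric panel; see docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cgm_data import CgmTrace, SubjectRecord

SLOTS_PER_DAY = 288
DEFAULT_START = pd.Timestamp("2024-03-04 00:00")


class SimulationError(Exception):
    pass


@dataclass(frozen=True)
class ArchetypeParams:
    """Generative parameters for one cohort archetype.

    Units: glucose quantities in mg/dL, times in minutes unless noted;
    ``wander_sd`` is the stationary SD of the log-scale physiological
    wander (dimensionless) and ``nocturnal_instability`` the additional
    nocturnal wander expressed in mg/dL at the basal level.
    """

    name: str
    basal_mean: float
    basal_sd: float  # between-subject spread of the basal level
    circadian_amplitude: float  # sinusoidal baseline swing, minimum near 03:00
    meal_times: tuple[float, ...]  # clock hours of main meals
    meal_time_sd: float  # hours of day-to-day jitter
    snack_prob: float  # probability of an extra afternoon snack per day
    snack_time: float  # clock hour
    excursion_peak: float  # mean meal peak height above baseline
    peak_sd_subject: float
    peak_sd_meal: float
    excursion_rise: float  # bi-exponential rise constant, minutes
    excursion_fall: float  # bi-exponential fall constant, minutes
    undershoot_prob: float  # per-meal probability of a reactive undershoot
    undershoot_depth: float  # mean depth of the negative kernel
    depth_sd_subject: float
    depth_sd_meal: float
    undershoot_delay: float  # minutes from meal to undershoot onset
    undershoot_rise: float
    undershoot_fall: float
    night_dip_prob: float  # per-night probability of a nocturnal dip
    night_dip_depth: float  # mean depth of the nocturnal negative kernel
    night_dip_sd: float
    wander_sd: float  # log-scale AR(1) stationary SD
    wander_rho: float  # per-5-min lag-1 correlation of the wander
    nocturnal_instability: float  # extra nocturnal wander, mg/dL at basal
    noise_ar1_rho: float = 0.7  # lag-1 correlation of sensor noise
    mard_target: float = 9.0  # percent, drives the noise magnitude
    noise_sd: float = 0.0  # optional additive white sensor noise, mg/dL
    dropout_rate: float = 0.08  # fraction of slots removed in bursts
    dropout_burst_mean: float = 6.0  # mean burst length, slots

    def __post_init__(self) -> None:
        if not self.basal_mean > 0:
            raise ValueError("basal_mean must be positive")
        if not 0 <= self.dropout_rate < 0.3:
            raise ValueError("dropout_rate must be in [0, 0.3)")
        if not 0 <= self.noise_ar1_rho < 1:
            raise ValueError("noise_ar1_rho must be in [0, 1)")
        if not 0 <= self.wander_rho < 1:
            raise ValueError("wander_rho must be in [0, 1)")


def default_archetypes() -> dict[str, ArchetypeParams]:
    """Frozen default parameters for the three cohort archetypes."""
    return {
        "RYGB": ArchetypeParams(
            name="RYGB",
            basal_mean=101.0,
            basal_sd=4.0,
            circadian_amplitude=2.0,
            meal_times=(7.5, 12.5, 19.0),
            meal_time_sd=0.6,
            snack_prob=0.4,
            snack_time=15.5,
            excursion_peak=90.0,
            peak_sd_subject=12.0,
            peak_sd_meal=46.0,
            excursion_rise=8.0,
            excursion_fall=22.0,
            undershoot_prob=0.41,
            undershoot_depth=42.0,
            depth_sd_subject=3.0,
            depth_sd_meal=11.0,
            undershoot_delay=110.0,
            undershoot_rise=15.0,
            undershoot_fall=28.0,
            night_dip_prob=0.22,
            night_dip_depth=34.0,
            night_dip_sd=8.0,
            wander_sd=0.10,
            wander_rho=0.985,
            nocturnal_instability=10.0,
        ),
        "T1D": ArchetypeParams(
            name="T1D",
            basal_mean=135.0,
            basal_sd=12.0,
            circadian_amplitude=1.0,
            meal_times=(7.5, 12.5, 19.0),
            meal_time_sd=0.7,
            snack_prob=0.4,
            snack_time=15.5,
            excursion_peak=27.0,
            peak_sd_subject=8.0,
            peak_sd_meal=10.0,
            excursion_rise=25.0,
            excursion_fall=80.0,
            undershoot_prob=0.40,
            undershoot_depth=68.0,
            depth_sd_subject=10.0,
            depth_sd_meal=8.0,
            undershoot_delay=150.0,
            undershoot_rise=20.0,
            undershoot_fall=40.0,
            night_dip_prob=0.12,
            night_dip_depth=80.0,
            night_dip_sd=10.0,
            wander_sd=0.35,
            wander_rho=0.994,
            nocturnal_instability=10.0,
        ),
        "HEALTHY": ArchetypeParams(
            name="HEALTHY",
            basal_mean=98.5,
            basal_sd=5.0,
            circadian_amplitude=1.0,
            meal_times=(7.5, 12.5, 19.0),
            meal_time_sd=0.6,
            snack_prob=0.3,
            snack_time=15.5,
            excursion_peak=24.0,
            peak_sd_subject=6.0,
            peak_sd_meal=8.0,
            excursion_rise=15.0,
            excursion_fall=70.0,
            undershoot_prob=0.65,
            undershoot_depth=22.0,
            depth_sd_subject=5.0,
            depth_sd_meal=6.0,
            undershoot_delay=100.0,
            undershoot_rise=25.0,
            undershoot_fall=60.0,
            night_dip_prob=0.12,
            night_dip_depth=28.0,
            night_dip_sd=6.0,
            wander_sd=0.033,
            wander_rho=0.985,
            nocturnal_instability=0.0,
        ),
    }


#: Per-cohort covariate models: age is common, BMI reflects each cohort.
COVARIATE_MODELS = {
    "RYGB": {"age_mean": 48.8, "age_sd": 13.3, "bmi_mean": 26.7, "bmi_sd": 5.2},
    "HEALTHY": {"age_mean": 48.3, "age_sd": 14.0, "bmi_mean": 25.5, "bmi_sd": 2.8},
    "T1D": {"age_mean": 48.1, "age_sd": 13.8, "bmi_mean": 27.4, "bmi_sd": 6.1},
}

#: Shifts applied to comparison pools in the confounded scenario.
CONFOUNDING_SHIFTS = {"age": 8.0, "bmi": -2.0}
FEMALE_FRACTION = 36 / 45


@dataclass
class SimConfig:
    n_subjects: int = 45
    n_days: int = 10
    interval: int = 5
    seed: int = 0
    scenario: str = "matched"  # "matched" or "confounded"
    pool_multiplier: int = 4  # pool size factor in the confounded scenario
    archetypes: dict[str, ArchetypeParams] = field(default_factory=default_archetypes)
    start: pd.Timestamp = DEFAULT_START

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["start"] = str(self.start)
        return d


@dataclass
class CohortDataset:
    """One simulated cohort: subject records plus the latent truth."""

    cohort: str
    records: list[SubjectRecord]
    latents: dict[str, CgmTrace]

    @property
    def covariates(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": [r.age for r in self.records],
                "sex": [r.sex for r in self.records],
                "bmi": [r.bmi for r in self.records],
                "cohort": self.cohort,
            },
            index=pd.Index([r.subject_id for r in self.records], name="subject_id"),
        )


def _subject_seed(seed: int, subject_id: str) -> np.random.SeedSequence:
    # Stable per-subject stream: adding a subject never perturbs others.
    return np.random.SeedSequence([int(seed), zlib.crc32(subject_id.encode())])


def _biexp_kernel(tau: np.ndarray, rise: float, fall: float) -> np.ndarray:
    """Unit-peak bi-exponential response for tau >= 0 minutes."""
    if fall <= rise:
        raise SimulationError("fall constant must exceed rise constant")
    t_peak = np.log(fall / rise) * rise * fall / (fall - rise)
    norm = np.exp(-t_peak / fall) - np.exp(-t_peak / rise)
    out = np.where(tau >= 0, np.exp(-tau / fall) - np.exp(-tau / rise), 0.0)
    return out / norm


def _soft_span(x: np.ndarray, lo: float = 40.0, hi: float = 400.0) -> np.ndarray:
    """Smooth saturation keeping values strictly inside (lo, hi).

    Identity in the physiological mid-range; exponential approach to the
    bounds beyond 55 / 350 mg/dL, C1-continuous at the knees.
    """
    lo_knee, hi_knee = lo + 15.0, hi - 50.0
    y = np.asarray(x, dtype=float).copy()
    low = y < lo_knee
    y[low] = lo_knee - (lo_knee - lo) * (1 - np.exp(-(lo_knee - y[low]) / (lo_knee - lo)))
    high = y > hi_knee
    y[high] = hi_knee + (hi - hi_knee) * (1 - np.exp(-(y[high] - hi_knee) / (hi - hi_knee)))
    return y


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: np.ndarray | float) -> np.ndarray:
    """Stationary AR(1) with (locally) stationary SD ``sd``."""
    sd = np.broadcast_to(np.asarray(sd, dtype=float), (n,))
    w = np.empty(n)
    eps = rng.standard_normal(n)
    w[0] = sd[0] * eps[0]
    c = np.sqrt(1.0 - rho * rho)
    for i in range(1, n):
        w[i] = rho * w[i - 1] + c * sd[i] * eps[i]
    return w


def simulate_subject(
    params: ArchetypeParams,
    days: int,
    seed: int | np.random.SeedSequence,
    subject_id: str = "S000",
    start: pd.Timestamp = DEFAULT_START,
    interval: int = 5,
) -> tuple[CgmTrace, CgmTrace]:
    """Simulate one subject; returns (latent trace, sensor trace).

    Both traces share the complete 5-min grid (dropout is injected
    separately).  The same seed always yields identical traces.
    """
    rng = np.random.default_rng(seed)
    n = days * (1440 // interval)
    minutes = np.arange(n) * interval
    clock_h = (minutes % 1440) / 60.0

    basal = rng.normal(params.basal_mean, params.basal_sd)
    circadian = params.circadian_amplitude * -np.cos(2 * np.pi * (clock_h - 3.0) / 24.0)

    peak_mean_i = max(0.0, rng.normal(params.excursion_peak, params.peak_sd_subject))
    # Undershoot depth tracks the subject's basal level: counter-regulation
    # targets an absolute nadir glucose, so higher-basal subjects fall
    # further while the nadir distribution stays basal-independent.
    basal_offset = basal - params.basal_mean
    depth_mean_i = max(
        0.0,
        rng.normal(params.undershoot_depth, params.depth_sd_subject) + basal_offset,
    )

    meals = np.zeros(n)
    horizon = min(n, 1440 // interval)  # kernels act over at most 24 h
    for day in range(days):
        times = list(params.meal_times)
        if rng.random() < params.snack_prob:
            times.append(params.snack_time)
        # stratified undershoot count: each day realises the expected
        # number of reactive episodes (plus Bernoulli remainder), which
        # keeps between-subject exposure comparable
        expected = params.undershoot_prob * len(times)
        n_us = int(expected) + (1 if rng.random() < expected - int(expected) else 0)
        n_us = min(n_us, len(times))
        us_meals = set(rng.choice(len(times), size=n_us, replace=False).tolist())
        for j, mt in enumerate(times):
            t_meal = np.clip(mt + rng.normal(0.0, params.meal_time_sd), 6.2, 23.0)
            start_min = day * 1440 + t_meal * 60.0
            i0 = int(np.ceil(start_min / interval))
            if i0 >= n:
                continue
            i1 = min(n, i0 + horizon)
            tau = minutes[i0:i1] - start_min
            peak = max(0.0, rng.normal(peak_mean_i, params.peak_sd_meal))
            meals[i0:i1] += peak * _biexp_kernel(tau, params.excursion_rise, params.excursion_fall)
            if j in us_meals:
                depth = max(0.0, rng.normal(depth_mean_i, params.depth_sd_meal))
                meals[i0:i1] -= depth * _biexp_kernel(
                    tau - params.undershoot_delay,
                    params.undershoot_rise,
                    params.undershoot_fall,
                )
        # nocturnal dip: basal overshoot / late post-dinner hypoglycaemia
        if rng.random() < params.night_dip_prob:
            t_dip = rng.uniform(0.5, 5.0)
            start_min = day * 1440 + t_dip * 60.0
            i0 = int(np.ceil(start_min / interval))
            if i0 < n:
                i1 = min(n, i0 + horizon)
                tau = minutes[i0:i1] - start_min
                depth = max(
                    0.0,
                    rng.normal(params.night_dip_depth, params.night_dip_sd)
                    + basal_offset,
                )
                meals[i0:i1] -= depth * _biexp_kernel(tau, 15.0, 35.0)

    night = clock_h < 6.0
    extra = params.nocturnal_instability / params.basal_mean
    sigma = np.where(night, params.wander_sd + extra, params.wander_sd)
    w = _ar1(rng, n, params.wander_rho, sigma)
    w = np.clip(w, -2.5 * sigma.max(), 2.5 * sigma.max())
    multiplier = np.exp(w - 0.5 * sigma**2)

    base = basal + circadian + meals
    latent = _soft_span(40.0 + (base - 40.0) * multiplier)
    latent = np.round(latent, 2)

    rel_sd = params.mard_target / 100.0 * np.sqrt(np.pi / 2.0)
    e = _ar1(rng, n, params.noise_ar1_rho, rel_sd)
    sensor = latent * (1.0 + e)
    if params.noise_sd > 0:
        sensor = sensor + rng.normal(0.0, params.noise_sd, n)
    sensor = np.round(np.clip(sensor, 40.0, 400.0))

    times_index = start + pd.to_timedelta(minutes, unit="m")
    return (
        CgmTrace(subject_id, times_index, latent, interval),
        CgmTrace(subject_id, times_index, sensor, interval),
    )


def inject_dropout(
    trace: CgmTrace,
    rate: float,
    burst_mean: float,
    seed: int | np.random.SeedSequence,
) -> CgmTrace:
    """Remove bursts of consecutive readings totalling ``rate`` of slots.

    Burst lengths are geometric with the given mean; the final burst is
    trimmed so the removed count equals ``round(rate * n)`` exactly.
    """
    if not 0 <= rate < 0.3:
        raise SimulationError("dropout rate must be in [0, 0.3)")
    n = len(trace)
    target = int(round(rate * n))
    if target == 0:
        return trace
    rng = np.random.default_rng(seed)
    drop = np.zeros(n, dtype=bool)
    removed = 0
    while removed < target:
        length = min(rng.geometric(1.0 / burst_mean), target - removed)
        i0 = rng.integers(0, n)
        i1 = min(n, i0 + length)
        newly = int((~drop[i0:i1]).sum())
        drop[i0:i1] = True
        removed += newly
    # trim over-removal caused by burst overlap
    if removed > target:
        extra = removed - target
        idx = np.flatnonzero(drop)[-extra:]
        drop[idx] = False
    keep = ~drop
    return CgmTrace(
        trace.subject_id, trace.times[keep], trace.glucose[keep], trace.nominal_interval
    )


def apply_dropout_mask(latent: CgmTrace, sensor_dropped: CgmTrace) -> CgmTrace:
    """Restrict the latent trace to the slots retained in the sensor trace."""
    keep = latent.times.isin(sensor_dropped.times)
    return CgmTrace(
        latent.subject_id, latent.times[keep], latent.glucose[keep], latent.nominal_interval
    )


def mard(sensor: CgmTrace, latent: CgmTrace) -> float:
    """Mean absolute relative difference of sensor vs latent glucose, percent."""
    if len(sensor) != len(latent) or not (sensor.times == latent.times).all():
        raise SimulationError("sensor and latent traces are not on the same grid")
    return float(
        np.mean(np.abs(sensor.glucose - latent.glucose) / latent.glucose) * 100.0
    )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _covariates(
    cohort: str,
    n: int,
    rng: np.random.Generator,
    shifted: bool,
    exact_sex: bool,
) -> pd.DataFrame:
    m = COVARIATE_MODELS[cohort]
    age_mean = m["age_mean"] + (CONFOUNDING_SHIFTS["age"] if shifted else 0.0)
    bmi_mean = m["bmi_mean"] + (CONFOUNDING_SHIFTS["bmi"] if shifted else 0.0)
    age = _truncated_normal(rng, age_mean, m["age_sd"], 18.0, 80.0, n)
    bmi = _truncated_normal(rng, bmi_mean, m["bmi_sd"], 16.0, 55.0, n)
    if exact_sex:
        n_f = int(round(FEMALE_FRACTION * n))
        sex = np.array([1] * n_f + [0] * (n - n_f))
        rng.shuffle(sex)
    else:
        sex = (rng.random(n) < FEMALE_FRACTION).astype(int)
    return pd.DataFrame({"age": age, "sex": sex, "bmi": bmi})


def simulate_covariates(
    cohort: str,
    n: int,
    seed: int,
    shifted: bool = False,
    exact_sex: bool = True,
    id_prefix: str | None = None,
) -> pd.DataFrame:
    """Covariate table alone (age, sex, bmi) for one cohort.

    ``shifted`` applies the confounded-scenario age/BMI shifts; useful
    for exercising matching without paying for trace simulation.
    """
    prefix = id_prefix or cohort
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(f"{prefix}-covariates".encode())])
    )
    cov = _covariates(cohort, n, rng, shifted, exact_sex)
    cov.index = pd.Index([f"{prefix}-{i + 1:03d}" for i in range(n)], name="subject_id")
    cov["cohort"] = cohort
    return cov


def simulate_cohort(
    cohort: str,
    params: ArchetypeParams,
    config: SimConfig,
    n: int | None = None,
    shifted: bool = False,
    exact_sex: bool = True,
    id_prefix: str | None = None,
) -> CohortDataset:
    n = n if n is not None else config.n_subjects
    prefix = id_prefix or cohort
    cov_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(f"{prefix}-covariates".encode())])
    )
    cov = _covariates(cohort, n, cov_rng, shifted, exact_sex)
    records: list[SubjectRecord] = []
    latents: dict[str, CgmTrace] = {}
    for i in range(n):
        sid = f"{prefix}-{i + 1:03d}"
        ss = _subject_seed(config.seed, sid)
        trace_seed, drop_seed = ss.spawn(2)
        latent, sensor = simulate_subject(
            params, config.n_days, trace_seed, sid, config.start, config.interval
        )
        sensor = inject_dropout(
            sensor, params.dropout_rate, params.dropout_burst_mean, drop_seed
        )
        latents[sid] = apply_dropout_mask(latent, sensor)
        records.append(
            SubjectRecord(
                trace=sensor,
                age=float(cov.at[i, "age"]),
                sex=int(cov.at[i, "sex"]),
                bmi=float(cov.at[i, "bmi"]),
                cohort=cohort,
            )
        )
    return CohortDataset(cohort=cohort, records=records, latents=latents)


def simulate_cohorts(config: SimConfig | None = None) -> dict[str, CohortDataset]:
    """Simulate the three cohorts under the configured scenario.

    ``matched``: three cohorts of ``n_subjects`` with identical covariate
    structure (sex exactly 36 F / 9 M at the default size).
    ``confounded``: the RYGB reference plus oversized comparison pools
    with shifted age and BMI and sampled sex, for exercising matching.
    """
    config = config or SimConfig()
    if config.scenario not in ("matched", "confounded"):
        raise SimulationError(f"unknown scenario {config.scenario!r}")
    out: dict[str, CohortDataset] = {}
    for cohort in ("RYGB", "HEALTHY", "T1D"):
        params = config.archetypes[cohort]
        if config.scenario == "confounded" and cohort != "RYGB":
            out[cohort] = simulate_cohort(
                cohort,
                params,
                config,
                n=config.pool_multiplier * config.n_subjects,
                shifted=True,
                exact_sex=False,
            )
        else:
            out[cohort] = simulate_cohort(cohort, params, config)
    return out


def covariates_frame(datasets: Mapping[str, CohortDataset]) -> pd.DataFrame:
    return pd.concat([d.covariates for d in datasets.values()])
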