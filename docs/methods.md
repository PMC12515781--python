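# Methods

`cgmdev` implements a comparative continuous-glucose-monitoring (CGM)
analysis for three adult cohorts — post-Roux-en-Y-gastric-bypass
subjects with reactive (post-bariatric) hypoglycaemia (RYGB),
insulin-pump-treated type 1 diabetes (T1D), and healthy controls —
together with a synthetic cohort simulator that reproduces the cohorts'
glycaemic signatures so the whole pipeline can be exercised and tested
without access to patient data.

## Analysis pipeline

**Eligibility and windowing.** Each subject contributes one window of
10 consecutive calendar days with sensor wear ≥ 70% (observed readings
divided by the 2880 nominal 5-minute slots; the comparison is
inclusive at the threshold). When several windows qualify, the
earliest is used — the earliest-start rule is the most reproducible
convention and is recorded in the run manifest. Timestamps are snapped
to the 5-minute grid, duplicate slots collapse to the first
transmission, and glucose is clipped to the reportable span
[40, 400] mg/dL with a clip counter in the parse report.

**Metric panel.** Per subject and per period — full 24 h, daytime
[06:00, 24:00), nighttime [00:00, 06:00), half-open so the two strata
partition each day exactly — the panel contains: mean glucose;
coefficient of variation CV = s/ȳ × 100 (sample SD); time in range
70 ≤ g ≤ 180 (TIR), tight range 70 ≤ g ≤ 140 (TITR), above range
g > 180 (TAR), below range g < 70 (TBR) with its level-1
(54 ≤ g < 70) and level-2 (g < 54) components; counts and mean
durations of L1-hypoglycaemic, L2-hypoglycaemic and hyperglycaemic
events; and the glucose management indicator
GMI = 3.31 + 0.02392 · (mean glucose), the published linear
HbA1c-equivalent. Band boundaries are closed below and open above so
that TIR + TAR + TBR = 100 and TBR = L1 + L2 hold exactly; all
denominators are non-missing readings, so data gaps never deflate a
percentage.

**Event detection.** An excursion event starts at the first of at
least 3 consecutive readings strictly beyond the threshold (below 70
or 54 mg/dL; above 180 mg/dL for hyperglycaemia) and ends once 3
consecutive readings have recovered, at any missing grid slot, or at
the end of the window; interludes at or within the threshold shorter
than the recovery run remain part of the event. Duration is the
in-event reading count × 5 min — trailing recovered readings are not
counted, and clock time across gaps never inflates an event. Events
are assigned to the period containing their first reading with their
full duration. A run below 54 is by construction also a run below 70,
so every L2 event is nested inside an L1 event; L1 counts include
runs that deepen into L2 (the alternative "pure-L1" counting can be
obtained by differencing the two event lists).

**Matching.** Comparison cohorts are matched 1:1 without replacement
to the fixed RYGB reference on age, sex and BMI, independently per
pairwise comparison. A logistic propensity model (reference coded 1)
is fit by iteratively reweighted least squares (coefficient tolerance
1e-8, ≤100 iterations), continuous covariates standardized internally,
binary covariates raw so their coefficients are log odds ratios. The
default matching rule processes reference subjects in descending
propensity order and, within a caliper of 0.2 × SD of the logit
scores, requires exact sex agreement and takes the candidate closest
in Euclidean z-score distance on age and BMI (caliper matching with
covariate refinement). Plain nearest-neighbour matching on the logit
score alone is available (`refine=False`); it balances only the
confounded direction of covariate space and in simulations leaves a
median max |SMD| ≈ 0.14 versus ≈ 0.10 for the refined rule, which is
why refinement is the default. Balance is reported as standardized
mean differences, SMD = (x̄₁ − x̄₂)/√((s₁² + s₂²)/2) (proportion
version for sex), between the matched samples, with |SMD| < 0.1 the
conventional adequacy flag. One caveat we quantified: with ~45
matched pairs the pure sampling SD of an SMD is √(2/45) ≈ 0.21, and
matching-induced correlation reduces it only to ≈ 0.06–0.12, so even
an optimal 1:1 assignment keeps all three covariates under 0.1 in
only roughly half of simulated replicates. Reported balance should
therefore be read as an estimate with that noise floor, not as a
sharp pass/fail property of the algorithm.

**Cohort comparison.** Per metric and period, cohorts are summarised
as median (IQR, Q3 − Q1, linear-interpolation quantiles). Two-group
tests are normality-gated: Welch's unequal-variance t test when both
samples pass Shapiro–Wilk at α = 0.05, otherwise the Mann–Whitney U
test; below 8 values per sample the gate has essentially no power and
the nonparametric branch is always taken, where the U distribution is
evaluated exactly for tie-free samples. p-values are two-sided,
significance at p < 0.05, deliberately without multiplicity
correction (mirrored in the report footer). Effect sizes are absolute
SMDs on the per-subject metric distributions, flagged at > 0.2
(moderate) and > 0.5 (large). The daily profile pools all readings of
a cohort by 5-minute clock bin (288 bins) across subjects and days
and reports the per-bin median and 5th–95th percentiles.

## Synthetic cohort generator

The generator is a mechanism-level, not physiological, model: latent
glucose is

    G(t) = soft[ 40 + (B_i + C(t) + M(t) − U(t) − N(t) − 40) · exp(w_t − σ_t²/2) ]

with subject basal level B_i ~ Normal(basal_mean, basal_sd); a
circadian term C(t) with minimum near 03:00; bi-exponential
meal-excursion kernels M(t) at breakfast/lunch/dinner (clock-jittered,
plus an optional afternoon snack); a delayed negative undershoot
kernel U(t) on a configurable fraction of meals (the reactive,
RYGB-dominant mechanism); an occasional nocturnal dip kernel N(t)
(late post-dinner/basal-overshoot hypoglycaemia); and a slow
log-scale AR(1) physiological wander w_t whose stationary SD may be
larger at night. Two modelling choices deserve note. First, the
wander acts multiplicatively above a 40 mg/dL floor, which skews
excursions upward and keeps hypoglycaemia rare relative to
hyperglycaemia at equal variance, as in real traces; `soft` is a
C1-continuous saturation beyond 55/350 mg/dL that keeps the latent
trace strictly inside the reportable span on every seed. Second,
undershoot and nocturnal-dip depths track the subject's basal level
(counter-regulation targets an absolute nadir glucose), so the nadir
distribution — and with it the hypoglycaemia event rate — is
independent of the basal draw; per day the number of undershoots is
the expected count plus a Bernoulli remainder rather than independent
per-meal coin flips, keeping between-subject exposure comparable.

The sensor trace is G(t) · (1 + e_t) rounded to integer mg/dL and
clipped to [40, 400], with e_t an AR(1) (lag-1 correlation 0.7)
relative error whose stationary SD is (MARD/100) · √(π/2), so the
mean absolute relative difference of sensor versus latent equals the
target MARD (9% by default) in closed form. Wear gaps are injected as
geometric bursts (mean 6 slots) totalling exactly 8% of slots, so the
wear fraction of 0.92 stays above the 0.70 eligibility bar.
Covariates are age ~ Normal(≈48, 14) truncated to [18, 80], BMI per
cohort (means 26.7/25.5/27.4, SDs 5.2/2.8/6.1 kg/m²), and sex exactly
36 female / 9 male per cohort in the matched scenario; the confounded
scenario instead samples sex Bernoulli(0.8) and shifts pool age by
+8 y and BMI by −2 kg/m² with pools four times the reference size, to
exercise matching.

**Calibration.** Per-archetype defaults (`default_archetypes()`) were
calibrated once by coarse manual search so that the cohort medians of
the per-subject overall panel land on the reference cohort values —
e.g. mean glucose ≈ 99 / 108 / 139 mg/dL and CV ≈ 16 / 29 / 32% for
healthy / RYGB / T1D, RYGB ≈ 12 L1 events per 10 days with quiet
nights, T1D with day- and night-comparable variability — and then
frozen; the acceptance suite checks the medians at a fixed seed
within the published interquartile ranges, and stability was verified
across a dozen seeds before freezing. Problem sizes everywhere follow
the study design: 45 subjects per cohort, 10 days at 5-minute
sampling.

**What the generator does not emulate.** Glucose–insulin ODE
dynamics, meal composition and size, exercise, stress, sensor
compression artefacts, calibration jumps, the worse *absolute*
accuracy of sensors in hypoglycaemia (the noise model is uniformly
relative; real devices degrade to 19–21% MARD below 70 mg/dL), and
day-of-week structure. Passing tests therefore demonstrate that the
analysis code recovers the statistical structure this generator
encodes — not that it would reproduce any particular clinical
dataset.

## Numerical conventions and degenerate inputs

- Quantiles use linear interpolation throughout (affects IQRs at n=45).
- Band boundaries: closed at 70/140/180 into the band; L1 is
  54 ≤ g < 70, L2 is g < 54, TAR is g > 180 (strict).
- Empty periods raise explicit "no data" errors rather than report 0;
  mean event durations are NaN (reported "NA") when a cohort has no
  events; constant-and-equal test samples return p = 1 with a warning;
  two constant samples at different values are an unbounded effect and
  flag "large".
- Greedy matching ties (equal scores or equal distances) break by
  lexical subject id; the pipeline fans one global seed out to
  per-subject streams by hashing subject ids, so adding a subject never
  perturbs the others' traces.
- If a caliper produces zero pairs (tiny cohorts), matching falls back
  to uncalipered nearest-neighbour with a warning.

## Known limitations

- The simulator's archetypes are calibrated to cohort *medians*; the
  dispersion across subjects is plausible but narrower than the
  published IQRs for some event metrics.
- Sensor noise contributes ≈ 11% relative SD at lag-0, which is the
  dominant term in the healthy nighttime CV; conclusions about
  variability at very low true variance are noise-limited by design.
- 1:1 matched balance at n = 45 carries the SMD noise floor discussed
  above; the |SMD| < 0.1 flag is a convention, not a guarantee.
- Local clock time is taken at face value (no timezone arithmetic or
  daylight-saving handling across travel).
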