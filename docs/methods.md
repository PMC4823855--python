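# Methods

## The validation model

The package measures the diagnostic accuracy of ICD-10 N17x coding for acute
kidney injury (AKI) in kidney transplant recipients against a reference
standard computed from serum creatinine. The pipeline is:

1. **Cohort.** Keep admissions of first kidney-only graft recipients,
   admitted ≥ 183 days post transplant, inside the study window, with at
   least one in-admission creatinine and a baseline creatinine 14–183 days
   pre-admission. When a patient has several eligible admissions, one index
   admission is drawn uniformly at random so each patient contributes a
   single observation (no within-patient clustering).
2. **Reference standard.** The creatinine-only AKIN stage from baseline and
   peak: stage 1 at a rise ≥ 26.4 µmol/L or a 1.5–2-fold increase; stage 2
   at a > 2–3-fold increase; stage 3 beyond 3-fold, or peak > 354 µmol/L
   with a rise ≥ 44 µmol/L. Three reference dichotomies are used: stage ≥ 1,
   stage ≥ 2, stage = 3.
3. **Index test.** N17x positivity under three algorithms of decreasing
   breadth: any of the 25 diagnosis fields; a pre-admission-type diagnosis;
   the unique most-responsible (type M) diagnosis. Codes are canonicalised
   (dots/whitespace stripped, uppercased) and prefix-matched on "N17".
4. **Accuracy.** Per (reference, algorithm) 2×2 table: Sn, Sp, PPV, NPV with
   Wilson score 95 % intervals, LR+ = Sn/(1−Sp); whole-table suppression
   when any cell is a nonzero count below the threshold (default 6, the
   "1–5 small cell" convention). Creatinine-change distributions of code
   groups are contrasted as median (IQR) with the Mann-Whitney test.

### Assumptions inherited from the design

* Only the creatinine criteria of AKIN are modelled. Urine output and the
  48-hour timing window are not represented in admission-level data and are
  deliberately omitted; the "acute" rise of the stage-3 absolute clause is
  evaluated as peak − baseline.
* "x-fold increase" is read as peak/baseline = x, so ratio exactly 2 is
  stage 1 and exactly 3 is stage 2; a rise of exactly 26.4 (or 44) meets the
  inclusive thresholds, a peak of exactly 354 fails the strict one.
* Day-resolution calendar time; an inpatient lab belongs to an admission iff
  its draw date lies in [admit, discharge], inclusive. "Six months" is
  183 days and "two weeks" 14 days, both window bounds inclusive. Same-day
  duplicate baselines are averaged; peak ties break to the earliest date.
* Comorbidity flags use a 1,095-day lookback with caller-supplied code
  prefix lists (validated lists are jurisdiction-specific, so none are baked
  in). eGFR descriptives use the 2009 CKD-EPI equation, race coefficient
  omitted by default.

## Rounding and the reconstruction oracle

Reported percentages use half-up rounding. The replication target tables
were printed at one decimal but follow a **double rounding** convention —
half-up to two decimals, then to one (statistical software prints two
decimals; transcription to one decimal rounds the printed value). This is
adopted as `paper_round` because it reproduces all forty published
percentages exactly, whereas direct one-decimal rounding disagrees on six
(e.g. a PPV of 26/54 = 48.148 % printed as 48.2, and a Wilson lower bound of
31.6486 % printed as 31.7). LR+ as published divides the *already rounded*
one-decimal percentages (`paper_rounded` mode, default in reports); the
library also exposes the exact ratio, which differs by 0.1 at print
precision in four of eight rows.

The oracle inverts a printed row by brute force over the true-positive
count: marginals (cohort size, reference-positives, code-positives) pin
FP/FN/TN once TP is fixed, and a candidate survives if all four recomputed
statistics re-round to print. Each of the eight unsuppressed published rows
has exactly one survivor; the suppressed main-diagnosis/stage ≥ 1 row is not
reconstructible from print and is excluded.

## The synthetic-data generator

The generator emulates the four registry extracts for a cohort in which
every patient is eligible by construction. Defaults are the study
conditions: n = 524; stage prevalences (55, 30.5, 4.0, 10.5) %; baseline
creatinine lognormal with median 133 µmol/L and log-SD 0.3887 (reproducing
the reported IQR 103–174); uniform timing ranges (transplant-to-admission
gap 200–2555 d, baseline draw 14–90 d pre-admission, stay 2–14 d, peak drawn
0–2 d after admission) consistent with the eligibility windows and the
reported "peak at median day 1" timing; study window 2003-04-01 to
2012-12-31.

Peaks are *planted by inversion of the staging rule*: for each (baseline,
stage) pair a peak is drawn uniformly from the interior of that stage's
creatinine region, at least 1 µmol/L (shrunk proportionally in narrow
regions) from every staging boundary, which guarantees that staging the
generated labs recovers the latent stage (the round-trip property tested at
10⁴ pairs). One consequence of the staging rule itself: **stage 2 is
unattainable for baselines ≥ ~177 µmol/L**, because any peak above twice
such a baseline already exceeds 354 µmol/L with a rise ≥ 44 and is stage 3.
`sample_peak_for_stage` raises for such pairs, and the generator draws
stage-2 baselines from the truncated (feasible) part of the baseline
distribution — a mild distortion affecting only the ~4 % stage-2 stratum.

Coding indicators are drawn conditional on the true stage with **nested
coupling**: any-diagnosis positivity first, admission-type positivity
conditional on it, main-diagnosis conditional on that. Nesting is a
structural necessity — an N17x row of any diagnosis type makes the
any-diagnosis algorithm positive, so the three indicators cannot be
independent — and the coupling preserves each algorithm's stage-conditional
marginal P(code+ | stage). Default profiles are the stage-conditional rates
implied by the reconstructed study counts (any: 8/288, 34/160, 10/21, 22/55;
admission and main analogously), which also reproduce the nested
code-positive totals 74 ⊇ 54 ⊇ 25. The published row suppressed in print
leaves one free integer — how the main-diagnosis algorithm's 12 false
positives against stage ≥ 2 split between stages 0 and 1; the default plant
places 2 at stage 0, which gives that pair a small cell so it renders as
suppressed, mirroring the original report.

**Exact planting** (`plant_exact_dataset`) assigns stages and nested code
patterns by count rather than by draw, so the full pipeline reproduces a
`PlantSpec`'s 2×2 tables cell-exactly for every pair at any seed; only
dates and creatinine values vary with the seed. `study_plant_spec()` solves
the spec from the oracle-reconstructed published tables.

What the generator does **not** emulate: correlated comorbidity structure,
multiple creatinine trajectories per admission beyond baseline/peak/one
midpoint value, seasonal admission patterns, inter-regional lab-coverage
differences, ICD-9-era records, or any dependence of coding on factors
other than the true stage. Passing tests therefore demonstrate the
correctness and calibration of the *pipeline*, not the realism of any
particular clinical scenario.

## Numerical choices

* Wilson intervals use the exact normal quantile (1.959964… at 95 %),
  closed form, clipped to [0, 1]; a zero denominator yields an undefined
  (NaN-flagged) metric, never an exception. Verified against a root-finding
  oracle to 1e-9 and against statsmodels.
* Quartiles use linear interpolation between order statistics (the
  convention is configurable in principle via numpy's `method`, documented
  here because the original software convention is unknowable).
* Mann-Whitney: exact enumeration for tie-free samples with combined
  n ≤ 12, otherwise the normal approximation with midrank tie correction
  and continuity correction; two-sided p by default.
* A single global seed drives all randomness through named substreams
  (simulation, index selection), so runs are byte-reproducible and each
  stage is independently replayable. Seeds derived for replicate studies
  stay below 2³¹.

## Problem sizes in the shipped studies

The recovery (simulate-then-estimate) study uses 200 replicates of
n = 50,000 patients with coding sensitivity 0.28 / specificity 0.972 against
stage ≥ 1, and checks Wilson-interval coverage of the generating values.
Nominal coverage is 95 %; a 200-replicate estimate of a 95 % rate has a
standard error of ~1.5 points, so observed coverage for any particular seed
set scatters a few points around 95 — the check uses a 93 % floor, and a
large-replicate statistical oracle (200,000 draws of the equivalent
binomial experiment) places the true coverage at 94.97 % for both metrics.

## Known limitations

* The cascade order of the eligibility rules (a)–(e) affects per-rule
  exclusion counts (not the final cohort); the order used is as listed.
* Whether a most-responsible N17x also counted toward the admission-type
  algorithm in the original coding practice is unknown; the algorithms are
  evaluated independently by diagnosis type here.
* The baseline-window arithmetic (183 vs 180 days; inclusive bounds) is a
  documented convention, configurable through `BaselineWindow`.
* Suppression thresholds vary by custodian; the default 6 encodes the
  common "cells of 1–5" rule and is configurable.
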