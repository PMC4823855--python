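"""Synthetic administrative/laboratory data for the code-validation pipeline.

The real linked registries behind AKI code-validation studies (transplant
registers, discharge abstracts, hospital lab warehouses) are not publicly
deposited, so this module generates the four input tables — patients,
transplants, admissions with typed diagnoses, and serum-creatinine draws —
with the statistical structure the analysis assumes:

* every patient is a first kidney-only transplant recipient with one (or
  optionally more) eligible admission, an in-admission creatinine and a
  baseline draw inside the 2-week-to-6-month window;
* each patient carries a latent AKIN stage drawn from configurable stage
  prevalences; the peak creatinine is constructed so that staging the
  generated labs recovers that stage exactly (round-trip guarantee);
* N17x coding is drawn conditional on the true stage, per algorithm, with
  nested positivity (main ⊆ admission ⊆ any diagnosis) — a structural
  necessity, since an N17x row of any type makes the any-diagnosis
  algorithm positive.

Two modes exist: :func:`generate_population` samples from the configured
distributions; :func:`plant_exact_dataset` deterministically plants the
joint (stage, code-pattern) counts of a :class:`PlantSpec`, so that the full
pipeline reproduces specified 2x2 tables cell for cell. Defaults are
calibrated to the published transplant validation cohort (n = 524, stage
prevalences 55/30.5/4/10.5 %, baseline creatinine median 133 IQR 103-174
umol/L, 14.1 % code-positive).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import pathlib
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .codes import ALGORITHMS, DX_MAIN, DX_OTHER, DX_PREADMIT
from .cohort import EligibilityConfig
from .errors import ConfigurationError, InconsistentCountsError
from .performance import TwoByTwo
from .staging import (
    STAGE1_DELTA,
    STAGE1_RATIO,
    STAGE2_RATIO,
    STAGE3_RATIO,
    STAGE3_DELTA,
    STAGE3_PEAK,
    akin_stage,
)

__all__ = [
    "CodeProfile",
    "TimingParams",
    "SimulationParams",
    "PlantSpec",
    "Population",
    "sample_peak_for_stage",
    "stage2_feasible",
    "generate_population",
    "plant_exact_dataset",
    "plant_spec_from_tables",
    "study_plant_spec",
]

# Highest baseline (umol/L) at which AKIN stage 2 is attainable at all: for
# baseline b >= 44, any peak above 2b with 2b >= 354 also trips the stage-3
# absolute clause (peak > 354 with a rise >= 44), so the stage-2 region
# (2b, min(3b, 354)] empties once 2b reaches 354.
STAGE2_BASELINE_SUP = STAGE3_PEAK / STAGE2_RATIO  # 177.0

_FILLER_MAIN_CODES = ("J189", "A419", "I509", "K566", "E119", "N390")
_N17_CODES = ("N170", "N171", "N179")


@dataclass(frozen=True)
class CodeProfile:
    """P(N17x code positive | true AKIN stage s), s = 0..3, per algorithm.

    Profiles must be nested (main <= admission <= any, stage by stage) so
    that the generated diagnosis rows can realise all three indicators
    coherently. Defaults are the stage-conditional rates implied by the
    reconstructed joint counts of the published cohort.
    """

    any_diagnosis: Tuple[float, float, float, float] = (8 / 288, 34 / 160, 10 / 21, 22 / 55)
    admission_diagnosis: Tuple[float, float, float, float] = (6 / 288, 22 / 160, 8 / 21, 18 / 55)
    main_diagnosis: Tuple[float, float, float, float] = (2 / 288, 10 / 160, 3 / 21, 10 / 55)

    def __post_init__(self):
        for name in ALGORITHMS:
            probs = getattr(self, name)
            if len(probs) != 4 or any(not 0.0 <= p <= 1.0 for p in probs):
                raise ConfigurationError(f"{name}: need four probabilities in [0, 1]")
        for s in range(4):
            if not (
                self.main_diagnosis[s] <= self.admission_diagnosis[s] + 1e-12
                and self.admission_diagnosis[s] <= self.any_diagnosis[s] + 1e-12
            ):
                raise ConfigurationError(
                    f"profile not nested at stage {s}: need main <= admission <= any"
                )


@dataclass(frozen=True)
class TimingParams:
    """Uniform day-count ranges for event timing, all inclusive.

    ``transplant_gap_days`` — transplant to index admission (must clear the
    6-month post-transplant exclusion); ``baseline_offset_days`` — baseline
    draw before admission (must sit inside the baseline window);
    ``length_of_stay_days``; ``peak_day_offset`` — admission to peak draw.
    """

    transplant_gap_days: Tuple[int, int] = (200, 2555)
    baseline_offset_days: Tuple[int, int] = (14, 90)
    length_of_stay_days: Tuple[int, int] = (2, 14)
    peak_day_offset: Tuple[int, int] = (0, 2)

    def validate(self, eligibility: EligibilityConfig) -> None:
        gap_lo, gap_hi = self.transplant_gap_days
        if gap_lo > gap_hi or gap_lo < eligibility.post_transplant_min_days:
            raise ConfigurationError(
                "transplant_gap_days must start at or after the post-transplant "
                f"exclusion window ({eligibility.post_transplant_min_days} days); "
                f"got {self.transplant_gap_days}"
            )
        off_lo, off_hi = self.baseline_offset_days
        w = eligibility.baseline_window
        if not (w.min_offset_days <= off_lo <= off_hi <= w.max_offset_days):
            raise ConfigurationError(
                "baseline_offset_days must lie inside the baseline window "
                f"[{w.min_offset_days}, {w.max_offset_days}]; got {self.baseline_offset_days}"
            )
        if not (0 <= self.peak_day_offset[0] <= self.peak_day_offset[1] <= self.length_of_stay_days[0]):
            raise ConfigurationError(
                "peak_day_offset must fit inside the shortest stay; "
                f"got {self.peak_day_offset} vs stay {self.length_of_stay_days}"
            )


@dataclass(frozen=True)
class SimulationParams:
    """Full parameterisation of the distributional generator.

    ``stage_prevalence`` gives P(AKIN stage 0..3); defaults are the study
    shares (55, 30.5, 4.0, 10.5 %). Baseline creatinine is lognormal with
    the given median and log-scale sigma (defaults reproduce median 133,
    IQR ~103-174 umol/L). ``boundary_margin`` keeps planted peaks away from
    staging thresholds to avoid float-edge flips.
    """

    n_patients: int = 524
    stage_prevalence: Tuple[float, float, float, float] = (0.55, 0.305, 0.04, 0.105)
    code_profile: CodeProfile = field(default_factory=CodeProfile)
    baseline_scr_median: float = 133.0
    baseline_scr_sigma: float = 0.3887
    timing: TimingParams = field(default_factory=TimingParams)
    eligibility: EligibilityConfig = field(default_factory=EligibilityConfig)
    female_fraction: float = 0.353
    age_mean: float = 57.7
    age_sd: float = 12.1
    extra_admission_prob: float = 0.0
    boundary_margin: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        prev = self.stage_prevalence
        if len(prev) != 4 or any(p < 0 or p > 1 for p in prev):
            raise ConfigurationError("stage_prevalence needs four probabilities in [0, 1]")
        if abs(sum(prev) - 1.0) > 1e-12:
            raise ConfigurationError(f"stage_prevalence must sum to 1, got {sum(prev)}")
        if not 0 <= self.extra_admission_prob <= 1:
            raise ConfigurationError("extra_admission_prob must be in [0, 1]")
        if self.baseline_scr_median <= 0 or self.baseline_scr_sigma <= 0:
            raise ConfigurationError("baseline creatinine distribution must be positive")
        self.timing.validate(self.eligibility)

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj):
                obj = dataclasses.asdict(obj)
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, _dt.date):
                return obj.isoformat()
            if isinstance(obj, (tuple, list)):
                return [conv(v) for v in obj]
            return obj

        return conv(self)


@dataclass
class Population:
    """The four generated tables (diagnoses split out as a fifth)."""

    patients: pd.DataFrame
    transplants: pd.DataFrame
    admissions: pd.DataFrame
    diagnoses: pd.DataFrame
    labs: pd.DataFrame
    params: dict
    seed: int

    _TABLES = ("patients", "transplants", "admissions", "diagnoses", "labs")

    def write(self, directory) -> None:
        """Write the CSV tables plus a JSON sidecar recording params/seed."""
        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            df = getattr(self, name).copy()
            for col in df.columns:
                if pd.api.types.is_datetime64_any_dtype(df[col]):
                    df[col] = df[col].dt.strftime("%Y-%m-%d")
            df.to_csv(directory / f"{name}.csv", index=False)
        (directory / "simulation.json").write_text(
            json.dumps({"seed": self.seed, "params": self.params}, indent=2)
        )

    @classmethod
    def read(cls, directory) -> "Population":
        directory = pathlib.Path(directory)
        frames = {}
        date_cols = {
            "patients": ["birth_date"],
            "transplants": ["transplant_date"],
            "admissions": ["admit_date", "discharge_date"],
            "diagnoses": [],
            "labs": ["draw_date"],
        }
        for name in cls._TABLES:
            path = directory / f"{name}.csv"
            if not path.exists():
                raise FileNotFoundError(f"missing input table {path}")
            frames[name] = pd.read_csv(path, parse_dates=date_cols[name])
        sidecar = directory / "simulation.json"
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(**frames, params=meta.get("params", {}), seed=meta.get("seed", -1))


def stage2_feasible(baseline, margin: float = 1.0):
    """Whether AKIN stage 2 is attainable at this baseline (vectorised)."""
    b = np.asarray(baseline, dtype=float)
    return STAGE2_RATIO * b + 2 * margin < np.minimum(
        STAGE3_RATIO * b, np.maximum(STAGE3_PEAK, b + STAGE3_DELTA)
    )


def sample_peak_for_stage(baseline, stage, rng, margin: float = 1.0):
    """Draw a peak creatinine whose staging against ``baseline`` is ``stage``.

    Vectorised over equal-length arrays. Peaks are sampled uniformly from the
    interior of the stage's creatinine region, at least ``margin`` umol/L
    (shrunk proportionally for narrow regions) away from each staging
    boundary so floating-point comparisons cannot flip the stage.

    Raises
    ------
    ConfigurationError
        For (baseline, stage 2) pairs with baseline at or above the
        feasibility bound of ~177 umol/L, where every peak beyond twice the
        baseline also satisfies the stage-3 absolute clause.
    """
    b = np.atleast_1d(np.asarray(baseline, dtype=float))
    s = np.broadcast_to(np.atleast_1d(np.asarray(stage, dtype=int)), b.shape)
    if np.any(b <= 0):
        raise ValueError("baseline must be positive")
    if np.any((s < 0) | (s > 3)):
        raise ValueError("stage must be in 0..3")

    infeasible = (s == 2) & ~stage2_feasible(b, margin)
    if infeasible.any():
        bad = b[infeasible][:5]
        raise ConfigurationError(
            f"stage 2 unattainable for baselines {np.round(bad, 1).tolist()} "
            f"(>= {STAGE2_BASELINE_SUP - 2 * margin:.0f} umol/L): any peak above twice "
            "the baseline also meets the stage-3 absolute criterion"
        )

    stage1_floor = np.minimum(b + STAGE1_DELTA, STAGE1_RATIO * b)
    abs3_edge = np.maximum(STAGE3_PEAK, b + STAGE3_DELTA)  # peaks beyond are stage 3

    lo = np.empty_like(b)
    hi = np.empty_like(b)
    m0, m3 = s == 0, s == 3
    m1, m2 = s == 1, s == 2
    lo[m0] = 0.6 * b[m0]
    hi[m0] = stage1_floor[m0]
    lo[m1] = stage1_floor[m1]
    hi[m1] = np.minimum(STAGE2_RATIO * b[m1], abs3_edge[m1])
    lo[m2] = STAGE2_RATIO * b[m2]
    hi[m2] = np.minimum(STAGE3_RATIO * b[m2], abs3_edge[m2])
    lo[m3] = np.minimum(STAGE3_RATIO * b[m3], abs3_edge[m3])
    hi[m3] = 1.6 * lo[m3]

    pad = np.minimum(margin, (hi - lo) / 4.0)
    peak = rng.uniform(lo + pad, hi - pad)
    got = akin_stage(b, peak)
    if np.any(got != s):  # pragma: no cover - guaranteed by construction
        raise AssertionError("sampled peak does not recover the requested stage")
    if np.isscalar(baseline) and np.isscalar(stage):
        return float(peak[0])
    return peak


def _draw_baselines(n, stage, params: SimulationParams, rng) -> np.ndarray:
    """Lognormal baselines; stage-2 rows redrawn into the feasible range."""
    mu = np.log(params.baseline_scr_median)
    b = rng.lognormal(mu, params.baseline_scr_sigma, size=n)
    need = (np.asarray(stage) == 2) & ~stage2_feasible(b, params.boundary_margin)
    while need.any():
        b[need] = rng.lognormal(mu, params.baseline_scr_sigma, size=int(need.sum()))
        need = (np.asarray(stage) == 2) & ~stage2_feasible(b, params.boundary_margin)
    return b


def _assemble(
    stage: np.ndarray,
    any_pos: np.ndarray,
    adm_pos: np.ndarray,
    main_pos: np.ndarray,
    baseline: np.ndarray,
    peak: np.ndarray,
    params: SimulationParams,
    rng: np.random.Generator,
    seed: int,
) -> Population:
    """Materialise the five tables from per-patient latent variables."""
    n = len(stage)
    elig = params.eligibility
    t = params.timing
    nums = np.char.zfill(np.arange(1, n + 1).astype("U6"), 6)
    pid = np.char.add("P", nums)
    aid = np.char.add("A", nums)

    max_stay = t.length_of_stay_days[1]
    start = pd.Timestamp(elig.study_start)
    # leave room so every discharge precedes the lab-capture end date
    span = (pd.Timestamp(elig.lab_end_date) - start).days - max_stay - 1
    if span <= 0:
        raise ConfigurationError("study window too short for the configured stays")
    admit = start + pd.to_timedelta(rng.integers(0, span + 1, n), unit="D")
    los = rng.integers(t.length_of_stay_days[0], t.length_of_stay_days[1] + 1, n)
    discharge = admit + pd.to_timedelta(los, unit="D")
    gap = rng.integers(t.transplant_gap_days[0], t.transplant_gap_days[1] + 1, n)
    tx_date = admit - pd.to_timedelta(gap, unit="D")

    sex = np.where(rng.random(n) < params.female_fraction, "F", "M")
    age = np.clip(rng.normal(params.age_mean, params.age_sd, n), 20.0, 90.0)
    birth = admit - pd.to_timedelta((age * 365.25).astype(int), unit="D")
    donor = rng.choice(["deceased", "living", "missing"], n, p=[0.662, 0.315, 0.023])

    patients = pd.DataFrame({"patient_id": pid, "sex": sex, "birth_date": birth})
    transplants = pd.DataFrame(
        {
            "patient_id": pid,
            "transplant_date": tx_date,
            "organ": "kidney",
            "graft_number": 1,
            "donor_type": donor,
        }
    )
    admissions = pd.DataFrame(
        {
            "admission_id": aid,
            "patient_id": pid,
            "admit_date": admit,
            "discharge_date": discharge,
        }
    )

    # --- diagnoses ---------------------------------------------------------
    filler = rng.choice(_FILLER_MAIN_CODES, n)
    n17 = rng.choice(_N17_CODES, n)
    main_code = np.where(main_pos, n17, filler)
    frames = [
        pd.DataFrame(
            {"admission_id": aid, "position": 1, "code": main_code, "dx_type": DX_MAIN}
        ),
        # transplant-status code on every abstract: realistic non-N17 noise
        pd.DataFrame(
            {"admission_id": aid, "position": 2, "code": "Z940", "dx_type": DX_OTHER}
        ),
    ]
    if adm_pos.any():
        frames.append(
            pd.DataFrame(
                {
                    "admission_id": aid[adm_pos],
                    "position": 3,
                    "code": n17[adm_pos],
                    "dx_type": DX_PREADMIT,
                }
            )
        )
    other_only = any_pos & ~adm_pos & ~main_pos
    if other_only.any():
        frames.append(
            pd.DataFrame(
                {
                    "admission_id": aid[other_only],
                    "position": 4,
                    "code": n17[other_only],
                    "dx_type": DX_OTHER,
                }
            )
        )
    diagnoses = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["admission_id", "position"])
        .reset_index(drop=True)
    )

    # --- labs ---------------------------------------------------------------
    base_offset = rng.integers(t.baseline_offset_days[0], t.baseline_offset_days[1] + 1, n)
    base_date = admit - pd.to_timedelta(base_offset, unit="D")
    peak_off = np.minimum(
        rng.integers(t.peak_day_offset[0], t.peak_day_offset[1] + 1, n), los
    )
    peak_date = admit + pd.to_timedelta(peak_off, unit="D")
    # optional second in-admission value strictly between baseline and peak
    # (below the peak when creatinine rose, between peak and baseline when it
    # fell), so it can never change the observed peak's stage
    mid_value = np.where(
        peak >= baseline, baseline + 0.5 * (peak - baseline), 0.5 * (peak + baseline)
    )
    has_mid = (rng.random(n) < 0.5) & (los >= 1)
    mid_date = admit + pd.to_timedelta(np.minimum(peak_off + 1, los), unit="D")

    def lab_frame(ids, dates, values, setting, adm_ids):
        return pd.DataFrame(
            {
                "patient_id": ids,
                "draw_date": dates,
                "analyte": "creatinine",
                "value": np.round(values, 1),
                "units": "umol/L",
                "setting": setting,
                "admission_id": adm_ids,
            }
        )

    labs = pd.concat(
        [
            lab_frame(pid, base_date, baseline, "outpatient", ""),
            lab_frame(pid, peak_date, peak, "inpatient", aid),
            lab_frame(
                pid[has_mid], mid_date[has_mid], mid_value[has_mid], "inpatient", aid[has_mid]
            ),
        ],
        ignore_index=True,
    ).sort_values(["patient_id", "draw_date"], kind="stable").reset_index(drop=True)

    pop = Population(
        patients=patients,
        transplants=transplants,
        admissions=admissions,
        diagnoses=diagnoses,
        labs=labs,
        params=params.to_dict(),
        seed=seed,
    )

    if params.extra_admission_prob > 0:
        _add_extra_admissions(pop, baseline, peak, base_offset, los, params, rng)
    return pop


def _add_extra_admissions(pop, baseline, peak, base_offset, los, params, rng):
    """Clone a random subset of admissions to exercise index selection."""
    adm = pop.admissions
    n = len(adm)
    chosen = rng.random(n) < params.extra_admission_prob
    shift = pd.to_timedelta(rng.integers(250, 600, n), unit="D")
    new_admit = adm["admit_date"] + shift
    new_discharge = adm["discharge_date"] + shift
    fits = new_discharge < pd.Timestamp(params.eligibility.lab_end_date)
    chosen &= fits.to_numpy()
    if not chosen.any():
        return
    idx = np.flatnonzero(chosen)
    new_aid = np.array([f"B{i:06d}" for i in idx + 1])
    pid = adm["patient_id"].to_numpy()[idx]
    pop.admissions = pd.concat(
        [
            adm,
            pd.DataFrame(
                {
                    "admission_id": new_aid,
                    "patient_id": pid,
                    "admit_date": new_admit.to_numpy()[idx],
                    "discharge_date": new_discharge.to_numpy()[idx],
                }
            ),
        ],
        ignore_index=True,
    )
    dx = pop.diagnoses
    cloned = dx[dx["admission_id"].isin(adm["admission_id"].to_numpy()[idx])].copy()
    remap = dict(zip(adm["admission_id"].to_numpy()[idx], new_aid))
    cloned["admission_id"] = cloned["admission_id"].map(remap)
    pop.diagnoses = pd.concat([dx, cloned], ignore_index=True)
    base_dates = new_admit.to_numpy()[idx] - pd.to_timedelta(base_offset[idx], unit="D")
    extra_labs = pd.DataFrame(
        {
            "patient_id": np.repeat(pid, 2),
            "draw_date": np.concatenate([base_dates, new_admit.to_numpy()[idx]]),
            "analyte": "creatinine",
            "value": np.round(np.concatenate([baseline[idx], peak[idx]]), 1),
            "units": "umol/L",
            "setting": np.repeat(["outpatient", "inpatient"], len(idx)),
            "admission_id": np.concatenate([np.full(len(idx), ""), new_aid]),
        }
    )
    pop.labs = pd.concat([pop.labs, extra_labs], ignore_index=True)


def generate_population(
    params: SimulationParams = SimulationParams(), seed: Optional[int] = None
) -> Population:
    """Sample a full synthetic dataset from the configured distributions.

    Equal seeds give byte-identical tables. The returned tables are wholly
    eligible by construction: the eligibility filter drops nothing, every
    admission stages exactly to its latent stage, and code flags match the
    planted diagnosis rows.
    """
    use_seed = params.seed if seed is None else seed
    rng = np.random.default_rng(use_seed)
    n = params.n_patients

    stage = rng.choice(4, size=n, p=np.asarray(params.stage_prevalence))
    baseline = _draw_baselines(n, stage, params, rng)
    peak = sample_peak_for_stage(baseline, stage, rng, params.boundary_margin)

    # nested coupling: any >= admission >= main, preserving each algorithm's
    # stage-conditional marginal
    prof = params.code_profile
    p_any = np.asarray(prof.any_diagnosis)[stage]
    p_adm = np.asarray(prof.admission_diagnosis)[stage]
    p_main = np.asarray(prof.main_diagnosis)[stage]
    with np.errstate(divide="ignore", invalid="ignore"):
        adm_given_any = np.where(p_any > 0, p_adm / p_any, 0.0)
        main_given_adm = np.where(p_adm > 0, p_main / p_adm, 0.0)
    any_pos = rng.random(n) < p_any
    adm_pos = any_pos & (rng.random(n) < adm_given_any)
    main_pos = adm_pos & (rng.random(n) < main_given_adm)

    return _assemble(stage, any_pos, adm_pos, main_pos, baseline, peak, params, rng, use_seed)


@dataclass(frozen=True)
class PlantSpec:
    """Exact joint counts to plant: patients per (stage, code pattern).

    ``stage_counts`` gives the cohort split over AKIN stages 0-3;
    ``positives[alg][s]`` the number of code-positive patients at stage s
    under each algorithm. Positivity must be nested (main <= admission <=
    any <= stage count) at every stage so the patterns are realisable.
    """

    stage_counts: Tuple[int, int, int, int]
    positives: Mapping[str, Tuple[int, int, int, int]]

    def __post_init__(self):
        if len(self.stage_counts) != 4 or any(c < 0 for c in self.stage_counts):
            raise InconsistentCountsError("stage_counts must be four nonnegative integers")
        pos = {k: tuple(v) for k, v in self.positives.items()}
        if set(pos) != set(ALGORITHMS):
            raise InconsistentCountsError(f"positives must cover {ALGORITHMS}")
        for s in range(4):
            a, d, m = (pos[k][s] for k in ALGORITHMS)
            if not 0 <= m <= d <= a <= self.stage_counts[s]:
                raise InconsistentCountsError(
                    f"stage {s}: need 0 <= main ({m}) <= admission ({d}) <= any ({a}) "
                    f"<= stage count ({self.stage_counts[s]})"
                )
        object.__setattr__(self, "positives", pos)

    @property
    def n_total(self) -> int:
        return int(sum(self.stage_counts))

    def expected_table(self, algorithm: str, reference: str) -> TwoByTwo:
        """The 2x2 the pipeline must reproduce for this pair."""
        ref_mask = {"stage_ge1": (0, 1, 1, 1), "stage_ge2": (0, 0, 1, 1), "stage_eq3": (0, 0, 0, 1)}[reference]
        pos = self.positives[algorithm]
        tp = sum(p for p, m in zip(pos, ref_mask) if m)
        fp = sum(p for p, m in zip(pos, ref_mask) if not m)
        refpos = sum(c for c, m in zip(self.stage_counts, ref_mask) if m)
        return TwoByTwo(tp, fp, refpos - tp, self.n_total - refpos - fp)


def plant_exact_dataset(
    spec: PlantSpec,
    params: Optional[SimulationParams] = None,
    seed: Optional[int] = None,
) -> Population:
    """Deterministically realise a :class:`PlantSpec` as a full dataset.

    Stage labels and code patterns are assigned by exact count; creatinine
    values and dates are drawn with the seeded generator, so equal seeds
    give byte-identical tables while the pipeline's 2x2 counts are exact for
    every (algorithm, reference) pair regardless of seed.
    """
    if params is None:
        params = SimulationParams(n_patients=spec.n_total)
    use_seed = params.seed if seed is None else seed
    rng = np.random.default_rng(use_seed)

    stage = np.repeat(np.arange(4), spec.stage_counts)
    n = len(stage)
    any_pos = np.zeros(n, dtype=bool)
    adm_pos = np.zeros(n, dtype=bool)
    main_pos = np.zeros(n, dtype=bool)
    start = 0
    for s, count in enumerate(spec.stage_counts):
        a, d, m = (spec.positives[k][s] for k in ALGORITHMS)
        any_pos[start : start + a] = True
        adm_pos[start : start + d] = True
        main_pos[start : start + m] = True
        start += count

    baseline = _draw_baselines(n, stage, params, rng)
    peak = sample_peak_for_stage(baseline, stage, rng, params.boundary_margin)
    return _assemble(stage, any_pos, adm_pos, main_pos, baseline, peak, params, rng, use_seed)


def plant_spec_from_tables(
    tables: Mapping[Tuple[str, str], TwoByTwo],
    stage0_main_positives: int = 2,
) -> PlantSpec:
    """Solve the joint (stage, pattern) counts behind per-pair 2x2 tables.

    ``tables`` maps (algorithm, reference) to target counts; the three
    references of at least one algorithm must be present so the stage split
    is identified. Marginals must agree across pairs (cohort size,
    reference-positive totals, code-positive totals within an algorithm);
    conflicts raise with the offending values listed.

    When an algorithm's stage_ge1 table is absent (as for the suppressed
    main-diagnosis row), its false positives against stage >= 2 are split
    between stages 0 and 1 by ``stage0_main_positives``.
    """
    totals = {pair: t.total for pair, t in tables.items()}
    if len(set(totals.values())) != 1:
        raise InconsistentCountsError(f"cohort sizes disagree across pairs: {totals}")
    n_total = next(iter(totals.values()))

    refpos: Dict[str, int] = {}
    for (alg, ref), t in tables.items():
        prev = refpos.setdefault(ref, t.reference_positive)
        if prev != t.reference_positive:
            raise InconsistentCountsError(
                f"reference-positive totals disagree for {ref}: {prev} vs "
                f"{t.reference_positive} ({alg})"
            )
    missing = {"stage_ge1", "stage_ge2", "stage_eq3"} - set(refpos)
    if missing:
        raise InconsistentCountsError(f"need all three references; missing {sorted(missing)}")
    n3 = refpos["stage_eq3"]
    n2 = refpos["stage_ge2"] - n3
    n1 = refpos["stage_ge1"] - refpos["stage_ge2"]
    n0 = n_total - refpos["stage_ge1"]
    if min(n0, n1, n2, n3) < 0:
        raise InconsistentCountsError(
            f"reference marginals are not monotone: {refpos} in cohort of {n_total}"
        )

    positives = {}
    for alg in ALGORITHMS:
        pairs = {ref: tables.get((alg, ref)) for ref in ("stage_ge1", "stage_ge2", "stage_eq3")}
        if pairs["stage_ge2"] is None or pairs["stage_eq3"] is None:
            raise InconsistentCountsError(f"{alg}: need at least stage_ge2 and stage_eq3 tables")
        codepos = {ref: t.code_positive for ref, t in pairs.items() if t is not None}
        if len(set(codepos.values())) != 1:
            raise InconsistentCountsError(
                f"{alg}: code-positive totals disagree across references: {codepos}"
            )
        k3 = pairs["stage_eq3"].tp
        k2 = pairs["stage_ge2"].tp - k3
        if pairs["stage_ge1"] is not None:
            k1 = pairs["stage_ge1"].tp - pairs["stage_ge2"].tp
            k0 = pairs["stage_ge1"].fp
        else:
            k0 = stage0_main_positives
            k1 = pairs["stage_ge2"].fp - k0
        if min(k0, k1, k2, k3) < 0:
            raise InconsistentCountsError(
                f"{alg}: true-positive counts are not monotone across references"
            )
        positives[alg] = (k0, k1, k2, k3)

    return PlantSpec(stage_counts=(n0, n1, n2, n3), positives=positives)


def study_plant_spec(stage0_main_positives: int = 2) -> PlantSpec:
    """The canonical planted cohort: exact counts behind the published rows.

    Reconstructs each unsuppressed printed row's 2x2 table and solves the
    joint allocation. The suppressed main-diagnosis/stage>=1 pair leaves one
    free integer — how its 12 false positives split between stages 0 and
    1 — defaulting to 2 at stage 0, a choice that makes the reconstructed
    pair itself carry a small cell and hence render as suppressed.
    """
    from .oracle import published_rows, reconstruct_counts

    tables = {
        (row.algorithm, row.reference): reconstruct_counts(row) for row in published_rows()
    }
    return plant_spec_from_tables(tables, stage0_main_positives)
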