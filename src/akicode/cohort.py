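"""Cohort construction for the transplant AKI code-validation analysis.

Five eligibility rules define an analysable admission:

(a) the patient's first transplant is a first, kidney-only graft;
(b) the admission begins at least six months after that transplant, so that
    delayed graft function, surgical complications and early rejection do
    not masquerade as AKI;
(c) at least one serum creatinine was drawn during the stay;
(d) the admission lies inside the study window — admitted on or after the
    study start and discharged before the end of laboratory data capture;
(e) a baseline creatinine exists 2 weeks to 6 months before admission.

Patients may qualify with several admissions; exactly one index admission
per patient is then drawn at random to avoid within-patient clustering in
the accuracy estimates.
"""

from __future__ import annotations

import datetime as _dt
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .codes import canonicalize_code
from .errors import DataIntegrityError
from .rounding import round_half_up
from .staging import BaselineWindow

__all__ = [
    "EligibilityConfig",
    "filter_eligible",
    "select_index_admission",
    "flag_comorbidities",
    "egfr_ckd_epi",
    "summarize_cohort",
    "CohortSummary",
]

RULE_NAMES = (
    "a_first_kidney_only_transplant",
    "b_admitted_6mo_post_transplant",
    "c_inpatient_creatinine",
    "d_within_study_window",
    "e_baseline_creatinine",
)


@dataclass(frozen=True)
class EligibilityConfig:
    """Windows and dates governing cohort eligibility.

    Defaults encode the original study conditions: six months = 183 days,
    study entry from 2003-04-01 (start of ICD-10 coding in the source
    region) and laboratory capture through the end of 2012.
    """

    post_transplant_min_days: int = 183
    baseline_window: BaselineWindow = field(default_factory=BaselineWindow)
    study_start: _dt.date = _dt.date(2003, 4, 1)
    lab_end_date: _dt.date = _dt.date(2012, 12, 31)
    seed: int = 0

    def __post_init__(self):
        if self.post_transplant_min_days <= 0:
            raise ValueError("post_transplant_min_days must be positive")
        if self.lab_end_date <= self.study_start:
            raise ValueError("lab_end_date must fall after study_start")


def filter_eligible(
    patients: pd.DataFrame,
    transplants: pd.DataFrame,
    admissions: pd.DataFrame,
    labs: pd.DataFrame,
    config: EligibilityConfig = EligibilityConfig(),
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Apply the five eligibility rules as a sequential cascade.

    Returns ``(eligible, exclusions)`` where ``eligible`` has one row per
    surviving admission (``patient_id``, ``admission_id``, ``admit_date``,
    ``discharge_date``) and ``exclusions`` counts admissions removed at each
    rule, in cascade order (an admission failing several rules is counted at
    the first). ``exclusions["input_admissions"]`` minus the per-rule counts
    equals the number of eligible admissions (conservation).
    """
    adm = admissions.copy()
    adm["admit_date"] = pd.to_datetime(adm["admit_date"])
    adm["discharge_date"] = pd.to_datetime(adm["discharge_date"])
    if (adm["admit_date"] > adm["discharge_date"]).any():
        raise DataIntegrityError("admission with admit_date after discharge_date")

    unknown = set(adm["patient_id"]) - set(patients["patient_id"])
    if unknown:
        raise DataIntegrityError(
            f"admissions reference unknown patients: {sorted(unknown)[:5]}"
        )

    exclusions: Dict[str, int] = {"input_admissions": len(adm)}

    # (a) first transplant is kidney-only graft number 1
    tx = transplants.copy()
    tx["transplant_date"] = pd.to_datetime(tx["transplant_date"])
    first = tx.sort_values(["patient_id", "transplant_date", "graft_number"]).groupby(
        "patient_id", as_index=False
    ).first()
    ok_patients = first.loc[
        (first["organ"] == "kidney") & (first["graft_number"] == 1),
        ["patient_id", "transplant_date"],
    ]
    merged = adm.merge(ok_patients, on="patient_id", how="left")
    keep = merged["transplant_date"].notna()
    exclusions[RULE_NAMES[0]] = int((~keep).sum())
    merged = merged[keep]

    # (b) admitted >= post_transplant_min_days after transplant
    keep = (
        merged["admit_date"] - merged["transplant_date"]
    ).dt.days >= config.post_transplant_min_days
    exclusions[RULE_NAMES[1]] = int((~keep).sum())
    merged = merged[keep]

    # creatinine draw dates per patient, shared by rules (c) and (e)
    scr = labs
    if "analyte" in scr.columns:
        scr = scr[scr["analyte"] == "creatinine"]
    scr = scr[["patient_id", "draw_date"]].copy()
    scr["draw_date"] = pd.to_datetime(scr["draw_date"])

    lab_join = merged[["admission_id", "patient_id", "admit_date", "discharge_date"]].merge(
        scr, on="patient_id", how="left"
    )

    # (c) at least one creatinine during the stay
    during = (
        (lab_join["draw_date"] >= lab_join["admit_date"])
        & (lab_join["draw_date"] <= lab_join["discharge_date"])
    )
    has_inpatient = lab_join.loc[during, "admission_id"].unique()
    keep = merged["admission_id"].isin(has_inpatient)
    exclusions[RULE_NAMES[2]] = int((~keep).sum())
    merged = merged[keep]

    # (d) study window: admitted on/after study start, discharged before lab end
    keep = (merged["admit_date"] >= pd.Timestamp(config.study_start)) & (
        merged["discharge_date"] < pd.Timestamp(config.lab_end_date)
    )
    exclusions[RULE_NAMES[3]] = int((~keep).sum())
    merged = merged[keep]

    # (e) baseline creatinine in the pre-admission window
    offset = (lab_join["admit_date"] - lab_join["draw_date"]).dt.days
    w = config.baseline_window
    in_window = (offset >= w.min_offset_days) & (offset <= w.max_offset_days)
    has_baseline = lab_join.loc[in_window, "admission_id"].unique()
    keep = merged["admission_id"].isin(has_baseline)
    exclusions[RULE_NAMES[4]] = int((~keep).sum())
    merged = merged[keep]

    eligible = merged[
        ["patient_id", "admission_id", "admit_date", "discharge_date"]
    ].reset_index(drop=True)
    exclusions["eligible_admissions"] = len(eligible)
    exclusions["eligible_patients"] = int(eligible["patient_id"].nunique())
    return eligible, exclusions


def select_index_admission(
    eligible: pd.DataFrame, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Draw one index admission per patient, uniformly at random.

    Deterministic for a fixed seed. Ordering of the input does not matter:
    candidates are sorted by (patient_id, admission_id) before drawing.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ordered = eligible.sort_values(["patient_id", "admission_id"]).reset_index(drop=True)
    sizes = ordered.groupby("patient_id", sort=True).size()
    picks = rng.integers(0, sizes.to_numpy())
    starts = np.concatenate([[0], np.cumsum(sizes.to_numpy())[:-1]])
    return ordered.iloc[starts + picks].reset_index(drop=True)


def flag_comorbidities(
    index_cases: pd.DataFrame,
    admissions: pd.DataFrame,
    diagnoses: pd.DataFrame,
    code_lists: Mapping[str, Sequence[str]],
    lookback_days: int = 1095,
) -> pd.DataFrame:
    """Prefix-match comorbidity codes in a 3-year lookback before the index.

    A flag is true when any diagnosis on an admission admitted within
    ``lookback_days`` before the index admission (the index admission itself
    excluded) matches one of that comorbidity's code prefixes. Code lists
    are caller-supplied; validated lists vary by jurisdiction and era, so
    none are baked in.
    """
    flags = pd.DataFrame({"patient_id": index_cases["patient_id"]}).set_index("patient_id")
    adm = admissions[["admission_id", "patient_id", "admit_date"]].copy()
    adm["admit_date"] = pd.to_datetime(adm["admit_date"])
    idx = index_cases[["patient_id", "admission_id", "admit_date"]].rename(
        columns={"admission_id": "index_admission", "admit_date": "index_date"}
    )
    idx["index_date"] = pd.to_datetime(idx["index_date"])
    hist = adm.merge(idx, on="patient_id")
    back = (hist["index_date"] - hist["admit_date"]).dt.days
    hist = hist[
        (back >= 0) & (back <= lookback_days) & (hist["admission_id"] != hist["index_admission"])
    ]
    dx = diagnoses.merge(hist[["admission_id", "patient_id"]], on="admission_id")
    codes = dx["code"].map(canonicalize_code)
    for name, prefixes in code_lists.items():
        if not prefixes:
            warnings.warn(f"empty code list for comorbidity {name!r}", stacklevel=2)
            flags[name] = False
            continue
        canon = tuple(canonicalize_code(p) for p in prefixes)
        hit = codes.str.startswith(canon)
        positive = set(dx.loc[hit, "patient_id"])
        flags[name] = flags.index.isin(positive)
    return flags.reset_index()


# CKD-EPI 2009 creatinine equation constants
_UMOL_PER_MGDL = 88.4
_KAPPA = {"F": 0.7, "M": 0.9}
_ALPHA = {"F": -0.329, "M": -0.411}
_SEX_FACTOR = {"F": 1.018, "M": 1.0}
_BLACK_FACTOR = 1.159


def egfr_ckd_epi(scr_umol, age_years, sex, black: bool = False):
    """Estimated GFR (mL/min/1.73 m^2) by the 2009 CKD-EPI equation.

    eGFR = 141 * min(Scr/k, 1)^alpha * max(Scr/k, 1)^-1.209 * 0.993^age
           * 1.018 [female] (* 1.159 with ``black=True``)

    with Scr in mg/dL (converted from umol/L at 88.4), k = 0.7 (F) / 0.9 (M)
    and alpha = -0.329 (F) / -0.411 (M). The race coefficient is omitted by
    default, matching current nephrology practice. Vectorised over inputs.
    """
    scr = np.asarray(scr_umol, dtype=float)
    age = np.asarray(age_years, dtype=float)
    if np.any(scr <= 0):
        raise ValueError("serum creatinine must be positive")
    sex_arr = np.asarray(sex)
    if sex_arr.ndim == 0:
        sex_arr = np.full(scr.shape if scr.ndim else (1,), sex_arr)
        scr = np.atleast_1d(scr)
        age = np.atleast_1d(age)
    valid = np.isin(sex_arr, ("F", "M"))
    if not valid.all():
        raise ValueError(f"sex must be 'F' or 'M', got {np.unique(sex_arr[~valid])}")
    kappa = np.where(sex_arr == "F", _KAPPA["F"], _KAPPA["M"])
    alpha = np.where(sex_arr == "F", _ALPHA["F"], _ALPHA["M"])
    factor = np.where(sex_arr == "F", _SEX_FACTOR["F"], _SEX_FACTOR["M"])
    ratio = (scr / _UMOL_PER_MGDL) / kappa
    egfr = (
        141.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.209
        * 0.993 ** age
        * factor
    )
    if black:
        egfr = egfr * _BLACK_FACTOR
    if np.isscalar(scr_umol) and np.isscalar(age_years):
        return float(egfr[0] if egfr.ndim else egfr)
    return egfr


_EGFR_BANDS = ((0, 15), (15, 30), (30, 45), (45, 60), (60, math.inf))


@dataclass
class CohortSummary:
    """Descriptive summary of the index cohort.

    ``table`` is a long-format frame (section, label, n, percent, value);
    ``key_facts`` repeats the analytically central rates as plain floats,
    percentages rounded half-up to one decimal.
    """

    table: pd.DataFrame
    key_facts: Dict[str, float]

    def __str__(self) -> str:  # pragma: no cover - convenience rendering
        lines = ["Cohort summary", ""]
        for _, r in self.table.iterrows():
            if not math.isnan(r["percent"]):
                lines.append(f"{r['section']:>22} | {r['label']:<24} {r['n']:>5.0f} ({r['percent']:.1f})")
            else:
                lines.append(f"{r['section']:>22} | {r['label']:<24} {r['value']}")
        return "\n".join(lines)


def summarize_cohort(
    assessments: pd.DataFrame,
    code_flags: pd.DataFrame,
    patients: Optional[pd.DataFrame] = None,
) -> CohortSummary:
    """Baseline-characteristics summary of the index cohort.

    Covers sex, age (mean, SD), baseline creatinine and eGFR (median, IQR,
    eGFR bands) when ``patients`` is supplied, and always the AKIN stage
    distribution and per-algorithm code-positive rates. SD is NaN-flagged
    for a single-patient cohort.
    """
    if assessments.empty:
        raise ValueError("cohort is empty")
    n = len(assessments)
    rows = []

    def add(section, label, count=None, value=None):
        pct = math.nan if count is None else round_half_up(100.0 * count / n)
        rows.append(
            {
                "section": section,
                "label": label,
                "n": math.nan if count is None else count,
                "percent": pct,
                "value": value,
            }
        )

    add("cohort", "index cases", n, None)

    if patients is not None:
        merged = assessments.merge(patients, on="patient_id")
        sex = merged["sex"]
        add("demographics", "women", int((sex == "F").sum()))
        age = (
            pd.to_datetime(merged["admit_date"]) - pd.to_datetime(merged["birth_date"])
        ).dt.days / 365.25
        sd = float(age.std(ddof=1)) if n > 1 else math.nan
        add("demographics", "age mean (SD), years", value=(float(age.mean()), sd))
        scr = merged["baseline"]
        add(
            "labs",
            "baseline creatinine median (IQR), umol/L",
            value=tuple(float(q) for q in np.percentile(scr, [50, 25, 75])),
        )
        egfr = egfr_ckd_epi(scr.to_numpy(), age.to_numpy(), sex.to_numpy())
        add(
            "labs",
            "eGFR median (IQR), mL/min/1.73m2",
            value=tuple(float(q) for q in np.percentile(egfr, [50, 25, 75])),
        )
        for lo, hi in _EGFR_BANDS:
            label = f"eGFR >={lo}" if math.isinf(hi) else f"eGFR {lo} to <{hi}"
            add("labs", label, int(((egfr >= lo) & (egfr < hi)).sum()))

    stages = assessments["stage"].to_numpy()
    n_aki = int((stages >= 1).sum())
    add("aki", "any AKI", n_aki)
    for s in (1, 2, 3):
        add("aki", f"AKIN stage {s}", int((stages == s).sum()))

    merged_flags = assessments[["patient_id"]].merge(code_flags, on="patient_id")
    for algorithm in ("any_diagnosis", "admission_diagnosis", "main_diagnosis"):
        if algorithm in merged_flags.columns:
            add("coding", f"N17x positive ({algorithm})", int(merged_flags[algorithm].sum()))

    key = {
        "n": n,
        "any_aki_pct": round_half_up(100.0 * n_aki / n),
        "stage1_pct": round_half_up(100.0 * (stages == 1).sum() / n),
        "stage2_pct": round_half_up(100.0 * (stages == 2).sum() / n),
        "stage3_pct": round_half_up(100.0 * (stages == 3).sum() / n),
        "stage1_share_of_aki_pct": (
            round_half_up(100.0 * (stages == 1).sum() / n_aki) if n_aki else math.nan
        ),
    }
    if "any_diagnosis" in merged_flags.columns:
        key["code_positive_pct"] = round_half_up(
            100.0 * merged_flags["any_diagnosis"].sum() / n
        )
    return CohortSummary(table=pd.DataFrame(rows), key_facts=key)
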