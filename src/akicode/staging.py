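"""Creatinine-based AKIN staging of acute kidney injury.

The reference standard for the code-validation analysis is the Acute Kidney
Injury Network (AKIN) classification restricted to its serum-creatinine
criteria, comparing the peak in-hospital creatinine against a pre-admission
baseline:

* stage 1 — rise >= 26.4 umol/L (0.3 mg/dL) *or* a 1.5- to 2-fold increase
  from baseline;
* stage 2 — a >2- to 3-fold increase from baseline;
* stage 3 — a >3-fold increase, or peak creatinine > 354 umol/L together
  with an acute rise of at least 44 umol/L (0.5 mg/dL).

"x-fold increase" is read as the ratio peak/baseline reaching x (AKIN's
"increase to 150-200 %"), so a ratio of exactly 2 is stage 1 and exactly 3 is
stage 2. The urine-output criterion and the 48-hour timing window of the full
AKIN definition are deliberately not modelled: admission-level administrative
data carry neither urine volumes nor reliable intra-admission timing, and the
validation this package reproduces used the same creatinine-only adaptation.

The baseline is the most recent creatinine drawn 2 weeks to 6 months before
admission; draws closer than 2 weeks are disallowed because they may already
reflect the incipient injury rather than a stable baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .errors import DataIntegrityError

__all__ = [
    "STAGE1_DELTA",
    "STAGE1_RATIO",
    "STAGE2_RATIO",
    "STAGE3_RATIO",
    "STAGE3_PEAK",
    "STAGE3_DELTA",
    "BaselineWindow",
    "AkinAssessment",
    "akin_stage",
    "select_baseline",
    "peak_creatinine",
    "assess",
    "assess_cohort",
]

# AKIN serum-creatinine thresholds, all in umol/L except the ratios.
STAGE1_DELTA = 26.4  # absolute rise for stage 1 (0.3 mg/dL)
STAGE1_RATIO = 1.5
STAGE2_RATIO = 2.0
STAGE3_RATIO = 3.0
STAGE3_PEAK = 354.0  # absolute-peak clause of stage 3
STAGE3_DELTA = 44.0  # acute rise required with the absolute-peak clause


@dataclass(frozen=True)
class BaselineWindow:
    """Window for baseline creatinine, as day offsets before admission.

    The default [14, 183] encodes "2 weeks to 6 months prior", inclusive at
    both ends and with months counted as 183/6 = 30.5 days.
    """

    min_offset_days: int = 14
    max_offset_days: int = 183

    def __post_init__(self):
        if not 0 < self.min_offset_days < self.max_offset_days:
            raise ValueError(
                "baseline window requires 0 < min_offset < max_offset, got "
                f"[{self.min_offset_days}, {self.max_offset_days}]"
            )


@dataclass(frozen=True)
class AkinAssessment:
    """Baseline/peak creatinine pair with derived changes and AKIN stage."""

    baseline: float
    baseline_date: pd.Timestamp
    peak: float
    peak_date: pd.Timestamp
    absolute_change: float
    relative_change_pct: float
    stage: int


def akin_stage(baseline, peak):
    """Assign the creatinine-only AKIN stage (0-3).

    Parameters
    ----------
    baseline, peak
        Serum creatinine in umol/L; scalars or equal-length array-likes.
        Both must be strictly positive.

    Returns
    -------
    int or ndarray of int
        0 for no AKI, otherwise the AKIN stage.

    Notes
    -----
    Boundary handling: a rise of exactly 26.4 or a ratio of exactly 1.5
    meets stage 1 (">=" in the definition); ratios of exactly 2 and 3 stay in
    the lower stage ("1.5- to 2-fold", ">2- to 3-fold"); a peak of exactly
    354 fails the ">354" clause while a rise of exactly 44 meets "at least
    44".
    """
    b = np.asarray(baseline, dtype=float)
    p = np.asarray(peak, dtype=float)
    if np.any(~np.isfinite(b)) or np.any(~np.isfinite(p)):
        raise ValueError("creatinine values must be finite")
    if np.any(b <= 0) or np.any(p <= 0):
        raise ValueError("creatinine values must be positive")
    ratio = p / b
    delta = p - b
    stage3 = (ratio > STAGE3_RATIO) | ((p > STAGE3_PEAK) & (delta >= STAGE3_DELTA))
    stage2 = ratio > STAGE2_RATIO
    stage1 = (delta >= STAGE1_DELTA) | (ratio >= STAGE1_RATIO)
    out = np.select([stage3, stage2, stage1], [3, 2, 1], default=0)
    if np.isscalar(baseline) and np.isscalar(peak):
        return int(out)
    return out


def select_baseline(
    labs: pd.DataFrame,
    admit_date,
    window: BaselineWindow = BaselineWindow(),
) -> Optional[Tuple[float, pd.Timestamp]]:
    """Pick the baseline creatinine for one admission.

    Among draws dated ``admit_date - max_offset`` to ``admit_date -
    min_offset`` (inclusive), the most recent is used; if several values share
    that date they are averaged. Returns ``None`` when the window is empty —
    such admissions are excluded upstream, absence is not an error.

    ``labs`` needs columns ``draw_date`` and ``value``.
    """
    admit = pd.Timestamp(admit_date)
    dates = pd.to_datetime(labs["draw_date"])
    offset = (admit - dates).dt.days
    in_window = (offset >= window.min_offset_days) & (offset <= window.max_offset_days)
    if not in_window.any():
        return None
    eligible = labs.loc[in_window]
    latest = pd.to_datetime(eligible["draw_date"]).max()
    on_day = eligible.loc[pd.to_datetime(eligible["draw_date"]) == latest, "value"]
    return float(on_day.mean()), latest


def peak_creatinine(
    labs: pd.DataFrame, admit_date, discharge_date
) -> Tuple[float, pd.Timestamp]:
    """Maximum creatinine drawn during the stay; ties go to the earliest date.

    Requires at least one draw dated within [admit_date, discharge_date];
    admissions without one fail cohort rule (c) and never reach this point.
    """
    admit, discharge = pd.Timestamp(admit_date), pd.Timestamp(discharge_date)
    dates = pd.to_datetime(labs["draw_date"])
    during = labs.loc[(dates >= admit) & (dates <= discharge)]
    if during.empty:
        raise DataIntegrityError(
            f"no in-admission creatinine between {admit.date()} and {discharge.date()}"
        )
    peak_value = during["value"].max()
    peak_date = pd.to_datetime(
        during.loc[during["value"] == peak_value, "draw_date"]
    ).min()
    return float(peak_value), peak_date


def assess(
    admission, labs: pd.DataFrame, window: BaselineWindow = BaselineWindow()
) -> AkinAssessment:
    """Full AKIN assessment of a single index admission.

    ``admission`` is any mapping with ``admit_date`` and ``discharge_date``;
    ``labs`` holds that patient's creatinine draws. The relative change is
    100 * (peak - baseline) / baseline.
    """
    base = select_baseline(labs, admission["admit_date"], window)
    if base is None:
        raise DataIntegrityError(
            f"admission {admission.get('admission_id', '?')}: no baseline creatinine "
            f"in the [{window.min_offset_days}, {window.max_offset_days}]-day window"
        )
    baseline, baseline_date = base
    peak, peak_date = peak_creatinine(
        labs, admission["admit_date"], admission["discharge_date"]
    )
    return AkinAssessment(
        baseline=baseline,
        baseline_date=baseline_date,
        peak=peak,
        peak_date=peak_date,
        absolute_change=peak - baseline,
        relative_change_pct=100.0 * (peak - baseline) / baseline,
        stage=akin_stage(baseline, peak),
    )


def assess_cohort(
    index_admissions: pd.DataFrame,
    labs: pd.DataFrame,
    window: BaselineWindow = BaselineWindow(),
) -> pd.DataFrame:
    """Vectorised AKIN assessment of every index admission.

    Parameters
    ----------
    index_admissions
        One row per index case with ``patient_id``, ``admission_id``,
        ``admit_date``, ``discharge_date``.
    labs
        Creatinine measurements with ``patient_id``, ``draw_date``, ``value``
        (rows for other analytes may be present if an ``analyte`` column
        identifies them and are ignored).

    Returns
    -------
    DataFrame with one row per admission: baseline, baseline_date, peak,
    peak_date, abs_change, rel_change_pct, stage.

    Raises
    ------
    DataIntegrityError
        Naming the admissions that lack a baseline or an in-admission value.
    """
    idx = index_admissions[
        ["patient_id", "admission_id", "admit_date", "discharge_date"]
    ].copy()
    idx["admit_date"] = pd.to_datetime(idx["admit_date"])
    idx["discharge_date"] = pd.to_datetime(idx["discharge_date"])

    scr = labs
    if "analyte" in scr.columns:
        scr = scr[scr["analyte"] == "creatinine"]
    scr = scr[["patient_id", "draw_date", "value"]].copy()
    scr["draw_date"] = pd.to_datetime(scr["draw_date"])

    merged = scr.merge(idx, on="patient_id", how="inner")
    offset = (merged["admit_date"] - merged["draw_date"]).dt.days

    base = merged[
        (offset >= window.min_offset_days) & (offset <= window.max_offset_days)
    ]
    latest = base.groupby("admission_id")["draw_date"].transform("max")
    base = base[base["draw_date"] == latest]
    baselines = base.groupby("admission_id").agg(
        baseline=("value", "mean"), baseline_date=("draw_date", "first")
    )

    inpatient = merged[
        (merged["draw_date"] >= merged["admit_date"])
        & (merged["draw_date"] <= merged["discharge_date"])
    ]
    inpatient = inpatient.sort_values(
        ["admission_id", "value", "draw_date"], ascending=[True, False, True]
    )
    peaks = inpatient.groupby("admission_id").first()[["value", "draw_date"]]
    peaks.columns = ["peak", "peak_date"]

    out = idx.join(baselines, on="admission_id").join(peaks, on="admission_id")
    missing_base = out.loc[out["baseline"].isna(), "admission_id"].tolist()
    missing_peak = out.loc[out["peak"].isna(), "admission_id"].tolist()
    if missing_base or missing_peak:
        raise DataIntegrityError(
            f"missing baseline for admissions {missing_base[:5]}; "
            f"missing in-admission creatinine for {missing_peak[:5]}"
        )
    out["abs_change"] = out["peak"] - out["baseline"]
    out["rel_change_pct"] = 100.0 * out["abs_change"] / out["baseline"]
    out["stage"] = akin_stage(out["baseline"].to_numpy(), out["peak"].to_numpy())
    return out.reset_index(drop=True)
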