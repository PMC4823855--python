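"""Diagnostic accuracy of a coding algorithm against a staging reference.

For each (reference standard, coding algorithm) pair the cohort collapses to
a 2x2 table

====================  ============  ============
                      reference +   reference -
====================  ============  ============
code +                TP            FP
code -                FN            TN
====================  ============  ============

from which sensitivity TP/(TP+FN), specificity TN/(TN+FP), positive
predictive value TP/(TP+FP) and negative predictive value TN/(TN+FN) follow,
each a binomial proportion whose 95 % confidence interval is computed with
the Wilson score method (well behaved near 0 and 1, unlike the Wald
interval). The positive likelihood ratio is Sn/(1-Sp).

Reference standards are creatinine-based AKIN stage thresholds: any AKI
(stage >= 1), moderate-severe (stage >= 2), and severe (stage 3).

Privacy suppression: tables derived from administrative health data may not
be released when any cell is a small nonzero count; the default threshold
marks counts 1-5 as small, matching the convention of Canadian data
custodians. Suppression is all-or-nothing — a suppressed table reports no
derived metrics at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .codes import ALGORITHMS
from .errors import DataIntegrityError
from .rounding import paper_round, round_half_up

__all__ = [
    "TwoByTwo",
    "MetricWithCI",
    "ReferenceStandard",
    "REFERENCE_STANDARDS",
    "wilson_interval",
    "proportion_with_ci",
    "performance",
    "positive_lr",
    "negative_lr",
    "apply_suppression",
    "build_two_by_two",
    "performance_report",
    "render_performance_text",
]


@dataclass(frozen=True)
class TwoByTwo:
    """Integer 2x2 counts for one (reference standard, algorithm) pair."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def reference_positive(self) -> int:
        return self.tp + self.fn

    @property
    def code_positive(self) -> int:
        return self.tp + self.fp

    def as_tuple(self):
        return (self.tp, self.fp, self.fn, self.tn)


@dataclass(frozen=True)
class MetricWithCI:
    """A binomial proportion with its Wilson interval.

    ``estimate`` and the bounds are proportions in [0, 1]; ``defined`` is
    False when the denominator is zero (the value carries NaNs then).
    """

    k: int
    n: int
    estimate: float
    ci_low: float
    ci_high: float

    @property
    def defined(self) -> bool:
        return self.n > 0

    def as_percent(self, rounder: Callable[[float], float] = paper_round):
        """(estimate, low, high) on the 0-100 scale, rounded for reporting."""
        if not self.defined:
            return (math.nan, math.nan, math.nan)
        return tuple(rounder(100.0 * v) for v in (self.estimate, self.ci_low, self.ci_high))


@dataclass(frozen=True)
class ReferenceStandard:
    """A predicate over the AKIN stage defining reference positivity."""

    name: str
    predicate: Callable[[np.ndarray], np.ndarray]
    label: str


REFERENCE_STANDARDS: Dict[str, ReferenceStandard] = {
    "stage_ge1": ReferenceStandard("stage_ge1", lambda s: s >= 1, "AKIN stage 1 or greater"),
    "stage_ge2": ReferenceStandard("stage_ge2", lambda s: s >= 2, "AKIN stage 2 or greater"),
    "stage_eq3": ReferenceStandard("stage_eq3", lambda s: s == 3, "AKIN stage 3"),
}


def wilson_interval(k: int, n: int, conf: float = 0.95):
    """Wilson score interval for a binomial proportion.

    Solves |p_hat - p| = z * sqrt(p (1 - p) / n) for p in closed form, using
    the exact normal quantile (1.959964... at 95 %). Returns ``(nan, nan)``
    when n = 0 rather than raising: an undefined proportion is a value, not
    an error. Bounds are clipped to [0, 1].
    """
    if n == 0:
        return (math.nan, math.nan)
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    z = norm.ppf(0.5 + conf / 2.0)
    p = k / n
    z2n = z * z / n
    centre = (p + z2n / 2.0) / (1.0 + z2n)
    half = z * math.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n)) / (1.0 + z2n)
    return (max(0.0, centre - half), min(1.0, centre + half))


def proportion_with_ci(k: int, n: int, conf: float = 0.95) -> MetricWithCI:
    """Package k/n with its Wilson interval; NaN-valued when n = 0."""
    if n == 0:
        return MetricWithCI(0, 0, math.nan, math.nan, math.nan)
    low, high = wilson_interval(k, n, conf)
    return MetricWithCI(int(k), int(n), k / n, low, high)


def performance(t: TwoByTwo, conf: float = 0.95) -> Dict[str, MetricWithCI]:
    """Sensitivity, specificity, PPV and NPV of a 2x2 table, with CIs."""
    return {
        "sn": proportion_with_ci(t.tp, t.tp + t.fn, conf),
        "sp": proportion_with_ci(t.tn, t.tn + t.fp, conf),
        "ppv": proportion_with_ci(t.tp, t.tp + t.fp, conf),
        "npv": proportion_with_ci(t.tn, t.tn + t.fn, conf),
    }


def positive_lr(sn: float, sp: float, mode: str = "exact") -> float:
    """Positive likelihood ratio Sn/(1-Sp) from proportions in [0, 1].

    ``mode="exact"`` uses the unrounded proportions. ``mode="paper_rounded"``
    first rounds Sn and Sp to one-decimal percentages (the precision at which
    reports print them) and rounds the ratio to one decimal — the convention
    that reproduces published report tables, where e.g. Sn 27.97 %, Sp
    97.22 % print LR+ 28.0/2.8 = 10.0 while the unrounded ratio is 10.07.
    Returns ``inf`` when Sp = 1 (no false positives).
    """
    if mode not in ("exact", "paper_rounded"):
        raise ValueError(f"mode must be 'exact' or 'paper_rounded', got {mode!r}")
    if mode == "exact":
        if sp >= 1.0:
            return math.inf
        return sn / (1.0 - sp)
    sn_pct = paper_round(100.0 * sn)
    sp_pct = paper_round(100.0 * sp)
    if sp_pct >= 100.0:
        return math.inf
    return round_half_up(sn_pct / (100.0 - sp_pct))


def negative_lr(sn: float, sp: float) -> float:
    """Negative likelihood ratio (1-Sn)/Sp; inf when Sp = 0."""
    if sp <= 0.0:
        return math.inf
    return (1.0 - sn) / sp


def apply_suppression(t: TwoByTwo, threshold: int = 6) -> bool:
    """Small-cell privacy rule: suppress when any cell is in [1, threshold).

    Structural zeros are not disclosive and do not trigger suppression; a
    threshold of 0 disables the rule. When a table is suppressed, no derived
    metric from it may be released either.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return any(1 <= c < threshold for c in t.as_tuple())


def build_two_by_two(
    assessments: pd.DataFrame,
    code_flags: pd.DataFrame,
    reference: ReferenceStandard | str,
    algorithm: str,
) -> TwoByTwo:
    """Cross-classify index cases by staging reference and code flag.

    ``assessments`` has one row per index case with ``patient_id`` and
    ``stage``; ``code_flags`` is indexed by admission_id or carries
    ``patient_id``, with one boolean column per algorithm. The two case sets
    must match exactly.
    """
    if isinstance(reference, str):
        reference = REFERENCE_STANDARDS[reference]
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")

    key = "patient_id" if "patient_id" in code_flags.columns else None
    if key is None:
        flags = code_flags[algorithm].reindex(assessments["admission_id"])
        orphans = flags.index[flags.isna()].tolist()
        if orphans:
            raise DataIntegrityError(f"index cases missing code flags: {orphans[:5]}")
        flag = flags.to_numpy(dtype=bool)
    else:
        merged = assessments.merge(code_flags, on="patient_id", how="left", indicator=True)
        orphans = merged.loc[merged["_merge"] != "both", "patient_id"].tolist()
        if orphans or len(merged) != len(assessments):
            raise DataIntegrityError(f"case sets do not match; orphans: {orphans[:5]}")
        flag = merged[algorithm].to_numpy(dtype=bool)

    ref = np.asarray(reference.predicate(assessments["stage"].to_numpy()), dtype=bool)
    return TwoByTwo(
        tp=int((ref & flag).sum()),
        fp=int((~ref & flag).sum()),
        fn=int((ref & ~flag).sum()),
        tn=int((~ref & ~flag).sum()),
    )


def performance_report(
    assessments: pd.DataFrame,
    code_flags: pd.DataFrame,
    algorithms: Sequence[str] = ALGORITHMS,
    references: Sequence[str] = ("stage_ge1", "stage_ge2", "stage_eq3"),
    suppress_threshold: int = 6,
    lr_mode: str = "paper_rounded",
    conf: float = 0.95,
) -> pd.DataFrame:
    """Full accuracy report: one row per (algorithm, reference) pair.

    Percent-scale columns are rounded with the publication convention
    (half-up through two decimals to one). Suppressed rows keep their counts
    internally but render every derived column as NaN with ``suppressed``
    True, so a renderer can show a suppression marker and nothing else.
    """
    rows = []
    for algorithm in algorithms:
        for ref_name in references:
            t = build_two_by_two(assessments, code_flags, ref_name, algorithm)
            suppressed = apply_suppression(t, suppress_threshold)
            row = {
                "algorithm": algorithm,
                "reference": ref_name,
                "tp": t.tp,
                "fp": t.fp,
                "fn": t.fn,
                "tn": t.tn,
                "suppressed": suppressed,
            }
            metrics = performance(t, conf)
            for name, m in metrics.items():
                pt, lo, hi = (
                    (math.nan,) * 3 if suppressed else m.as_percent(paper_round)
                )
                row[name] = pt
                row[f"{name}_lo"] = lo
                row[f"{name}_hi"] = hi
            if suppressed or not metrics["sn"].defined or not metrics["sp"].defined:
                row["lr_plus"] = math.nan
            else:
                lr = positive_lr(metrics["sn"].estimate, metrics["sp"].estimate, lr_mode)
                row["lr_plus"] = lr if lr_mode == "paper_rounded" else round_half_up(lr)
            rows.append(row)
    return pd.DataFrame(rows)


def render_performance_text(report: pd.DataFrame) -> str:
    """Human-readable accuracy table mirroring the published layout."""
    lines = [
        "Diagnostic performance of ICD-10 N17x coding algorithms",
        "vs creatinine-based AKIN reference standards (95 % CI)",
        "",
    ]
    labels = {r.name: r.label for r in REFERENCE_STANDARDS.values()}
    for algorithm, block in report.groupby("algorithm", sort=False):
        lines.append(algorithm.replace("_", " "))
        for _, row in block.iterrows():
            lines.append(f"  {labels[row['reference']]}")
            if row["suppressed"]:
                lines.append("    -- suppressed (small cells) --")
                continue
            for name, tag in (("sn", "Sn"), ("sp", "Sp"), ("ppv", "PPV"), ("npv", "NPV")):
                lines.append(
                    f"    {tag} = {row[name]:.1f} ({row[f'{name}_lo']:.1f}, {row[f'{name}_hi']:.1f})"
                )
            lines.append(f"    LR+ = {row['lr_plus']:.1f}")
        lines.append("")
    return "\n".join(lines)
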