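"""Reconstruction of latent 2x2 counts from printed accuracy statistics.

Published validation tables print sensitivity, specificity, PPV and NPV as
rounded percentages together with the cohort marginals (total n, number
reference-positive, number code-positive). Because all four statistics are
determined by a single free integer — the true-positive count — the latent
2x2 table can be recovered by brute force: enumerate every feasible TP,
derive FP/FN/TN from the marginals, recompute the four statistics, and keep
the candidates whose rounded values match the printed row. A unique survivor
pins down the exact counts; zero survivors expose an inconsistent row and
multiple survivors an under-determined one.

Matching uses the same rounding convention as the published tables
(half-up through two decimals to one, see :mod:`akicode.rounding`): the
printed value is trusted to the last digit shown and no further.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Dict, List, Optional

from .errors import AmbiguousCountsError, InconsistentCountsError
from .performance import TwoByTwo
from .rounding import paper_round

__all__ = ["PrintedRow", "reconstruct_counts", "published_rows", "published_descriptives"]


@dataclass(frozen=True)
class PrintedRow:
    """One printed accuracy row plus the marginals that frame it.

    ``sn``/``sp``/``ppv``/``npv`` are the printed one-decimal percentages.
    """

    n_total: int
    n_ref_pos: int
    n_code_pos: int
    sn: float
    sp: float
    ppv: float
    npv: float
    algorithm: Optional[str] = None
    reference: Optional[str] = None
    lr_plus: Optional[float] = None

    def __post_init__(self):
        if not (0 <= self.n_ref_pos <= self.n_total):
            raise ValueError("need 0 <= n_ref_pos <= n_total")
        if not (0 <= self.n_code_pos <= self.n_total):
            raise ValueError("need 0 <= n_code_pos <= n_total")


def _candidates(row: PrintedRow, rounder: Callable[[float], float]) -> List[TwoByTwo]:
    found = []
    for tp in range(min(row.n_ref_pos, row.n_code_pos) + 1):
        fp = row.n_code_pos - tp
        fn = row.n_ref_pos - tp
        tn = row.n_total - tp - fp - fn
        if min(fp, fn, tn) < 0:
            continue
        checks = (
            (tp, row.n_ref_pos, row.sn),
            (tn, tn + fp, row.sp),
            (tp, row.n_code_pos, row.ppv),
            (tn, tn + fn, row.npv),
        )
        if all(n > 0 and rounder(100.0 * k / n) == printed for k, n, printed in checks):
            found.append(TwoByTwo(tp, fp, fn, tn))
    return found


def reconstruct_counts(
    row: PrintedRow, rounder: Callable[[float], float] = paper_round
) -> TwoByTwo:
    """Recover the unique 2x2 table behind a printed row.

    Raises
    ------
    InconsistentCountsError
        No TP value reproduces the printed statistics — the row contradicts
        its marginals under the assumed rounding.
    AmbiguousCountsError
        More than one TP survives; the printed precision does not pin the
        table down (the exception carries all candidates).
    """
    found = _candidates(row, rounder)
    if not found:
        raise InconsistentCountsError(
            f"no 2x2 table with marginals (n={row.n_total}, ref+={row.n_ref_pos}, "
            f"code+={row.n_code_pos}) reproduces sn={row.sn}, sp={row.sp}, "
            f"ppv={row.ppv}, npv={row.npv}"
        )
    if len(found) > 1:
        raise AmbiguousCountsError(
            f"{len(found)} tables reproduce the printed row: "
            f"{[t.as_tuple() for t in found]}",
            found,
        )
    return found[0]


def _load() -> dict:
    with resources.files("akicode.data").joinpath("published_rows.json").open() as fh:
        return json.load(fh)


def published_rows() -> List[PrintedRow]:
    """The eight unsuppressed printed rows of the validation study.

    The ninth (main diagnosis vs stage >= 1) pair was withheld under the
    privacy small-cell rule and cannot be reconstructed from print.
    """
    raw = _load()
    return [
        PrintedRow(
            n_total=raw["n_total"],
            n_ref_pos=raw["reference_positive"][r["reference"]],
            n_code_pos=raw["code_positive"][r["algorithm"]],
            sn=r["sn"],
            sp=r["sp"],
            ppv=r["ppv"],
            npv=r["npv"],
            algorithm=r["algorithm"],
            reference=r["reference"],
            lr_plus=r["lr_plus"],
        )
        for r in raw["rows"]
    ]


def published_row_details() -> List[Dict]:
    """Raw printed rows including the confidence-interval bounds."""
    return _load()["rows"]


def published_descriptives() -> Dict:
    """Printed cohort descriptives (stage counts, code-positive rate, ...)."""
    return _load()["descriptives"]
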