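"""ICD-10 N17x code positivity under three coding algorithms.

Hospital discharge abstracts carry up to 25 diagnosis codes, each with a
diagnosis *type*: "M" for the most responsible (main) diagnosis — the
condition consuming the most resources or length of stay — a pre-admission
type for conditions present before admission and treated during the stay,
and various other types. A record is tested for acute kidney injury coding
under three algorithms of decreasing breadth:

* ``any_diagnosis`` — an N17x code in any of the 25 fields;
* ``admission_diagnosis`` — an N17x code typed as pre-admission;
* ``main_diagnosis`` — the (unique) most responsible diagnosis is N17x.

"N17x" is a prefix match on canonicalised codes (dots and whitespace
stripped, uppercased), so N17, N170 ... N179 all match while N18x chronic
kidney disease codes never do.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import DataIntegrityError

__all__ = [
    "DX_MAIN",
    "DX_PREADMIT",
    "DX_OTHER",
    "ALGORITHMS",
    "DEFAULT_DX_TYPE_MAP",
    "CodingAlgorithm",
    "canonicalize_code",
    "normalize_dx_types",
    "code_positive",
    "classify_admissions",
]

DX_MAIN = "M"
DX_PREADMIT = "PREADMIT"
DX_OTHER = "OTHER"

ALGORITHMS = ("any_diagnosis", "admission_diagnosis", "main_diagnosis")

# Mapping from raw CIHI diagnosis-type codes to the three types the
# algorithms distinguish. Type M is the most responsible diagnosis; type 1 is
# a pre-admission comorbidity; types 2/3/W/X/Y (post-admission, secondary and
# service-transfer types) all fall under OTHER. Override for other codings.
DEFAULT_DX_TYPE_MAP: Mapping[str, str] = {
    "M": DX_MAIN,
    "1": DX_PREADMIT,
    "2": DX_OTHER,
    "3": DX_OTHER,
    "W": DX_OTHER,
    "X": DX_OTHER,
    "Y": DX_OTHER,
    DX_MAIN: DX_MAIN,
    DX_PREADMIT: DX_PREADMIT,
    DX_OTHER: DX_OTHER,
}

_CANON_RE = re.compile(r"[.\s]+")


@dataclass(frozen=True)
class CodingAlgorithm:
    """One of the three phenotyping algorithms, with its target code family."""

    name: str
    target_prefix: str = "N17"

    def __post_init__(self):
        if self.name not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.name!r}; expected one of {ALGORITHMS}")
        prefix = canonicalize_code(self.target_prefix)
        if not prefix or not prefix.isalnum():
            raise ValueError(f"target prefix must be nonempty alphanumeric, got {self.target_prefix!r}")
        object.__setattr__(self, "target_prefix", prefix)


def canonicalize_code(code: str) -> str:
    """Uppercase an ICD-10 code and strip dots and whitespace.

    "n17.0", "N17 0" and "N170" all canonicalise to "N170".
    """
    return _CANON_RE.sub("", str(code)).upper()


def normalize_dx_types(
    diagnoses: pd.DataFrame, mapping: Mapping[str, str] = DEFAULT_DX_TYPE_MAP
) -> pd.DataFrame:
    """Map raw diagnosis-type codes onto {M, PREADMIT, OTHER}.

    Unknown raw types raise, since silently treating them as OTHER could
    hide a mis-specified mapping.
    """
    raw = diagnoses["dx_type"].astype(str)
    unknown = sorted(set(raw) - set(mapping))
    if unknown:
        raise DataIntegrityError(f"unmapped diagnosis types: {unknown}")
    out = diagnoses.copy()
    out["dx_type"] = raw.map(mapping)
    return out


def code_positive(
    admission_diagnoses: pd.DataFrame | Iterable[tuple],
    algorithm: CodingAlgorithm | str,
) -> bool:
    """Is a single admission code-positive under ``algorithm``?

    ``admission_diagnoses`` holds that admission's diagnosis rows with
    ``code`` and ``dx_type`` (already normalised to M/PREADMIT/OTHER).
    """
    if isinstance(algorithm, str):
        algorithm = CodingAlgorithm(algorithm)
    if isinstance(admission_diagnoses, pd.DataFrame):
        df = admission_diagnoses
    else:
        df = pd.DataFrame(list(admission_diagnoses))
    if df.empty:
        return False
    codes = df["code"].map(canonicalize_code)
    types = df["dx_type"]
    if (types == DX_MAIN).sum() > 1:
        raise DataIntegrityError("admission has more than one most responsible (type M) diagnosis")
    matches = codes.str.startswith(algorithm.target_prefix)
    if algorithm.name == "any_diagnosis":
        return bool(matches.any())
    if algorithm.name == "admission_diagnosis":
        return bool((matches & (types == DX_PREADMIT)).any())
    return bool((matches & (types == DX_MAIN)).any())


def classify_admissions(
    diagnoses: pd.DataFrame,
    admission_ids: Iterable | None = None,
    target_prefix: str = "N17",
) -> pd.DataFrame:
    """Code positivity of many admissions under all three algorithms at once.

    Parameters
    ----------
    diagnoses
        Long-format table with ``admission_id``, ``code``, ``dx_type``.
    admission_ids
        Admissions to report on (defaults to those present in ``diagnoses``);
        admissions with no diagnosis rows are negative everywhere.

    Returns
    -------
    DataFrame indexed by admission_id with boolean columns
    ``any_diagnosis``, ``admission_diagnosis``, ``main_diagnosis``.
    """
    prefix = canonicalize_code(target_prefix)
    df = diagnoses[["admission_id", "code", "dx_type"]].copy()

    n_main = df[df["dx_type"] == DX_MAIN].groupby("admission_id").size()
    dup = n_main[n_main > 1]
    if not dup.empty:
        raise DataIntegrityError(
            f"admissions with more than one type-M diagnosis: {dup.index.tolist()[:5]}"
        )

    codes = df["code"].map(canonicalize_code)
    hit = codes.str.startswith(prefix).to_numpy()
    flags = pd.DataFrame(
        {
            "admission_id": df["admission_id"],
            "any_diagnosis": hit,
            "admission_diagnosis": hit & (df["dx_type"] == DX_PREADMIT).to_numpy(),
            "main_diagnosis": hit & (df["dx_type"] == DX_MAIN).to_numpy(),
        }
    )
    out = flags.groupby("admission_id").any()
    if admission_ids is not None:
        out = out.reindex(pd.Index(admission_ids, name="admission_id"), fill_value=False)
    return out
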