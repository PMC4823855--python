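"""Rounding conventions used when rendering statistics as printed percentages.

Administrative-data validation reports typically present proportions as
percentages with one decimal place. Two conventions are provided:

``round_half_up``
    Ordinary commercial rounding (0.5 always rounds away from zero), applied
    once at the requested precision.

``paper_round``
    Half-up rounding applied twice: first to two decimals, then to one.
    Statistical packages such as SAS print proportions to (at least) two
    decimals; when a report is then transcribed to one decimal by hand, values
    like 48.148 pass through 48.15 and land on 48.2 rather than 48.1. This
    double rounding reproduces every percentage in the published validation
    tables this package replicates, whereas single rounding does not.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "paper_round"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    Python's built-in ``round`` uses banker's rounding (93.75 -> 93.7 at one
    decimal); reported percentages follow the half-up convention instead
    (93.75 -> 93.8).
    """
    if x != x:  # NaN passes through
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def paper_round(x: float, ndigits: int = 1) -> float:
    """Half-up round to ``ndigits + 1`` decimals, then to ``ndigits``."""
    return round_half_up(round_half_up(x, ndigits + 1), ndigits)
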