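"""Small shared helpers (rounding conventions, formatting)."""
from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as tabular reports conventionally do.

    Python's built-in ``round`` uses banker's rounding; published claims
    tables round 70.915 up to 70.92, so all percentages in this package go
    through this helper.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """numerator/denominator as a percentage, rounded half-up.

    Raises ``ZeroDivisionError`` for a zero denominator: a prevalence over an
    empty prescription database is undefined, not zero.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage undefined: denominator is zero")
    q = Decimal(1).scaleb(-ndigits)
    # str() round-trips plain and numpy scalars alike
    value = Decimal(str(numerator)) * 100 / Decimal(str(denominator))
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def fmt_pct(numerator: float, denominator: float, ndigits: int = 2) -> str:
    """Formatted percentage string, e.g. ``'70.92'``."""
    return f"{pct(numerator, denominator, ndigits):.{ndigits}f}"
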