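"""Small numeric helpers shared across modules."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero-half behaviour (0.5 -> 1), unlike
    Python's banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_ratio(num: int, den: int, ndigits: int) -> float:
    """Half-up rounding of an exact integer ratio, avoiding float noise."""
    if den == 0:
        raise ZeroDivisionError("denominator is zero")
    q = Decimal(1).scaleb(-ndigits)
    return float((Decimal(num) / Decimal(den)).quantize(q, rounding=ROUND_HALF_UP))


def percent_value(count: int, total: int) -> float:
    """Percentage as printed in summary text: an integer percent unless the
    exact value terminates after one decimal place (e.g. 15/24 -> 62.5)."""
    if total <= 0:
        raise ValueError("total must be positive")
    frac = Fraction(count * 1000, total)
    if frac.denominator == 1 and frac.numerator % 10 != 0:
        # exactly one decimal place, e.g. 62.5
        return round_ratio(100 * count, total, 1)
    return round_ratio(100 * count, total, 0)


def percent_label(count: int, total: int) -> str:
    v = percent_value(count, total)
    return f"{v:g}%"
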