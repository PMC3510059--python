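"""Small numeric helpers shared across modules."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention used in printed tables).

    Python's built-in ``round`` uses banker's rounding, which turns 42.5 into
    42; printed percentages in epidemiological tables round half up.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 0) -> float:
    """Percentage rounded half-up to ``ndigits``."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty total is undefined")
    return round_half_up(100.0 * numerator / denominator, ndigits)
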