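"""Half-up decimal rounding, matching how the study's tables were formatted."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round ``value`` to ``ndigits`` decimals with ties away from zero.

    Python's built-in ``round`` is banker's rounding; printed percentages in
    expression tables conventionally round 0.5 up (93.5% -> 94%), so all
    display rounding goes through this helper.
    """
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


def percent_half_up(numerator: float, denominator: float) -> int:
    """Integer percentage, half-up. Raises on zero denominator."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return int(round_half_up(100.0 * numerator / denominator, 0))
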