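"""Small numeric helpers shared across modules."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float | int:
    """Round with ties going away from zero at the given decimal place.

    Python's builtin ``round`` uses banker's rounding; report percentages the
    way statistics packages print them (0.5 rounds up), so 26.35 -> 26.4.
    Returns an int when ``ndigits <= 0``.
    """
    q = Decimal(1).scaleb(-ndigits)
    v = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return int(v) if ndigits <= 0 else float(v)


def percentage(count: int, total: int, ndigits: int = 1) -> float | int:
    """``100 * count / total`` rounded half-up to ``ndigits`` decimals."""
    if total <= 0:
        raise ValueError("percentage denominator must be positive")
    return round_half_up(100.0 * count / total, ndigits)


def truncated_mean(values) -> int:
    """Integer-truncated arithmetic mean (floor toward zero) of a sequence."""
    vals = list(values)
    if not vals:
        raise ValueError("truncated_mean of empty sequence")
    return int(sum(vals) / len(vals))
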