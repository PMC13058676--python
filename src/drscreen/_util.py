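"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (the convention of clinical tables).

    Python's built-in ``round`` uses banker's rounding; published screening
    tables round 0.5 up in magnitude, so reported percentages must too.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_half_away_int(x: float) -> int:
    """``round_half_away`` to an integer count."""
    return int(round_half_away(x, 0))
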