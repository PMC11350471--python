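"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (reporting convention).

    Python's built-in ``round`` uses banker's rounding; printed tables here
    follow the half-away-from-zero convention instead (90.5 % -> 91 %).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
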