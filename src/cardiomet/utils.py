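"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (clinical-table convention).

    Python's builtin ``round`` is banker's rounding; published tables round
    14/32 = 43.75% to 44%, so half-up is used wherever a printed value is
    reproduced.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))
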