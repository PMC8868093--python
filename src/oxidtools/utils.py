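"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round ``value`` half-up to ``ndigits`` decimals.

    Percentages are reported at two decimals with ties rounded away from
    zero (so 0.005 -> 0.01), matching how the summary tables print them.
    Python's built-in ``round`` uses banker's rounding, hence Decimal here.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
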