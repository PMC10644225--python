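"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero at ``ndigits`` decimals.

    Published pharmacovigilance tables round half-up (60.955 prints as
    60.96), whereas Python's built-in ``round`` is banker's rounding.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(
        quantum, rounding=ROUND_HALF_UP))
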