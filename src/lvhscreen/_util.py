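"""Small shared helpers."""
from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

__all__ = ["round_half_up"]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero at the given decimal place.

    Report percentages use this convention (8.70% -> 9%), unlike banker's
    rounding used by ``round``/``numpy.round``.
    """
    q = Decimal(1).scaleb(-decimals)
    value = float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
    return value if decimals > 0 else float(int(value))
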