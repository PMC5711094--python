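"""Small shared helpers."""

from __future__ import annotations

import decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from the midpoint going up (0.5 -> 1), matching
    how printed QA tables are conventionally rounded (not banker's)."""
    q = decimal.Decimal(10) ** -ndigits
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)
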