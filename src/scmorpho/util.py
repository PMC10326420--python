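"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["percent_round_half_up"]


def percent_round_half_up(count: int, total: int, decimals: int = 1) -> float:
    """Percentage of ``count / total`` rounded half-up to ``decimals`` places.

    Half-up (not banker's) rounding matches how phenotype-penetrance
    fractions are conventionally reported, e.g. 10 of 26 -> 38.5.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    q = Decimal(1).scaleb(-decimals)
    value = Decimal(count) * 100 / Decimal(total)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))
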