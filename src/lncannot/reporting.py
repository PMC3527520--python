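"""Small numeric reporting helpers shared by the summary tables."""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, Decimal


def percentage(numerator: int, denominator: int, decimals: int = 2) -> float:
    """100 * numerator/denominator, round-half-to-even at ``decimals``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_EVEN
    )
    return float(value)
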