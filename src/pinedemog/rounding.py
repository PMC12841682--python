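"""Presentation rounding: round-half-even at decimals or significant figures.

Used only when rendering or comparing to published tables; all pipeline
arithmetic is carried at full precision.
"""

from __future__ import annotations

import math


def round_half_even(x: float, ndigits: int = 0) -> float:
    """Round to ``ndigits`` decimal places with ties to even."""
    return round(float(x), ndigits)


def signif(x: float, digits: int) -> float:
    """Round to ``digits`` significant figures (ties to even); signif(0) = 0."""
    if digits < 1:
        raise ValueError("digits must be >= 1")
    if x == 0 or not math.isfinite(x):
        return float(x)
    exponent = math.floor(math.log10(abs(x)))
    return round(float(x), digits - 1 - exponent)
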