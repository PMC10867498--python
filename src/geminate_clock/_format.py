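"""Report formatting helpers.

All printed distances and rates are percentages rounded to one decimal,
half away from zero (so 4.857 -> 4.9 and 2.45 -> 2.5). Python's builtin
``round`` uses banker's rounding and would print 2.45 -> 2.4.
"""

import math


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round to ``ndigits`` decimals, ties away from zero."""
    factor = 10.0**ndigits
    scaled = x * factor
    # nudge by a relative epsilon so float artefacts like 2.4499999999
    # arising from an exact 2.45 still round up
    eps = abs(scaled) * 1e-12
    if scaled >= 0:
        return math.floor(scaled + 0.5 + eps) / factor
    return math.ceil(scaled - 0.5 - eps) / factor


def as_percent(proportion: float, ndigits: int = 1) -> float:
    """Proportion -> percent, rounded for presentation (0.13571 -> 13.6)."""
    return round_half_away(100.0 * proportion, ndigits)


def fmt_percent(proportion: float, ndigits: int = 1) -> str:
    return f"{as_percent(proportion, ndigits):.{ndigits}f}"
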