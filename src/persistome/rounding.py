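"""Half-up decimal rounding for printed percentages.

Python's builtin ``round`` is banker's rounding; the report tables use
conventional half-up rounding at the precision each figure is printed with.
"""

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(value: float, ndigits: int = 1) -> float:
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up."""
    return round_half_up(100.0 * numerator / denominator, ndigits)
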