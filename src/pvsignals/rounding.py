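"""Half-away-from-zero decimal rounding for displayed percentages.

Python's builtin ``round`` is banker's rounding; published tables round
half away from zero, so percentage fields go through this helper.
"""

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
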