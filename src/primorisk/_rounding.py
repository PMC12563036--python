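"""Half-up decimal rounding for the reporting boundary.

All pipeline arithmetic is carried at full float precision; rounding
happens only when a number is written to a report. Regulatory tables round
half-up (122.5% -> 123%), which differs from Python's builtin banker's
rounding, hence this helper.
"""

from decimal import Decimal, ROUND_HALF_UP

# Floats within 1e-9 of a representable tie are treated as that tie, so a
# ratio like 0.627/0.6*100 = 104.49999999999999... still rounds to 105.
_GUARD = 9


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimal places, ties away from zero."""
    d = Decimal(repr(float(x)))
    if ndigits < _GUARD:
        d = d.quantize(Decimal(1).scaleb(-_GUARD), rounding=ROUND_HALF_UP)
    return float(d.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


def round_sig(x: float, sig: int) -> float:
    """Round ``x`` to ``sig`` significant figures, ties away from zero."""
    if x == 0:
        return 0.0
    d = Decimal(repr(float(x)))
    shift = sig - d.adjusted() - 1
    return round_half_up(x, shift)
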