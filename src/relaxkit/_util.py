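"""Small shared helpers."""

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (report convention for percentages).

    Python's built-in ``round`` uses banker's rounding; report tables in this
    package always round 98.85 -> 98.9, -0.05 -> -0.1.
    """
    q = Decimal(10) ** -ndigits
    d = Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP) if x >= 0 else \
        -((-Decimal(repr(x))).quantize(q, rounding=ROUND_HALF_UP))
    return float(d)
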