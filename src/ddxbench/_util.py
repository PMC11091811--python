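"""Small shared helpers: half-up rounding matching the reporting convention."""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (half-up), as in the reported tables.

    Python's built-in ``round`` is banker's rounding; reported percentages
    use the conventional half-up rule (e.g. 53.95 -> 54.0, SD 8.5 -> 9).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
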