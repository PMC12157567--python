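"""Shared numeric helpers."""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    Table emission needs reproducible decimal rounding; Python's built-in
    ``round`` uses banker's rounding, which differs on exact .5 ties.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))
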