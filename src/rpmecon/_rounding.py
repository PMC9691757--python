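"""Half-up display rounding.

All model arithmetic is carried out unrounded; published figures round
half-up to a fixed precision (whole dollars for annual totals, cents for
per-contact rates, two decimals for FTE). Python's built-in ``round`` uses
banker's rounding, so display values go through :func:`round_half_up`.
"""

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` half-away-from-zero-on-ties to ``ndigits`` decimals.

    Uses ``repr`` of the float so that values like 0.125 stored as
    0.12499999...e0 are not an issue for the short decimals this model
    produces.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
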