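"""Small shared numeric helpers."""

from __future__ import annotations

import decimal


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (``2.5 -> 3``, ``-2.5 -> -3``).

    This is the convention of the statistical software the published
    tables were produced with, and differs from Python's banker's
    rounding on exact halves.
    """
    quant = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(float(value))).quantize(quant, rounding=decimal.ROUND_HALF_UP)
    return float(d)
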