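"""Fixed-decimal display rounding for report tables.

All tabular output rounds half away from zero on the decimal value
(``ROUND_HALF_UP``), which reproduces published genebank burden tables
digit-for-digit; binary-float round-half-even does not (e.g. the mean of
0.00246 and 0.00491 must print as 0.00369).  Conventions: 3 decimals for
cohort-level summaries, 5 for per-country tables, 6 for carrier
frequencies.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

COHORT_DECIMALS = 3
COUNTRY_DECIMALS = 5
FREQUENCY_DECIMALS = 6


def round_half_up(x: float, ndigits: int) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fmt(x: float, ndigits: int) -> str:
    """Fixed-decimal string under the same rounding rule."""
    q = Decimal(1).scaleb(-ndigits)
    return str(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
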