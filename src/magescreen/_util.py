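"""Small shared helpers: display rounding and rate arithmetic.

Clinical reports round half-up (so 8.571% prints as 9%, 0.4390% as 0.44%),
which differs from Python's banker's rounding; all internal values stay at
full precision and these helpers are applied at display/report time only.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round `x` half-up to `ndigits` decimal places (1.25 -> 1.3 at 1 digit)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def rate_pct(numerator: float, denominator: float) -> float:
    """Full-precision percentage numerator/denominator * 100."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    return 100.0 * numerator / denominator


def rate_pct_display(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Display-rounded percentage (half-up)."""
    return round_half_up(rate_pct(numerator, denominator), ndigits)
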