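"""Fixed-point currency helpers.

All monetary amounts are ``decimal.Decimal`` quantities so that totals are
bit-stable across platforms; binary floats never enter an amount. Rounding is
half-up (commercial rounding), applied per component before summation.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

CENT = Decimal("0.01")
TENTH = Decimal("0.1")
ZERO = Decimal("0.00")


def as_decimal(value) -> Decimal:
    """Convert a number or numeric string to an exact Decimal.

    Floats are converted through their shortest repr so that e.g. ``0.1``
    becomes ``Decimal('0.1')`` and not its binary expansion.
    """
    if isinstance(value, Decimal):
        return value
    if isinstance(value, float):
        return Decimal(repr(value))
    return Decimal(value)


def round2(value) -> Decimal:
    """Round to euro cents, half-up."""
    return as_decimal(value).quantize(CENT, rounding=ROUND_HALF_UP)


def round1(value) -> Decimal:
    """Round to one decimal (reported percentages), half-up."""
    return as_decimal(value).quantize(TENTH, rounding=ROUND_HALF_UP)


def money_str(value: Decimal) -> str:
    """Canonical two-decimal string used in all serialised outputs."""
    return str(round2(value))
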