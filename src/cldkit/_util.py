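"""Small shared helpers."""

from __future__ import annotations

import re
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

_SLUG_RE = re.compile(r"[^a-z0-9]+")


def slugify(label: str) -> str:
    """Lowercase, hyphen-separated identifier derived from a label.

    Used as the stable key for variables in file formats; the original
    spelling is kept in ``Variable.label``.
    """
    slug = _SLUG_RE.sub("-", label.lower()).strip("-")
    if not slug:
        raise ValueError(f"label {label!r} slugifies to an empty id")
    return slug


def round_half_up(value: Fraction | float, decimals: int = 1) -> float:
    """Round with ties going away from zero (reporting convention).

    Percentages are kept as exact rationals internally and only rounded
    at the reporting boundary, so 6.75 prints as 6.8, never 6.7.
    """
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(float(value)))
    quantum = Decimal(1).scaleb(-decimals)
    return float(dec.quantize(quantum, rounding=ROUND_HALF_UP))
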