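"""Small shared helpers: rounding and date coercion."""

from __future__ import annotations

import datetime as dt
from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (0.5 -> 1, -0.5 -> -1).

    Python's built-in ``round`` uses banker's rounding; published percentage
    tables are conventionally rounded half-away-from-zero, so reported
    percentages go through this helper.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def as_date(value) -> dt.date:
    """Coerce an ISO string / datetime / date to a ``datetime.date``."""
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))
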