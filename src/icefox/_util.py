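"""Small shared helpers: rounding, date arithmetic, logging."""

from __future__ import annotations

import logging
from datetime import date, timedelta
from decimal import ROUND_HALF_UP, Decimal

logger = logging.getLogger("icefox")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed tables),
    unlike Python's banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def daterange(start: date, end: date):
    """Yield dates in the half-open interval [start, end)."""
    d = start
    while d < end:
        yield d
        d += timedelta(days=1)


def consecutive_runs(dates) -> list[tuple[date, date]]:
    """Maximal runs of consecutive calendar dates, as (first, last) pairs."""
    ds = sorted(set(dates))
    runs: list[tuple[date, date]] = []
    if not ds:
        return runs
    start = prev = ds[0]
    for d in ds[1:]:
        if (d - prev).days == 1:
            prev = d
        else:
            runs.append((start, prev))
            start = prev = d
    runs.append((start, prev))
    return runs
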