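"""Partial-date parsing and calendar arithmetic.

Dates in manifests and metadata snapshots are accepted at day, month, or
year precision (``YYYY``, ``YYYY-MM``, ``YYYY-MM-DD``); missing components
default to the first month/day.  All downstream arithmetic works on plain
:class:`datetime.date` values under this convention.
"""

from __future__ import annotations

import re
from datetime import date

_PARTIAL_DATE_RE = re.compile(r"^(\d{4})(?:-(\d{1,2})(?:-(\d{1,2}))?)?$")


class DateParseError(ValueError):
    """Raised when a string is not a valid ISO-8601 date prefix."""


def parse_partial_date(text: str) -> date:
    """Parse ``YYYY``, ``YYYY-MM`` or ``YYYY-MM-DD``; missing parts become 1.

    >>> parse_partial_date("2005-03")
    datetime.date(2005, 3, 1)
    """
    m = _PARTIAL_DATE_RE.match(text.strip())
    if m is None:
        raise DateParseError(f"not an ISO-8601 date prefix: {text!r}")
    year = int(m.group(1))
    month = int(m.group(2)) if m.group(2) else 1
    day = int(m.group(3)) if m.group(3) else 1
    try:
        return date(year, month, day)
    except ValueError as exc:
        raise DateParseError(f"invalid calendar date: {text!r}") from exc


def days_between(start: date, end: date) -> int:
    """Whole days elapsed from ``start`` to ``end``."""
    return (end - start).days


def whole_years_between(start: date, end: date) -> int:
    """Calendar years elapsed, decremented if ``end``'s month-day precedes
    ``start``'s (the "birthday" convention): Mar 2005 -> Nov 2016 is 11.
    """
    years = end.year - start.year
    if (end.month, end.day) < (start.month, start.day):
        years -= 1
    return years


def first_of_month(d: date) -> date:
    return d.replace(day=1)


def add_months(d: date, n: int) -> date:
    """Shift the first-of-month date ``d`` by ``n`` months."""
    total = d.year * 12 + (d.month - 1) + n
    return date(total // 12, total % 12 + 1, 1)


def month_grid(start: date, end: date) -> list[date]:
    """Inclusive monthly grid of first-of-month dates covering start..end."""
    if end < start:
        raise ValueError("grid end precedes start")
    out = []
    t = first_of_month(start)
    stop = first_of_month(end)
    while t <= stop:
        out.append(t)
        t = add_months(t, 1)
    return out
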