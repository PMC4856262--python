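"""Calendar-month arithmetic helpers (day-resolution dates throughout)."""

from __future__ import annotations

import calendar
import datetime as dt

DAYS_PER_MONTH = 30.44  # fixed duration conversion factor


def add_months(day: dt.date, months: int) -> dt.date:
    """Shift by whole calendar months, clamping to the month's last day."""
    m = day.month - 1 + months
    year = day.year + m // 12
    month = m % 12 + 1
    return dt.date(year, month, min(day.day, calendar.monthrange(year, month)[1]))


def month_index(day: dt.date) -> int:
    """Months since year 0 (orders and differences calendar months)."""
    return day.year * 12 + day.month - 1


def days_to_months(days: int | float) -> float:
    return days / DAYS_PER_MONTH
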