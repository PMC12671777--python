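"""365-day calendar arithmetic.

The synthetic weather generator and the output dialect use idealized
365-day years (February always has 28 days, no leap days). This keeps
day-of-year arithmetic exact across multi-decade series. Helpers here
convert between day-of-year and (month, day) in that calendar.
"""

from __future__ import annotations

import numpy as np

MONTH_LENGTHS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
_CUM = np.concatenate([[0], np.cumsum(MONTH_LENGTHS)])  # 13 entries, _CUM[12] == 365

DAYS_PER_YEAR = 365


def doy_to_month_day(doy) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized day-of-year (1..365) -> (month 1..12, day-of-month 1..31)."""
    doy = np.asarray(doy, dtype=np.int64)
    if np.any((doy < 1) | (doy > DAYS_PER_YEAR)):
        raise ValueError("doy must be in 1..365")
    month = np.searchsorted(_CUM[1:], doy, side="left") + 1
    day = doy - _CUM[month - 1]
    return month, day


def month_day_to_doy(month: int, day: int) -> int:
    """(month, day) -> day-of-year in the 365-day calendar."""
    if not 1 <= month <= 12:
        raise ValueError("month must be in 1..12")
    if not 1 <= day <= MONTH_LENGTHS[month - 1]:
        raise ValueError(f"day {day} invalid for month {month}")
    return int(_CUM[month - 1]) + int(day)
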