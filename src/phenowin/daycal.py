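"""Non-leap calendar arithmetic for breeding-season day indices.

All internal dates are integer *day indices*: day 1 is January 1 of the
breeding year, day 365 is December 31, and days of the preceding autumn/winter
carry non-positive indices (November 1 of the previous year is day -60).
A fixed 365-day calendar (no February 29) keeps day-interval arithmetic exact
across the multi-year averages the reporting layer works with; the reported
community lag intervals only reproduce under this convention.
"""

from __future__ import annotations

import warnings

import numpy as np

DAYS_PER_YEAR = 365

_DAYS_IN_MONTH = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
_CUM_DAYS = np.concatenate([[0], np.cumsum(_DAYS_IN_MONTH)])

_MONTH_NAMES = (
    "Jan", "Feb", "Mar", "Apr", "May", "Jun",
    "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
)

#: Day-of-year of the first day of each supported origin (day 1 = Jan 1).
ORIGIN_DOY = {"jan1": 1, "apr1": 91}


def doy(month: int, day: int) -> int:
    """Day of year (Jan 1 = 1) of a month/day pair in the non-leap calendar."""
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range: {month}")
    if not 1 <= day <= _DAYS_IN_MONTH[month - 1]:
        raise ValueError(f"day out of range for month {month}: {day}")
    return int(_CUM_DAYS[month - 1]) + day


def doy_to_monthday(d: int) -> tuple[int, int]:
    """Inverse of :func:`doy` for d in 1..365."""
    if not 1 <= d <= DAYS_PER_YEAR:
        raise ValueError(f"day of year out of range: {d}")
    month = int(np.searchsorted(_CUM_DAYS, d, side="left"))
    return month, d - int(_CUM_DAYS[month - 1])


def parse_monthday(text: str) -> int:
    """Parse 'MM-DD' (e.g. '11-01') to a day of year."""
    try:
        m, d = (int(p) for p in text.split("-"))
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise ValueError(f"expected 'MM-DD', got {text!r}") from exc
    return doy(m, d)


def format_day(day_index: int, year: int | None = None) -> str:
    """Human-readable label ('Feb 19' or '2003-02-19') for a day index."""
    y, d = resolve_day(day_index, year if year is not None else 0)
    m, dd = doy_to_monthday(d)
    if year is None:
        return f"{_MONTH_NAMES[m - 1]} {dd}"
    return f"{y:04d}-{m:02d}-{dd:02d}"


def resolve_day(day_index: int, breeding_year: int) -> tuple[int, int]:
    """Map a breeding-year day index to an absolute (calendar year, doy) pair.

    Non-positive indices resolve into the preceding calendar year.
    """
    y, d = breeding_year, int(day_index)
    while d < 1:
        d += DAYS_PER_YEAR
        y -= 1
    while d > DAYS_PER_YEAR:
        d -= DAYS_PER_YEAR
        y += 1
    return y, d


def day_interval(from_day: int, to_day: int) -> int:
    """Days strictly after ``from_day`` up to and including ``to_day``.

    A reversed pair returns the (negative) signed count with a warning rather
    than raising, so that bulk report generation can proceed.
    """
    n = int(to_day) - int(from_day)
    if n < 0:
        warnings.warn(
            f"day_interval: to_day ({to_day}) precedes from_day ({from_day}); "
            "returning a negative count",
            stacklevel=2,
        )
    return n


def convert_day_origin(day_index, from_origin: str = "jan1",
                       to_origin: str = "apr1"):
    """Re-express a day index relative to a different calendar origin.

    Both origins use the convention that the origin date itself is day 1,
    so the Jan 1 -> Apr 1 shift is 90 days in the non-leap calendar
    (day 128 after Jan 1, May 8, becomes day 38 after Apr 1).
    """
    for o in (from_origin, to_origin):
        if o not in ORIGIN_DOY:
            raise ValueError(f"unknown origin {o!r}; expected one of {sorted(ORIGIN_DOY)}")
    shift = ORIGIN_DOY[to_origin] - ORIGIN_DOY[from_origin]
    if np.isscalar(day_index):
        return int(day_index) - shift
    return np.asarray(day_index) - shift
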