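"""365-day no-leap model calendar.

The model runs on a fixed calendar (no leap days): years are 365 days,
months keep their usual lengths with February at 28 days.  Time is an
integer day index counted from 1780-01-01.
"""

from __future__ import annotations

import numpy as np

DAYS_PER_YEAR = 365
MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
MONTH_START = np.concatenate([[0], np.cumsum(MONTH_LENGTHS)])  # day-of-year of month starts
MONTH_MID = MONTH_START[:-1] + MONTH_LENGTHS / 2.0             # month mid-points (doy, float)

BASE_YEAR = 1780

#: month-of-year (0..11) for each day-of-year (0..364)
MONTH_OF_DOY = np.repeat(np.arange(12), MONTH_LENGTHS)


def day_index(year: int, month: int = 1, day: int = 1) -> int:
    """Day index from 1780-01-01 for a no-leap calendar date (1-based m/d)."""
    return (year - BASE_YEAR) * DAYS_PER_YEAR + int(MONTH_START[month - 1]) + (day - 1)


def year_fraction(day: float) -> float:
    """Decimal year of a day index (e.g. 1930.5 for mid-1930)."""
    return BASE_YEAR + day / DAYS_PER_YEAR


def month_index(day: int) -> int:
    """Running month number (0-based from Jan 1780) of a day index."""
    year, doy = divmod(int(day), DAYS_PER_YEAR)
    return year * 12 + int(MONTH_OF_DOY[doy])


def monthly_interp_weights(doy: np.ndarray):
    """Linear interpolation stencil from month mid-points to days of year.

    Returns ``(m0, m1, w1)`` such that a climatological monthly field ``f``
    (length 12) interpolates to ``f[m0]*(1-w1) + f[m1]*w1`` on each day,
    periodic across the year boundary.
    """
    doy = np.asarray(doy, dtype=float)
    mids = MONTH_MID
    m0 = np.searchsorted(mids, doy, side="right") - 1
    m0w = np.mod(m0, 12)
    m1w = np.mod(m0 + 1, 12)
    lo = mids[np.mod(m0, 12)] + np.where(m0 < 0, -DAYS_PER_YEAR, 0.0)
    hi = lo + np.mod(mids[m1w] - mids[m0w], DAYS_PER_YEAR)
    w1 = (doy - lo) / (hi - lo)
    return m0w, m1w, w1
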