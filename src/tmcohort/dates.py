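"""Day-offset calendar arithmetic.

All dates are handled internally as integer day offsets from a fixed origin
(EPOCH, 2017-12-01, the first day covered by the study database analog).
Claims records are day-granular, so integer days avoid any timezone or
resolution ambiguity; conversion to ISO-8601 happens only at the file
boundary.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd

EPOCH = _dt.date(2017, 12, 1)

DAYS_PER_YEAR = 365.25


def to_day(date: str | _dt.date | _dt.datetime) -> int:
    """Convert a calendar date (ISO string or date object) to a day offset."""
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    elif isinstance(date, _dt.datetime):
        date = date.date()
    return (date - EPOCH).days


def from_day(day: int) -> _dt.date:
    """Convert a day offset back to a calendar date."""
    return EPOCH + _dt.timedelta(days=int(day))


def days_to_dates(days) -> pd.Series:
    """Vectorized day-offset -> ISO date string conversion."""
    base = pd.Timestamp(EPOCH)
    ts = base + pd.to_timedelta(np.asarray(days, dtype="int64"), unit="D")
    return pd.Series(ts).dt.strftime("%Y-%m-%d")


def dates_to_days(dates) -> np.ndarray:
    """Vectorized ISO date -> day-offset conversion."""
    ts = pd.to_datetime(pd.Series(dates), format="ISO8601")
    return ((ts - pd.Timestamp(EPOCH)).dt.days).to_numpy(dtype="int64")


def age_in_years(birth_day, at_day) -> np.ndarray:
    """Completed years between two day offsets (365.25-day years)."""
    return np.floor((np.asarray(at_day) - np.asarray(birth_day)) / DAYS_PER_YEAR).astype(
        "int64"
    )
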