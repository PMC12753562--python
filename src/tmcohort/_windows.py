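"""Vectorized per-patient date-window queries.

Record dates for one code class are packed into a single sorted int64 key
array ``position * DAY_SPAN + day`` (``position`` is the patient's row index
in the patients table, ``day`` a non-negative day offset).  Window counts and
first-on-or-after lookups then reduce to ``np.searchsorted`` over the packed
keys, which keeps cohort construction fully vectorized.
"""

from __future__ import annotations

import numpy as np

# larger than any day offset that can occur in a study window (~2100 days);
# leaves ample headroom for multi-decade observation periods.
DAY_SPAN = 1 << 17

_NO_DATE = np.int64(-1)


def pack_keys(positions: np.ndarray, days: np.ndarray) -> np.ndarray:
    """Sorted packed keys for (patient position, record day) pairs."""
    days = np.asarray(days, dtype=np.int64)
    if days.size and (days.min() < 0 or days.max() >= DAY_SPAN):
        raise ValueError("record day offsets must lie in [0, DAY_SPAN)")
    keys = np.asarray(positions, dtype=np.int64) * DAY_SPAN + days
    return np.sort(keys)


def count_in_window(keys: np.ndarray, positions, lo, hi) -> np.ndarray:
    """Number of records for each patient position with lo <= day <= hi.

    ``lo``/``hi`` may be scalars or arrays aligned with ``positions``.
    Windows with hi < lo return 0.
    """
    positions = np.asarray(positions, dtype=np.int64)
    lo = np.maximum(np.asarray(lo, dtype=np.int64), 0)
    hi = np.maximum(np.asarray(hi, dtype=np.int64), -1)
    left = np.searchsorted(keys, positions * DAY_SPAN + lo, side="left")
    right = np.searchsorted(keys, positions * DAY_SPAN + hi, side="right")
    return np.maximum(right - left, 0)


def first_on_or_after(keys: np.ndarray, positions, day) -> np.ndarray:
    """Earliest record day >= day for each patient position, -1 if none."""
    positions = np.asarray(positions, dtype=np.int64)
    day = np.maximum(np.asarray(day, dtype=np.int64), 0)
    pos = np.searchsorted(keys, positions * DAY_SPAN + day, side="left")
    out = np.full(positions.shape, _NO_DATE)
    valid = pos < len(keys)
    if keys.size:
        kp = keys[np.minimum(pos, len(keys) - 1)]
        hit = valid & (kp // DAY_SPAN == positions)
        out[hit] = kp[hit] % DAY_SPAN
    return out
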