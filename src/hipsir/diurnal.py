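"""Day/night classification of fracture times and event-class SIRs.

Fracture clock times split events into night (20:00-07:59) and day
(08:00-19:59); events without a recorded time are ``unknown`` and are
excluded from both numerator and rates (complete-case analysis).  The
person-day denominators are full days for both classes, so the class
split enters only through event counts; with both classes spanning
twelve hours this convention cancels from the O/E ratio.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .sir import SIRResult, sir_from_table

__all__ = ["classify_time", "classify_times", "diurnal_sir"]

_NIGHT_START_MIN = 20 * 60  # 20:00
_DAY_START_MIN = 8 * 60  # 08:00


def _minutes(t) -> int | None:
    if t is None:
        return None
    if isinstance(t, dt.time):
        return t.hour * 60 + t.minute
    s = str(t).strip()
    if not s:
        return None
    h, m = s.split(":")
    return int(h) * 60 + int(m)


def classify_time(t) -> str:
    """Label a clock time: 'night' (20:00-07:59), 'day' (08:00-19:59)
    or 'unknown' (absent)."""
    m = _minutes(t)
    if m is None:
        return "unknown"
    if not 0 <= m < 24 * 60:
        raise ValueError(f"clock time out of range: {t!r}")
    return "night" if (m >= _NIGHT_START_MIN or m < _DAY_START_MIN) else "day"


def classify_times(times: pd.Series) -> np.ndarray:
    """Vectorised :func:`classify_time` over 'HH:MM' strings ('' = unknown)."""
    return np.array([classify_time(t) for t in times], dtype=object)


def diurnal_sir(
    table: pd.DataFrame,
    which: str,
    n_total: int | None = None,
    method: str = "exact",
    alpha: float = 0.05,
    **meta,
) -> SIRResult:
    """SIR for fractures of one diurnal class.

    O counts exposed events of the requested class; stratum rates use
    unexposed events of that class over (full) unexposed person-days.
    ``n_total`` defaults to all events of the class in the table, for
    the class-specific attributable risk.  Raises if the table holds no
    known-time events at all, or no events of the requested class in
    any stratum usable for rates.
    """
    if which not in ("day", "night"):
        raise ValueError("which must be 'day' or 'night'")
    known = int(table["day_events"].sum() + table["night_events"].sum())
    if known == 0:
        raise ValueError("diurnal analysis not estimable: no known-time events")
    return sir_from_table(
        table,
        event_col=f"{which}_events",
        n_total=n_total,
        method=method,
        alpha=alpha,
        **meta,
    )
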