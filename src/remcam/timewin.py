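"""Daily clock-window arithmetic (day/night classification and effort).

The night window is half-open, [18:00, 06:00): 18:00 itself is night, 06:00
is day, and no timestamp is double-counted when a day is partitioned into the
two windows. Windows wrap midnight when start >= end.
"""

from __future__ import annotations

from datetime import datetime, time, timedelta
from typing import Optional, Tuple

NIGHT_WINDOW: Tuple[time, time] = (time(18, 0), time(6, 0))

ClockWindow = Optional[Tuple[time, time]]


def _normalize(window) -> ClockWindow:
    if window is None or window == "all":
        return None
    if window == "night":
        return NIGHT_WINDOW
    if window == "day":
        return (NIGHT_WINDOW[1], NIGHT_WINDOW[0])
    s, e = window
    return (s, e)


def window_hours_per_day(window) -> float:
    """Length of the daily window in hours (24 for the all-hours window)."""
    w = _normalize(window)
    if w is None:
        return 24.0
    s, e = w
    sh = s.hour + s.minute / 60 + s.second / 3600
    eh = e.hour + e.minute / 60 + e.second / 3600
    return (eh - sh) % 24 or 24.0


def in_window(ts: datetime, window) -> bool:
    """True iff the clock time of ``ts`` falls in the half-open daily window."""
    w = _normalize(window)
    if w is None:
        return True
    s, e = w
    t = ts.time()
    if s <= e:
        return s <= t < e
    return t >= s or t < e


def interval_window_hours(start: datetime, end: datetime, window) -> float:
    """Hours of [start, end) that fall inside the daily clock window.

    For a camera active over whole days this gives 12 h per day for the
    default night window, matching the convention that night effort is 12
    hours per active camera-day.
    """
    if end <= start:
        return 0.0
    w = _normalize(window)
    if w is None:
        return (end - start).total_seconds() / 3600.0
    s, e = w
    span = timedelta(hours=window_hours_per_day(w))
    total = 0.0
    # Daily window instances starting the day before `start` cover wrap cases.
    day = datetime.combine(start.date(), s) - timedelta(days=1)
    while day < end:
        lo = max(day, start)
        hi = min(day + span, end)
        if hi > lo:
            total += (hi - lo).total_seconds() / 3600.0
        day += timedelta(days=1)
    return total


def split_interval_by_window(start: datetime, end: datetime, window):
    """Split [start, end) into maximal sub-intervals inside/outside the window.

    Returns a list of (sub_start, sub_end, inside: bool). Used to allocate
    follow-segment distances pro-rata across the 18:00/06:00 boundaries.
    """
    w = _normalize(window)
    if w is None:
        return [(start, end, True)]
    s, _ = w
    span = timedelta(hours=window_hours_per_day(w))
    edges = {start, end}
    day = datetime.combine(start.date(), s) - timedelta(days=1)
    while day < end:
        for edge in (day, day + span):
            if start < edge < end:
                edges.add(edge)
        day += timedelta(days=1)
    cuts = sorted(edges)
    return [(a, b, in_window(a, w)) for a, b in zip(cuts[:-1], cuts[1:])]
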