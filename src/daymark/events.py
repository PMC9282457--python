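"""Exacerbation-event detection, sobriety index, labels and eligibility.

An exacerbation event (EE) is a run of at least two consecutive "bad" days,
where a day is bad when alcohol was detected or all scheduled breathalyzer
tests were omitted — non-compliance counts as relapse-indicating. Forecast
labels mark the days from which an EE *start* is visible within a look-ahead
range (1-3 or 5-7 days ahead), and an eligibility mask restricts evaluation
to days outside the start-up period, outside any EE, and with a sobriety
index of at least 40.

The sobriety index computed here is an approximation built from the same
gap-decay + exponential-smoothing machinery as the questionnaire biomarkers
(no-alcohol days coded 100, detected days 0, omitted days missing). When an
externally computed Addiction Monitoring Index is supplied in the input it
is preferred over this approximation.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .biomarker import SmoothingParams, exponential_smooth, impute_raw_series

__all__ = [
    "EventCalendar",
    "LabelSet",
    "LOOK_AHEAD_RANGES",
    "daily_bad_day",
    "detect_exacerbation_events",
    "sobriety_index",
    "make_labels",
    "eligibility_mask",
]

#: The two supported look-ahead ranges (inclusive day offsets).
LOOK_AHEAD_RANGES = ((1, 3), (5, 7))

_STATUS_CODE = {"no_alcohol": 100.0, "alcohol_detected": 0.0, "all_omitted": np.nan}


def daily_bad_day(status: str) -> bool:
    """True iff the day is relapse-indicating: alcohol detected or all tests
    omitted. Unknown statuses raise ``ValueError``."""
    if status == "alcohol_detected" or status == "all_omitted":
        return True
    if status == "no_alcohol":
        return False
    raise ValueError(f"unknown sobriety status {status!r}")


@dataclass
class EventCalendar:
    """Per-patient exacerbation-event intervals on the panel's day axis.

    ``intervals`` holds (start, end) day indices, inclusive, non-overlapping
    and each of length >= the detection minimum; ``in_ee[t]`` flags days
    covered by an interval; ``starts`` lists the interval start days.
    """

    n_days: int
    intervals: list[tuple[int, int]]
    in_ee: np.ndarray
    patient_id: str | None = None

    @property
    def starts(self) -> np.ndarray:
        return np.array([s for s, _ in self.intervals], dtype=int)


def detect_exacerbation_events(
    status_series: Sequence[str],
    min_len: int = 2,
    patient_id: str | None = None,
) -> EventCalendar:
    """Find maximal runs of bad days of length >= ``min_len``.

    ``status_series`` must be gapless and daily; two bad runs separated by
    at least one good day are never merged.
    """
    bad = np.array([daily_bad_day(s) for s in status_series], dtype=bool)
    n = len(bad)
    intervals: list[tuple[int, int]] = []
    t = 0
    while t < n:
        if bad[t]:
            start = t
            while t < n and bad[t]:
                t += 1
            if t - start >= min_len:
                intervals.append((start, t - 1))
        else:
            t += 1
    in_ee = np.zeros(n, dtype=bool)
    for s, e in intervals:
        in_ee[s : e + 1] = True
    return EventCalendar(
        n_days=n, intervals=intervals, in_ee=in_ee, patient_id=patient_id
    )


def sobriety_index(
    status_series: Sequence[str],
    params: SmoothingParams = SmoothingParams(),
) -> np.ndarray:
    """Approximate sobriety index from daily statuses.

    Statuses are coded no_alcohol=100, alcohol_detected=0, all_omitted=
    missing, then run through the gap-decay imputation and exponential
    smoothing used for the questionnaire biomarkers. Days before the first
    performed test carry NaN.
    """
    raw = np.array([_STATUS_CODE[s] if s in _STATUS_CODE else np.nan
                    for s in status_series])
    for s in status_series:
        if s not in _STATUS_CODE:
            raise ValueError(f"unknown sobriety status {s!r}")
    observed = ~np.isnan(raw)
    out = np.full(len(raw), np.nan)
    if not observed.any():
        return out
    first = int(np.argmax(observed))
    filled, _ = impute_raw_series(raw[first:])
    out[first:] = exponential_smooth(filled, params)
    return out


@dataclass
class LabelSet:
    """Per-day binary forecast labels for one look-ahead range.

    ``labels[t]`` is 1 iff an EE starts at some day in
    ``[t + lo, t + hi]``; ``defined[t]`` is False where the full horizon
    does not fit inside the panel, so the label is unknowable.
    """

    look_ahead: tuple[int, int]
    labels: np.ndarray
    defined: np.ndarray


def make_labels(
    calendar: EventCalendar,
    look_ahead: tuple[int, int] = (1, 3),
    allow_custom: bool = False,
) -> LabelSet:
    """Label each day by whether an EE starts within the look-ahead window.

    Only the ranges (1, 3) and (5, 7) are accepted unless ``allow_custom``.
    """
    lo, hi = look_ahead
    if (lo, hi) not in LOOK_AHEAD_RANGES and not allow_custom:
        raise ValueError(
            f"look-ahead {look_ahead} not in {LOOK_AHEAD_RANGES}; "
            "pass allow_custom=True to override"
        )
    if not (0 < lo <= hi):
        raise ValueError(f"invalid look-ahead range {look_ahead}")
    n = calendar.n_days
    is_start = np.zeros(n, dtype=bool)
    for s in calendar.starts:
        is_start[s] = True
    labels = np.zeros(n, dtype=int)
    defined = np.zeros(n, dtype=bool)
    for t in range(n):
        if t + hi > n - 1:
            continue
        defined[t] = True
        labels[t] = int(is_start[t + lo : t + hi + 1].any())
    return LabelSet(look_ahead=(lo, hi), labels=labels, defined=defined)


def eligibility_mask(
    calendar: EventCalendar,
    ami_series: Sequence[float],
    ami_min: float = 40.0,
    startup_days: int = 7,
) -> np.ndarray:
    """Days on which a forecast would be issued.

    Eligible iff the day index is >= ``startup_days`` (the start-up period
    is excluded), the day is not inside an EE, and the same-day sobriety
    index is present and >= ``ami_min`` (boundary inclusive). Days with a
    missing index are ineligible.
    """
    ami = np.asarray(ami_series, dtype=float)
    if len(ami) != calendar.n_days:
        raise ValueError("sobriety index and calendar must share the day axis")
    t = np.arange(calendar.n_days)
    return (t >= startup_days) & ~calendar.in_ee & ~np.isnan(ami) & (ami >= ami_min)
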