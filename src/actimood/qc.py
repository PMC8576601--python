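"""Completeness-based quality control for wearable streams.

Device use time is verified from the heart-rate stream, the channel most
sensitive to non-wear: a minute is *complete* iff at least one
heart-rate sample falls inside it, and activity/sleep minutes outside
complete minutes are excluded downstream. Days need >= 20 complete
hours; participants need >= 10 complete days and >= 3 weekday sleep
nights. Participant-level summaries (mean heart rate, mean daily steps)
are additionally screened with the Tukey 1.5*IQR outlier rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .streams import MINUTES_PER_DAY, ParticipantStreams

MIN_COMPLETE_HOURS = 20.0
MIN_COMPLETE_DAYS = 10
MIN_WEEKDAY_SLEEP_NIGHTS = 3


@dataclass
class CompletenessReport:
    """Per-minute and per-day completeness derived from heart-rate coverage."""

    pid: str
    complete_minute: np.ndarray        # bool, one flag per tracked minute
    complete_hours_per_day: np.ndarray  # float in [0, 24], one per day

    @property
    def n_days(self) -> int:
        return len(self.complete_hours_per_day)

    @property
    def minutes_complete(self) -> int:
        return int(self.complete_minute.sum())

    def complete_days(self, min_hours: float = MIN_COMPLETE_HOURS) -> np.ndarray:
        return filter_days(self, min_hours)

    def minutes_retained(self, min_hours: float = MIN_COMPLETE_HOURS) -> int:
        """Complete minutes on days passing the day-level rule."""
        days = self.complete_days(min_hours)
        per_day = self.complete_minute.reshape(self.n_days, MINUTES_PER_DAY)
        return int(per_day[days].sum())

    def minutes_discarded(self, min_hours: float = MIN_COMPLETE_HOURS) -> int:
        """Complete minutes lost to excluded days."""
        return self.minutes_complete - self.minutes_retained(min_hours)


def completeness_mask(streams: ParticipantStreams) -> CompletenessReport:
    """Flag each tracked minute complete iff it contains >= 1 HR sample.

    An empty heart-rate stream yields a report with zero complete days
    (the participant simply fails the inclusion rule) rather than an
    exception.
    """
    n_min = streams.n_minutes
    complete = np.zeros(n_min, dtype=bool)
    if len(streams.hr_t):
        minute_idx = np.unique(streams.hr_t // 60)
        minute_idx = minute_idx[(minute_idx >= 0) & (minute_idx < n_min)]
        complete[minute_idx] = True
    hours = complete.reshape(streams.n_days, MINUTES_PER_DAY).sum(axis=1) / 60.0
    return CompletenessReport(streams.pid, complete, hours)


def filter_days(report: CompletenessReport,
                min_hours: float = MIN_COMPLETE_HOURS) -> np.ndarray:
    """Indices of days with at least ``min_hours`` complete hours
    (boundary inclusive)."""
    return np.flatnonzero(report.complete_hours_per_day >= min_hours)


def filter_participants(day_sets: dict, weekday_sleep_nights: dict | None = None,
                        min_days: int = MIN_COMPLETE_DAYS,
                        min_weekday_nights: int = MIN_WEEKDAY_SLEEP_NIGHTS) -> dict:
    """Participant inclusion flags from complete-day sets.

    A participant is retained iff they have at least ``min_days``
    complete days and, when ``weekday_sleep_nights`` is given, at least
    ``min_weekday_nights`` weekday sleep nights.
    """
    flags = {}
    for pid, days in day_sets.items():
        ok = len(days) >= min_days
        if ok and weekday_sleep_nights is not None:
            ok = weekday_sleep_nights.get(pid, 0) >= min_weekday_nights
        flags[pid] = bool(ok)
    return flags


def tukey_outlier_flags(values, k: float = 1.5) -> np.ndarray:
    """Tukey fences: flag values beyond ``k`` * IQR outside the quartiles.

    Quartiles use linear-interpolation (type-7) quantiles; NaNs are never
    flagged. With fewer than 4 finite values no fences are computed and a
    warning is issued.
    """
    values = np.asarray(values, dtype=float)
    flags = np.zeros(values.shape, dtype=bool)
    finite = np.isfinite(values)
    if finite.sum() < 4:
        warnings.warn("fewer than 4 values: Tukey fences not computed",
                      stacklevel=2)
        return flags
    q1, q3 = np.percentile(values[finite], [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    flags[finite] = (values[finite] < lo) | (values[finite] > hi)
    return flags
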