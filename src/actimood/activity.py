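"""Physical-activity biomarkers from per-minute steps and METs.

Intensity bands follow the CDC conventions: moderate activity is 3.0 to
6.0 METs, vigorous above 6.0 METs. Sedentary time is waking time at
<= 1.5 METs; "light" activity is operationalized as the disjoint
(1.5, 3.0) MET band while awake, so the four waking bands partition the
day. Weekdays are Monday-Friday by the local calendar.
"""

from __future__ import annotations

import warnings

import numpy as np

from .streams import MINUTES_PER_DAY, ParticipantStreams


def _day_type_subsets(streams: ParticipantStreams, day_set: np.ndarray):
    wd = streams.weekday_mask()
    day_set = np.asarray(day_set, dtype=int)
    return {
        "": day_set,
        ".wd": day_set[wd[day_set]],
        ".we": day_set[~wd[day_set]],
    }


def daily_steps(streams: ParticipantStreams, complete_minute: np.ndarray,
                day_set: np.ndarray) -> dict:
    """Mean daily step total over complete minutes of included days,
    for all days and weekday/weekend subsets. Missing subsets are NaN."""
    steps = np.where(complete_minute, streams.steps, 0.0)
    per_day = steps.reshape(streams.n_days, MINUTES_PER_DAY).sum(axis=1)
    out = {}
    for tag, days in _day_type_subsets(streams, day_set).items():
        out[f"steps{tag}"] = float(per_day[days].mean()) if len(days) else np.nan
    return out


def intensity_minutes(streams: ParticipantStreams, complete_minute: np.ndarray,
                      sleep_mask: np.ndarray, day_set: np.ndarray) -> dict:
    """Mean daily minutes of light/moderate/vigorous activity.

    Bands: light (1.5, 3.0) METs while awake; moderate [3.0, 6.0];
    vigorous > 6.0. Only complete minutes of included days count; a day
    with no MET data is skipped with a warning.
    """
    mets = streams.mets
    valid = complete_minute & np.isfinite(mets)
    awake = valid & ~sleep_mask
    bands = {
        "light": awake & (mets > 1.5) & (mets < 3.0),
        "moderate": valid & (mets >= 3.0) & (mets <= 6.0),
        "vigorous": valid & (mets > 6.0),
    }
    day_set = np.asarray(day_set, dtype=int)
    has_data = valid.reshape(streams.n_days, MINUTES_PER_DAY).any(axis=1)
    usable = day_set[has_data[day_set]]
    if len(usable) < len(day_set):
        warnings.warn(
            f"{streams.pid}: {len(day_set) - len(usable)} day(s) without MET "
            "data skipped", stacklevel=2)
    out = {}
    for name, mask in bands.items():
        per_day = mask.reshape(streams.n_days, MINUTES_PER_DAY).sum(axis=1)
        out[name] = float(per_day[usable].mean()) if len(usable) else np.nan
    return out


def sedentary_minutes(streams: ParticipantStreams, complete_minute: np.ndarray,
                      sleep_mask: np.ndarray, day_set: np.ndarray) -> dict:
    """Mean daily waking minutes at <= 1.5 METs (all/weekday/weekend)."""
    sed = complete_minute & ~sleep_mask & np.isfinite(streams.mets) \
        & (streams.mets <= 1.5)
    per_day = sed.reshape(streams.n_days, MINUTES_PER_DAY).sum(axis=1)
    out = {}
    for tag, days in _day_type_subsets(streams, day_set).items():
        out[f"sedentary{tag}"] = float(per_day[days].mean()) if len(days) else np.nan
    return out


def activity_summary(streams: ParticipantStreams, complete_minute: np.ndarray,
                     sleep_mask: np.ndarray, day_set: np.ndarray) -> dict:
    out = {}
    out.update(daily_steps(streams, complete_minute, day_set))
    out.update(sedentary_minutes(streams, complete_minute, sleep_mask, day_set))
    out.update(intensity_minutes(streams, complete_minute, sleep_mask, day_set))
    return out
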