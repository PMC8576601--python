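"""Physiological biomarkers from the heart-rate stream.

Resting heart rate is the mean heart rate over calendar-aligned 15-min
windows containing zero steps; delta heart rate is the overall mean
minus RHR. Night windows (12-2, 2-4, 4-6 AM) and the 2-4 PM day window
are summarized per night/day and then averaged, so the reported CV is
the mean over nights of (window SD / window mean). RMSSD is computed
from raw samples (gaps break successiveness) and from hourly means.
"""

from __future__ import annotations

import numpy as np

from .streams import MINUTES_PER_DAY, SECONDS_PER_DAY, ParticipantStreams

NIGHT_WINDOWS = {"0002": (0, 2), "0204": (2, 4), "0406": (4, 6)}
DAY_WINDOW = (14, 16)


def _restrict(streams: ParticipantStreams, day_set) -> tuple[np.ndarray, np.ndarray]:
    """HR samples on included days."""
    days = np.zeros(streams.n_days, dtype=bool)
    days[np.asarray(day_set, dtype=int)] = True
    t = streams.hr_t
    keep = days[t // SECONDS_PER_DAY]
    return t[keep], streams.hr[keep]


def minute_means(streams: ParticipantStreams, day_set) -> tuple[np.ndarray, np.ndarray]:
    """Per-minute mean heart rate over included days.

    Returns (minute indices, means); only minutes with samples appear.
    Weighting each complete minute equally makes 5-s and 10-s devices
    comparable.
    """
    t, hr = _restrict(streams, day_set)
    if len(t) == 0:
        return np.array([], dtype=int), np.array([])
    minute = t // 60
    sums = np.bincount(minute, weights=hr, minlength=streams.n_minutes)
    cnts = np.bincount(minute, minlength=streams.n_minutes)
    idx = np.flatnonzero(cnts)
    return idx, sums[idx] / cnts[idx]


def overall_mean_hr(streams: ParticipantStreams, day_set) -> float:
    idx, means = minute_means(streams, day_set)
    return float(means.mean()) if len(means) else np.nan


def resting_heart_rate(streams: ParticipantStreams, day_set) -> float:
    """Mean HR over calendar-aligned, non-overlapping 15-min windows with
    zero total steps; all 15 minutes must be complete. NaN when no
    window qualifies."""
    idx, means = minute_means(streams, day_set)
    if len(idx) == 0:
        return np.nan
    n_win = streams.n_minutes // 15
    hr_sum = np.zeros(n_win)
    hr_cnt = np.zeros(n_win, dtype=int)
    np.add.at(hr_sum, idx // 15, means)
    np.add.at(hr_cnt, idx // 15, 1)
    step_sum = streams.steps.reshape(n_win, 15).sum(axis=1)
    ok = (hr_cnt == 15) & (step_sum == 0)
    if not ok.any():
        return np.nan
    return float((hr_sum[ok] / 15).mean())


def delta_heart_rate(overall: float, rhr: float) -> float:
    if not (np.isfinite(overall) and np.isfinite(rhr)):
        return np.nan
    return overall - rhr


def window_hr_stats(streams: ParticipantStreams, day_set,
                    window: tuple[float, float]) -> dict:
    """Mean/SD/CV of heart rate in a clock-time window.

    Per included day the window's samples give a mean and SD (ddof=1);
    the reported statistics average these per-day values across days.
    """
    t, hr = _restrict(streams, day_set)
    out = {"mean": np.nan, "sd": np.nan, "cv": np.nan}
    if len(t) == 0:
        return out
    hour = (t % SECONDS_PER_DAY) / 3600.0
    in_win = (hour >= window[0]) & (hour < window[1])
    if not in_win.any():
        return out
    day = (t[in_win] // SECONDS_PER_DAY).astype(int)
    vals = hr[in_win]
    means, sds, cvs = [], [], []
    for d in np.unique(day):
        v = vals[day == d]
        m = v.mean()
        means.append(m)
        if len(v) >= 2:
            s = v.std(ddof=1)
            sds.append(s)
            if m > 0:
                cvs.append(s / m)
    out["mean"] = float(np.mean(means))
    out["sd"] = float(np.mean(sds)) if sds else np.nan
    out["cv"] = float(np.mean(cvs)) if cvs else np.nan
    return out


def rmssd(streams: ParticipantStreams, day_set, mode: str = "raw") -> float:
    """Root mean square of successive differences of heart rate.

    ``raw`` uses consecutive samples (a gap of more than twice the
    typical sampling interval, or a day boundary between included days,
    breaks successiveness); ``hourly`` uses hourly mean values with
    only adjacent hours paired.
    """
    t, hr = _restrict(streams, day_set)
    if len(hr) < 2:
        return np.nan
    if mode == "raw":
        dt = np.diff(t)
        max_gap = 2 * np.median(dt)
        diffs = np.diff(hr)[dt <= max_gap]
    elif mode == "hourly":
        hour_idx = t // 3600
        sums = np.bincount(hour_idx, weights=hr)
        cnts = np.bincount(hour_idx)
        present = np.flatnonzero(cnts)
        means = sums[present] / cnts[present]
        adjacent = np.diff(present) == 1
        diffs = np.diff(means)[adjacent]
    else:
        raise ValueError("mode must be 'raw' or 'hourly'")
    if len(diffs) == 0:
        return np.nan
    return float(np.sqrt(np.mean(diffs**2)))


def heart_rate_summary(streams: ParticipantStreams, day_set) -> dict:
    """All heart-rate biomarkers as a flat dict of dotted names."""
    out = {}
    overall = overall_mean_hr(streams, day_set)
    rhr = resting_heart_rate(streams, day_set)
    out["HR"] = overall
    out["RHR"] = rhr
    out["deltaHR"] = delta_heart_rate(overall, rhr)
    day = window_hr_stats(streams, day_set, DAY_WINDOW)
    out["DHR"] = day["mean"]
    out["DHR.sd"] = day["sd"]
    out["DHR.cv"] = day["cv"]
    for name, win in NIGHT_WINDOWS.items():
        stats = window_hr_stats(streams, day_set, win)
        out[f"NHR.{name}"] = stats["mean"]
        out[f"NHR.{name}.sd"] = stats["sd"]
        out[f"NHR.{name}.cv"] = stats["cv"]
    out["RMSSD.raw"] = rmssd(streams, day_set, "raw")
    out["RMSSD.hourly"] = rmssd(streams, day_set, "hourly")
    return out
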