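"""Sleep biomarkers from 30-s stage epochs.

Contiguous stage epochs form device sleep records; each night's main
episode is the longest record overlapping the 8 PM-noon window, naps are
discarded. Episodes are assigned to the calendar date of the sleep
offset (the wake-day), so "weekday nights" are nights ending on a
Monday-Friday morning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .streams import SECONDS_PER_DAY, ParticipantStreams

EPOCH_S = 30
EPOCH_MIN = 0.5


@dataclass
class SleepEpisode:
    """One contiguous device sleep record and its derived metrics."""

    onset_s: int                 # seconds from tracking start (bedtime)
    stages: np.ndarray           # ordered 30-s stage labels
    wake_day: int                # tracking-day index of the sleep offset
    weekday: bool                # wake-day falls on Monday-Friday

    @property
    def offset_s(self) -> int:
        return self.onset_s + len(self.stages) * EPOCH_S

    @property
    def time_in_bed_min(self) -> float:
        return len(self.stages) * EPOCH_MIN

    def metrics(self) -> dict | None:
        """TIB, TST, SE, SOL and WASO in minutes (SE a proportion).

        TST is time in bed minus total wake time; SOL the time to the
        first non-wake epoch; WASO the wake minutes whose epoch index
        lies in the middle half of the episode, ``[floor(N/4),
        floor(3N/4))``. An all-wake episode has no sleep onset and is
        dropped with a warning (returns None).
        """
        stages = self.stages
        n = len(stages)
        wake = stages == "wake"
        if wake.all():
            warnings.warn("all-wake sleep episode dropped", stacklevel=2)
            return None
        tib = n * EPOCH_MIN
        wake_min = float(wake.sum()) * EPOCH_MIN
        tst = tib - wake_min
        sol = float(np.argmax(~wake)) * EPOCH_MIN
        mid = wake[n // 4: (3 * n) // 4]
        waso = float(mid.sum()) * EPOCH_MIN
        return {"tib": tib, "tst": tst, "se": tst / tib, "sol": sol,
                "waso": waso}


def sleep_records(streams: ParticipantStreams) -> list[SleepEpisode]:
    """Split the stage stream into contiguous device records."""
    t, stages = streams.sleep_t, streams.sleep_stage
    if len(t) == 0:
        return []
    breaks = np.flatnonzero(np.diff(t) != EPOCH_S) + 1
    episodes = []
    for seg_t, seg_s in zip(np.split(t, breaks), np.split(stages, breaks)):
        offset = int(seg_t[-1]) + EPOCH_S
        wake_day = min(offset // SECONDS_PER_DAY, streams.n_days - 1)
        episodes.append(SleepEpisode(
            onset_s=int(seg_t[0]), stages=seg_s, wake_day=int(wake_day),
            weekday=streams.day_of_week(int(wake_day)) < 5,
        ))
    return episodes


def detect_main_sleep(records: list[SleepEpisode], night: int
                      ) -> SleepEpisode | None:
    """The night's main episode: longest record overlapping the window
    from 8 PM of day ``night - 1`` to noon of day ``night``."""
    w0 = (night - 1) * SECONDS_PER_DAY + 20 * 3600
    w1 = night * SECONDS_PER_DAY + 12 * 3600
    best = None
    for ep in records:
        if ep.offset_s <= w0 or ep.onset_s >= w1:
            continue
        if best is None or len(ep.stages) > len(best.stages):
            best = ep
    return best


def main_episodes(streams: ParticipantStreams,
                  day_set: np.ndarray | None = None) -> list[SleepEpisode]:
    """Main nightly episodes, optionally restricted to wake-days in
    ``day_set``."""
    records = sleep_records(streams)
    keep = None if day_set is None else set(int(d) for d in day_set)
    out = []
    for night in range(streams.n_days):
        ep = detect_main_sleep(records, night)
        if ep is None or ep.wake_day != night:
            continue
        if keep is not None and night not in keep:
            continue
        out.append(ep)
    return out


def _midpoint_hours(ep: SleepEpisode) -> float:
    """Episode midpoint in hours since midnight of the wake-day
    (negative when the midpoint falls before midnight)."""
    mid_s = ep.onset_s + (len(ep.stages) * EPOCH_S) / 2.0
    return (mid_s - ep.wake_day * SECONDS_PER_DAY) / 3600.0


def _offset_hours(ep: SleepEpisode) -> float:
    return (ep.offset_s - ep.wake_day * SECONDS_PER_DAY) / 3600.0


def timing_metrics(episodes: list[SleepEpisode], min_nights: int = 3) -> dict:
    """Mean and SD of sleep offset and midpoint (hours since midnight).

    Pre-midnight midpoints enter the average as negative hours and the
    mean is normalized back to [0, 24); fewer than ``min_nights``
    episodes yield NaNs.
    """
    out = {"offset": np.nan, "offset.sd": np.nan,
           "midpoint": np.nan, "midpoint.sd": np.nan}
    if len(episodes) < min_nights:
        return out
    offs = np.array([_offset_hours(ep) for ep in episodes])
    mids = np.array([_midpoint_hours(ep) for ep in episodes])
    out["offset"] = float(offs.mean() % 24.0)
    out["offset.sd"] = float(offs.std(ddof=1))
    out["midpoint"] = float(mids.mean() % 24.0)
    out["midpoint.sd"] = float(mids.std(ddof=1))
    return out


def _mean_cv(values: np.ndarray) -> tuple[float, float]:
    if len(values) == 0:
        return np.nan, np.nan
    mean = float(values.mean())
    if len(values) < 2:
        return mean, np.nan
    sd = float(values.std(ddof=1))
    cv = sd / mean if mean > 0 else np.nan
    return mean, cv


def sleep_summary(streams: ParticipantStreams,
                  day_set: np.ndarray | None = None,
                  min_nights: int = 3) -> dict:
    """Per-participant sleep biomarkers: mean and CV of TIB/TST/SE/SOL/
    WASO plus offset/midpoint timing, for all nights and weekday nights.

    Returns a flat dict keyed ``sleep.<metric>[.wd][.cv|.sd]``.
    """
    episodes = main_episodes(streams, day_set)
    out = {}
    for tag, eps in (("", episodes), (".wd", [e for e in episodes if e.weekday])):
        rows = [m for m in (ep.metrics() for ep in eps) if m is not None]
        for name in ("tib", "tst", "se", "sol", "waso"):
            vals = np.array([r[name] for r in rows])
            if len(vals) < min_nights:
                mean, cv = np.nan, np.nan
            else:
                mean, cv = _mean_cv(vals)
            out[f"sleep.{name}{tag}"] = mean
            out[f"sleep.{name}{tag}.cv"] = cv
        timing = timing_metrics(eps, min_nights=min_nights)
        out[f"sleep.offset{tag}"] = timing["offset"]
        out[f"sleep.offset{tag}.sd"] = timing["offset.sd"]
        out[f"sleep.midpoint{tag}"] = timing["midpoint"]
        out[f"sleep.midpoint{tag}.sd"] = timing["midpoint.sd"]
    return out


def weekday_night_count(streams: ParticipantStreams) -> int:
    """Number of weekday main sleep episodes (participant-level QC input)."""
    return sum(1 for ep in main_episodes(streams) if ep.weekday)


def sleep_minute_mask(streams: ParticipantStreams) -> np.ndarray:
    """Boolean per-minute mask of time inside any main sleep episode."""
    mask = np.zeros(streams.n_minutes, dtype=bool)
    for ep in main_episodes(streams):
        m0 = ep.onset_s // 60
        m1 = min(int(np.ceil(ep.offset_s / 60)), streams.n_minutes)
        mask[m0:m1] = True
    return mask
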