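"""In-memory container for one participant's raw wearable streams.

All streams share a common local-clock origin (``start``, a midnight).
Minute-resolution streams (steps, METs) are dense numpy arrays; heart
rate and sleep stages are sparse, addressed by offsets in seconds from
``start``. Timestamps are timezone-naive local clock throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SLEEP_STAGES = ("wake", "light", "deep", "rem")

SECONDS_PER_DAY = 86_400
MINUTES_PER_DAY = 1_440


@dataclass
class ParticipantStreams:
    """Raw multirate time series for a single participant.

    Attributes
    ----------
    pid : str
        Participant identifier.
    start : pandas.Timestamp
        Local midnight at which the tracking period begins.
    n_days : int
        Length of the tracking period in whole calendar days.
    steps : numpy.ndarray
        Per-minute step counts, length ``n_days * 1440``.
    mets : numpy.ndarray
        Per-minute METs, same length as ``steps``.
    hr_t : numpy.ndarray
        Heart-rate sample offsets in seconds from ``start`` (strictly
        increasing).
    hr : numpy.ndarray
        Heart-rate samples in bpm, same length as ``hr_t``.
    sleep_t : numpy.ndarray
        Sleep-epoch offsets in seconds from ``start`` (30-s grid,
        strictly increasing); epochs exist only while the device records
        a sleep episode.
    sleep_stage : numpy.ndarray
        Stage label per epoch, one of ``wake/light/deep/rem``.
    wear_gaps : list[tuple[int, int]]
        Generator ledger of injected non-wear intervals, as
        ``(start_s, end_s)`` offsets. Empty for ingested data.
    """

    pid: str
    start: pd.Timestamp
    n_days: int
    steps: np.ndarray
    mets: np.ndarray
    hr_t: np.ndarray
    hr: np.ndarray
    sleep_t: np.ndarray
    sleep_stage: np.ndarray
    wear_gaps: list = field(default_factory=list)

    def __post_init__(self):
        self.start = pd.Timestamp(self.start)
        n_min = self.n_days * MINUTES_PER_DAY
        if len(self.steps) != n_min or len(self.mets) != n_min:
            raise ValueError(
                f"{self.pid}: minute streams must have length {n_min}"
            )
        self.validate()

    def validate(self):
        if np.nanmin(self.steps, initial=0) < 0:
            raise ValueError(f"{self.pid}: negative step counts")
        if np.nanmin(self.mets, initial=0) < 0:
            raise ValueError(f"{self.pid}: negative METs")
        if len(self.hr) and not ((self.hr > 20) & (self.hr < 250)).all():
            raise ValueError(f"{self.pid}: heart rate outside (20, 250) bpm")
        for t in (self.hr_t, self.sleep_t):
            if len(t) > 1 and not (np.diff(t) > 0).all():
                raise ValueError(f"{self.pid}: timestamps not strictly increasing")
        bad = set(np.unique(self.sleep_stage)) - set(SLEEP_STAGES)
        if bad:
            raise ValueError(f"{self.pid}: unknown sleep stages {sorted(bad)}")

    @property
    def n_minutes(self) -> int:
        return self.n_days * MINUTES_PER_DAY

    def day_of_week(self, day: int) -> int:
        """Weekday index (Monday=0) of tracking day ``day``."""
        return (self.start.dayofweek + day) % 7

    def weekday_mask(self) -> np.ndarray:
        """Boolean per-day mask, True on Monday-Friday."""
        dows = (self.start.dayofweek + np.arange(self.n_days)) % 7
        return dows < 5

    # -- pandas views (used by CSV IO and plotting) -------------------

    def steps_series(self) -> pd.Series:
        idx = self.start + pd.to_timedelta(np.arange(self.n_minutes), unit="m")
        return pd.Series(self.steps, index=idx, name="steps")

    def mets_series(self) -> pd.Series:
        idx = self.start + pd.to_timedelta(np.arange(self.n_minutes), unit="m")
        return pd.Series(self.mets, index=idx, name="mets")

    def hr_series(self) -> pd.Series:
        idx = self.start + pd.to_timedelta(self.hr_t, unit="s")
        return pd.Series(self.hr, index=idx, name="bpm")

    def sleep_series(self) -> pd.Series:
        idx = self.start + pd.to_timedelta(self.sleep_t, unit="s")
        return pd.Series(self.sleep_stage, index=idx, name="stage")
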