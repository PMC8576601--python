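"""CSV dialects for wearable streams and survey outcomes.

One file per stream per participant, columns ``timestamp,value``
(``timestamp,stage`` for sleep), plus a cohort manifest CSV mapping
participant id to file paths. The synthetic generator writes the same
dialect the ingestion functions read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .streams import MINUTES_PER_DAY, ParticipantStreams

STREAM_KINDS = ("steps", "mets", "heart_rate", "sleep")


def write_participant_csvs(streams: ParticipantStreams, directory) -> dict:
    """Write one CSV per stream; returns kind -> path mapping."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    frames = {
        "steps": streams.steps_series(),
        "mets": streams.mets_series(),
        "heart_rate": streams.hr_series(),
        "sleep": streams.sleep_series(),
    }
    for kind, series in frames.items():
        path = directory / f"{streams.pid}_{kind}.csv"
        df = series.rename_axis("timestamp").reset_index()
        df.columns = ["timestamp", "stage" if kind == "sleep" else "value"]
        df.to_csv(path, index=False)
        paths[kind] = path
    return paths


def write_cohort(streams: dict, outcomes: pd.DataFrame, directory) -> Path:
    """Write a full cohort (streams, outcomes, manifest); returns the
    manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for pid, s in streams.items():
        paths = write_participant_csvs(s, directory / "streams")
        rows.append({"pid": pid,
                     **{k: str(p.relative_to(directory)) for k, p in paths.items()}})
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    outcomes.to_csv(directory / "outcomes.csv")
    return manifest


def read_participant_csvs(pid: str, paths: dict, base: Path | None = None
                          ) -> ParticipantStreams:
    """Rebuild :class:`ParticipantStreams` from the CSV dialect."""
    def _load(kind):
        p = Path(paths[kind])
        if base is not None and not p.is_absolute():
            p = Path(base) / p
        df = pd.read_csv(p, parse_dates=["timestamp"])
        return df

    steps_df = _load("steps")
    mets_df = _load("mets")
    hr_df = _load("heart_rate")
    sleep_df = _load("sleep")

    start = steps_df["timestamp"].iloc[0].normalize()
    n_days = int(np.ceil(
        ((steps_df["timestamp"].iloc[-1] - start).total_seconds() + 60) / 86400))
    n_min = n_days * MINUTES_PER_DAY

    def _minute_array(df):
        arr = np.full(n_min, np.nan)
        idx = ((df["timestamp"] - start).dt.total_seconds() // 60).astype(int)
        arr[idx] = df.iloc[:, 1].to_numpy(dtype=float)
        return np.nan_to_num(arr)

    hr_t = ((hr_df["timestamp"] - start).dt.total_seconds()).astype(np.int64)
    sleep_t = ((sleep_df["timestamp"] - start).dt.total_seconds()).astype(np.int64)
    return ParticipantStreams(
        pid=pid, start=start, n_days=n_days,
        steps=_minute_array(steps_df), mets=_minute_array(mets_df),
        hr_t=hr_t.to_numpy(), hr=hr_df["value"].to_numpy(dtype=float),
        sleep_t=sleep_t.to_numpy(),
        sleep_stage=sleep_df["stage"].to_numpy(dtype=object),
    )


def read_cohort(directory) -> tuple[dict, pd.DataFrame]:
    """Read a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    streams = {}
    for _, row in manifest.iterrows():
        paths = {k: row[k] for k in STREAM_KINDS}
        streams[row["pid"]] = read_participant_csvs(row["pid"], paths,
                                                    base=directory)
    outcomes = pd.read_csv(directory / "outcomes.csv", index_col="pid")
    return streams, outcomes
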