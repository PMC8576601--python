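"""Per-participant digital-biomarker extraction.

Combines the activity, sleep, circadian and heart-rate feature families
into one named vector per participant with dotted biomarker names
(e.g. ``IS.st.wd``, ``NHR.0406.cv``, ``AC.st.15m``). Only minutes flagged
complete by QC, on days passing the 20-h rule, enter any feature.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import circadian
from .activity import activity_summary
from .heart_rate import heart_rate_summary
from .qc import CompletenessReport, completeness_mask, filter_days
from .sleep import sleep_minute_mask, sleep_summary
from .streams import MINUTES_PER_DAY, SECONDS_PER_DAY, ParticipantStreams

PEAK_PARAMS = dict(lag=12, threshold=2.0, influence=0.1)  # 15-min bins, 3-h lag
FAMILIES = ("activity", "sleep", "circadian", "heart_rate")


def binned_steps(streams: ParticipantStreams, complete_minute: np.ndarray,
                 day_set: np.ndarray, bin_minutes: int) -> np.ndarray:
    """(n_days_selected, bins_per_day) matrix of step totals per bin.

    Bin values are the mean over complete minutes scaled to the bin
    length; bins without complete minutes are NaN.
    """
    bins_per_day = MINUTES_PER_DAY // bin_minutes
    steps = np.where(complete_minute, streams.steps, 0.0)
    sums = steps.reshape(streams.n_days, bins_per_day, bin_minutes).sum(axis=2)
    cnts = complete_minute.reshape(
        streams.n_days, bins_per_day, bin_minutes).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(cnts > 0, sums / cnts * bin_minutes, np.nan)
    return vals[np.asarray(day_set, dtype=int)]


def binned_hr(streams: ParticipantStreams, day_set: np.ndarray,
              bin_minutes: int) -> np.ndarray:
    """(n_days_selected, bins_per_day) matrix of mean heart rate per bin."""
    bins_per_day = MINUTES_PER_DAY // bin_minutes
    n_bins = streams.n_days * bins_per_day
    idx = streams.hr_t // (bin_minutes * 60)
    sums = np.bincount(idx, weights=streams.hr, minlength=n_bins)
    cnts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(cnts > 0, sums / cnts, np.nan)
    return vals.reshape(streams.n_days, bins_per_day)[
        np.asarray(day_set, dtype=int)]


def _circadian_block(matrix_by_bin: dict, src: str, tag: str) -> dict:
    """Circadian features for one source/day-type from binned matrices.

    ``matrix_by_bin`` maps bin width (minutes) -> (days, bins) matrix;
    the 60-min matrix drives the nonparametric and cosinor metrics.
    """
    out = {}
    hourly = matrix_by_bin[60]
    suffix = f".{src}{tag}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out[f"IS{suffix}"] = circadian.interdaily_stability(hourly)
        out[f"IV{suffix}"] = circadian.intradaily_variability(hourly)
        out[f"ICV{suffix}"] = circadian.interdaily_cv(hourly)
        m10, l5, ra = circadian.m10_l5_ra(hourly)
    out[f"M10{suffix}"] = m10
    out[f"L5{suffix}"] = l5
    out[f"RA{suffix}"] = ra
    for bin_min in (15, 30, 60):
        mat = matrix_by_bin[bin_min]
        out[f"AC.{src}.{bin_min}m{tag}"] = circadian.day_lag_autocorrelation(
            mat.reshape(-1), mat.shape[1])
    # cosinor on the hourly series (hour-center clock times)
    d, p = hourly.shape
    t = np.tile(np.arange(p) + 0.5, d)
    try:
        fit = circadian.fit_extended_cosinor(t, hourly.reshape(-1))
    except ValueError:
        fit = None
    names = ("mesor", "amp", "acro", "alpha", "beta", "F")
    if fit is None or not fit.converged:
        for nm in names:
            out[f"{nm}{suffix}"] = np.nan
    else:
        out[f"mesor{suffix}"] = fit.mesor
        out[f"amp{suffix}"] = fit.amplitude
        out[f"acro{suffix}"] = fit.acrophase
        out[f"alpha{suffix}"] = fit.alpha
        out[f"beta{suffix}"] = fit.beta
        out[f"F{suffix}"] = fit.pseudo_f
    # peaks on the 15-min series
    mat = matrix_by_bin[15]
    try:
        mean, sd = circadian.peaks_per_day(mat.reshape(-1), mat.shape[1],
                                           **PEAK_PARAMS)
    except ValueError:
        mean, sd = np.nan, np.nan
    out[f"peaks{suffix}"] = mean
    out[f"peaks{suffix}.sd"] = sd
    return out


def extract_features(streams: ParticipantStreams,
                     report: CompletenessReport | None = None,
                     min_hours: float = 20.0,
                     families: tuple = FAMILIES) -> pd.Series:
    """Extract the full biomarker vector for one participant.

    Days failing the completeness rule are excluded everywhere; an empty
    day set yields an all-NaN vector. ``families`` restricts the roster
    to the named feature families.
    """
    if report is None:
        report = completeness_mask(streams)
    day_set = filter_days(report, min_hours)
    wd_mask = streams.weekday_mask()
    day_set_wd = day_set[wd_mask[day_set]]

    out = {}
    sleep_mask = sleep_minute_mask(streams)
    if "activity" in families:
        if len(day_set):
            out.update(activity_summary(streams, report.complete_minute,
                                        sleep_mask, day_set))
        else:
            for k in ("steps", "steps.wd", "steps.we", "sedentary",
                      "sedentary.wd", "sedentary.we", "light", "moderate",
                      "vigorous"):
                out[k] = np.nan
    if "sleep" in families:
        out.update(sleep_summary(streams, day_set if len(day_set) else None))
    if "circadian" in families:
        for tag, days in (("", day_set), (".wd", day_set_wd)):
            if len(days) >= 2:
                st = {b: binned_steps(streams, report.complete_minute, days, b)
                      for b in (15, 30, 60)}
                hr = {b: binned_hr(streams, days, b) for b in (15, 30, 60)}
                out.update(_circadian_block(st, "st", tag))
                out.update(_circadian_block(hr, "hr", tag))
            else:
                for src in ("st", "hr"):
                    blank = _blank_circadian(src, tag)
                    out.update(blank)
    if "heart_rate" in families:
        if len(day_set):
            out.update(heart_rate_summary(streams, day_set))
        else:
            for k in _HR_NAMES:
                out[k] = np.nan
    return pd.Series(out, name=streams.pid, dtype=float)


_HR_NAMES = ("HR", "RHR", "deltaHR", "DHR", "DHR.sd", "DHR.cv",
             "NHR.0002", "NHR.0002.sd", "NHR.0002.cv",
             "NHR.0204", "NHR.0204.sd", "NHR.0204.cv",
             "NHR.0406", "NHR.0406.sd", "NHR.0406.cv",
             "RMSSD.raw", "RMSSD.hourly")


def _blank_circadian(src: str, tag: str) -> dict:
    suffix = f".{src}{tag}"
    names = [f"{nm}{suffix}" for nm in
             ("IS", "IV", "ICV", "M10", "L5", "RA",
              "mesor", "amp", "acro", "alpha", "beta", "F")]
    names += [f"AC.{src}.{b}m{tag}" for b in (15, 30, 60)]
    names += [f"peaks{suffix}", f"peaks{suffix}.sd"]
    return {n: np.nan for n in names}


def extract_cohort_features(streams: dict, reports: dict | None = None,
                            min_hours: float = 20.0,
                            families: tuple = FAMILIES) -> pd.DataFrame:
    """Feature matrix (participants x biomarkers) for a cohort."""
    rows = []
    for pid, s in streams.items():
        rep = reports.get(pid) if reports else None
        rows.append(extract_features(s, rep, min_hours, families))
    return pd.DataFrame(rows)
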