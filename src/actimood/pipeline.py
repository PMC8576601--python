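"""End-to-end pipeline: generate/ingest -> QC -> features -> associations
-> screening models, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import platform
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .association import spearman_screen
from .config import CohortConfig, ConfigurationError
from .features import FAMILIES, extract_features
from .phq9 import assign_labels, contrasted_subsample
from .qc import completeness_mask, filter_days, filter_participants, \
    tukey_outlier_flags
from .screening import ScreeningModel, select_features
from .sleep import weekday_night_count
from .synthetic import generate_cohort


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    cohort: CohortConfig
    min_hours: float = 20.0
    min_days: int = 10
    families: tuple = FAMILIES
    cutoff_rules: tuple = ("A",)
    selection_rules: tuple = ("B",)
    contrasted: bool = True
    cv_folds: int = 4
    cv_repeats: int = 25
    cv_seed: int = 0
    subsample_seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cohort = d.pop("cohort", None)
        if cohort is None:
            raise ConfigurationError("pipeline config needs a 'cohort' section")
        if isinstance(cohort, dict):
            cohort = CohortConfig(**cohort)
        for key in ("families", "cutoff_rules", "selection_rules"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(cohort=cohort, **d)


@dataclass
class PipelineReport:
    """Bundle of everything a pipeline run produces."""

    features: pd.DataFrame
    outcomes: pd.DataFrame
    qc: pd.DataFrame
    associations: pd.DataFrame
    screening: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def run_qc(streams: dict, min_hours: float = 20.0, min_days: int = 10
           ) -> tuple[pd.DataFrame, dict]:
    """Apply the day/participant completeness rules and Tukey screens.

    Returns a per-participant QC table and the per-participant
    complete-day sets.
    """
    day_sets, nights, rows = {}, {}, {}
    for pid, s in streams.items():
        rep = completeness_mask(s)
        days = filter_days(rep, min_hours)
        day_sets[pid] = days
        nights[pid] = weekday_night_count(s)
        if len(days):
            steps = np.where(rep.complete_minute, s.steps, 0.0)
            per_day = steps.reshape(s.n_days, -1).sum(axis=1)[days]
            mean_steps = float(per_day.mean())
            hr_days = np.isin(s.hr_t // 86_400, days)
            mean_hr = float(s.hr[hr_days].mean()) if hr_days.any() else np.nan
        else:
            mean_steps, mean_hr = np.nan, np.nan
        rows[pid] = {"complete_days": len(days), "weekday_nights": nights[pid],
                     "mean_daily_steps": mean_steps, "mean_hr": mean_hr}
    qc = pd.DataFrame.from_dict(rows, orient="index").rename_axis("pid")
    flags = filter_participants(day_sets, nights, min_days=min_days)
    qc["enough_days"] = [flags[p] for p in qc.index]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        qc["hr_outlier"] = tukey_outlier_flags(qc["mean_hr"])
        qc["steps_outlier"] = tukey_outlier_flags(qc["mean_daily_steps"])
    qc["included"] = qc["enough_days"] & ~qc["hr_outlier"] & ~qc["steps_outlier"]
    return qc, day_sets


def run_pipeline(config: PipelineConfig, streams=None, outcomes=None
                 ) -> PipelineReport:
    """Execute the full analysis and return the report bundle.

    Streams/outcomes may be passed in (e.g. read from disk); by default
    they are generated from ``config.cohort``. When ``output_dir`` is
    set, the feature matrix, QC table, association table, performance
    tables and a manifest are written there.
    """
    if streams is None or outcomes is None:
        streams, outcomes = generate_cohort(config.cohort)

    qc, _ = run_qc(streams, config.min_hours, config.min_days)
    included = qc.index[qc["included"]]
    feats = pd.DataFrame([
        extract_features(streams[pid], min_hours=config.min_hours,
                         families=config.families)
        for pid in included])
    outcomes = outcomes.loc[included]

    assoc = spearman_screen(feats, outcomes["phq9_avg"])

    screening = {}
    for sel_rule in config.selection_rules:
        chosen = select_features(assoc, sel_rule)
        for cutoff in config.cutoff_rules:
            key = f"sel{sel_rule}_cut{cutoff}"
            if config.contrasted:
                sub = contrasted_subsample(outcomes, cutoff,
                                           seed=config.subsample_seed)
                X = feats.loc[sub.index, chosen]
                y = sub["label"]
            else:
                y = assign_labels(outcomes, cutoff)
                keep = y != "excluded"
                X, y = feats.loc[keep, chosen], y[keep]
            model = ScreeningModel(X, y, task="classify")
            screening[key] = model.fit(folds=config.cv_folds,
                                       repeats=config.cv_repeats,
                                       seed=config.cv_seed)

    manifest = _manifest(config, feats)
    report = PipelineReport(features=feats, outcomes=outcomes, qc=qc,
                            associations=assoc, screening=screening,
                            manifest=manifest)
    if config.output_dir:
        _write_report(report, config)
    return report


def _manifest(config: PipelineConfig, feats: pd.DataFrame) -> dict:
    from . import __version__
    cfg = asdict(config)
    cfg.pop("output_dir", None)  # where results land is not analysis state
    cfg_json = json.dumps(cfg, sort_keys=True, default=str)
    return {
        "version": __version__,
        "python": platform.python_version(),
        "config": cfg,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seeds": {"cohort": config.cohort.seed, "cv": config.cv_seed,
                  "subsample": config.subsample_seed},
        "n_features": int(feats.shape[1]),
        "n_participants": int(feats.shape[0]),
    }


def _write_report(report: PipelineReport, config: PipelineConfig):
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.features.rename_axis("pid").to_csv(out / "features.csv")
    report.qc.to_csv(out / "qc.csv")
    report.associations.rename_axis("biomarker").to_csv(out / "associations.csv")
    perf_rows = []
    for key, res in report.screening.items():
        row = {"model": key, "nir": res.nir, **res.metrics}
        perf_rows.append(row)
        imp = res.feature_importances.rename_axis("biomarker")
        imp.to_frame("importance").to_csv(out / f"importance_{key}.csv")
    if perf_rows:
        pd.DataFrame(perf_rows).set_index("model").to_csv(out / "performance.csv")
    (out / "manifest.json").write_text(
        json.dumps(report.manifest, indent=2, sort_keys=True, default=str))
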