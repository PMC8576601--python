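"""Gradient-boosted depression screening models with repeated k-fold CV.

Features enter through correlation-threshold selection frozen on the
full sample; models are extreme gradient boosting with the DART booster
(depth 3, 200 rounds, learning rate 0.1, drop rate 0.1 by default).
Classification performance (accuracy, sensitivity, specificity, PPV,
NPV, Cohen kappa, AUC, alongside the no-information rate) and
regression performance (R^2, Pearson r, RMSE, MAE) are averaged over
the holdout folds of a repeated stratified 4-fold x 25-repeat split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedKFold, RepeatedStratifiedKFold
import xgboost as xgb

DEFAULT_BOOSTER_PARAMS = dict(
    booster="dart",
    max_depth=3,
    n_estimators=200,
    learning_rate=0.1,
    rate_drop=0.1,
    tree_method="hist",
    n_jobs=1,
)

SELECTION_RULES = ("A", "B", "C")
DEMOGRAPHICS = ("age", "gender", "ethnicity", "marital")


def select_features(assoc: pd.DataFrame, rule: str) -> list:
    """Correlation-threshold feature selection on raw Spearman p values.

    Rules: A — p < .01; B — p < .05; C — .01 <= p < .05 (B minus A).
    The returned set is frozen on the full sample and reused unchanged
    for every subsample model. An empty selection raises with advice to
    relax the rule.
    """
    if len(assoc) == 0 or "p" not in assoc:
        raise ValueError("empty association table: run the Spearman screen "
                         "on a cohort with at least 10 complete pairs first")
    p = assoc["p"]
    if rule == "A":
        chosen = assoc.index[p < 0.01]
    elif rule == "B":
        chosen = assoc.index[p < 0.05]
    elif rule == "C":
        chosen = assoc.index[(p >= 0.01) & (p < 0.05)]
    else:
        raise ValueError(f"unknown selection rule {rule!r}; "
                         f"expected one of {SELECTION_RULES}")
    chosen = list(chosen)
    if not chosen:
        raise ValueError(
            f"selection rule {rule} selected no features; relax the rule "
            "or use a larger sample")
    return chosen


def performance_from_confusion(tp: int, fp: int, fn: int, tn: int) -> dict:
    """Confusion-matrix metrics; divisions by zero yield NaN markers.

    Kappa uses the margin-based chance agreement
    ``pe = (pos_true*pos_pred + neg_true*neg_pred) / total^2``.
    """
    for v in (tp, fp, fn, tn):
        if v < 0:
            raise ValueError("confusion counts must be nonnegative")
    total = tp + fp + fn + tn
    if total == 0:
        raise ValueError("empty confusion matrix")

    def _div(a, b):
        return a / b if b > 0 else np.nan

    po = (tp + tn) / total
    pe = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / total**2
    kappa = (po - pe) / (1 - pe) if pe != 1 else np.nan
    return {
        "accuracy": po,
        "sensitivity": _div(tp, tp + fn),
        "specificity": _div(tn, tn + fp),
        "ppv": _div(tp, tp + fp),
        "npv": _div(tn, tn + fn),
        "kappa": kappa,
    }


@dataclass
class ScreeningResults:
    """Cross-validated performance of a screening model.

    ``metrics`` holds the per-holdout-fold mean of each metric (NaN
    folds are skipped in the average, mirroring the N/A convention for
    undefined rates); ``metrics_sd`` the across-fold SD;
    ``feature_importances`` the gain-based importances normalized to
    sum 1 and averaged across folds.
    """

    task: str
    n_obs: int
    n_features: int
    folds: int
    repeats: int
    nir: float | None
    metrics: dict = field(default_factory=dict)
    metrics_sd: dict = field(default_factory=dict)
    feature_importances: pd.Series | None = None
    fold_metrics: pd.DataFrame | None = None

    def summary(self) -> str:
        head = (f"{'Classification' if self.task == 'classify' else 'Regression'}"
                f" screening model — DART gradient boosting")
        lines = [head,
                 f"  n={self.n_obs}, features={self.n_features}, "
                 f"{self.folds}-fold x {self.repeats} repeats"]
        if self.nir is not None:
            lines.append(f"  NIR            : {self.nir:.3f}")
        for k, v in self.metrics.items():
            sd = self.metrics_sd.get(k, np.nan)
            lines.append(f"  {k:<15}: {v:.3f} (SD {sd:.3f})")
        if self.feature_importances is not None:
            lines.append("  top features   : " + ", ".join(
                f"{n} ({v:.2f})"
                for n, v in self.feature_importances.head(5).items()))
        return "\n".join(lines)


class ScreeningModel:
    """DART-boosted prediction of depression status or symptom severity.

    Parameters
    ----------
    X : DataFrame
        Feature matrix (participants x biomarkers); NaNs are handled
        natively by the booster.
    y : Series or array
        Binary labels (``depressed``/``healthy`` strings or 0/1) for
        classification, continuous outcome for regression.
    task : {"classify", "regress"}
    params : dict, optional
        Overrides of the booster defaults.
    """

    def __init__(self, X: pd.DataFrame, y, task: str = "classify",
                 params: dict | None = None):
        if task not in ("classify", "regress"):
            raise ValueError("task must be 'classify' or 'regress'")
        self.X = X.astype(float)
        self.task = task
        self.params = {**DEFAULT_BOOSTER_PARAMS, **(params or {})}
        y = pd.Series(y, index=X.index) if not isinstance(y, pd.Series) else y
        if task == "classify":
            if y.dtype == object:
                y = (y == "depressed").astype(int)
            classes = np.unique(y)
            if len(classes) != 2:
                raise ValueError("classification needs both classes present")
        self.y = y.astype(float if task == "regress" else int)

    @property
    def nir(self) -> float | None:
        """No-information rate: prevalence of the majority class."""
        if self.task != "classify":
            return None
        return float(max(self.y.mean(), 1 - self.y.mean()))

    def _splitter(self, folds, repeats, stratified, seed):
        if self.task == "classify" and stratified:
            return RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                           random_state=seed)
        return RepeatedKFold(n_splits=folds, n_repeats=repeats,
                             random_state=seed)

    def fit(self, folds: int = 4, repeats: int = 25, stratified: bool = True,
            seed: int = 0) -> ScreeningResults:
        X, y = self.X.to_numpy(), self.y.to_numpy()
        splitter = self._splitter(folds, repeats, stratified, seed)
        fold_rows = []
        importances = []
        rng = np.random.default_rng(seed)
        for train, test in splitter.split(X, y if self.task == "classify" else None):
            booster_seed = int(rng.integers(0, 2**31 - 1))
            if self.task == "classify":
                if len(np.unique(y[train])) < 2:
                    warnings.warn("single-class training fold skipped",
                                  stacklevel=2)
                    continue
                model = xgb.XGBClassifier(random_state=booster_seed,
                                          eval_metric="logloss", **self.params)
                model.fit(X[train], y[train])
                pred = model.predict(X[test])
                prob = model.predict_proba(X[test])[:, 1]
                tp = int(np.sum((pred == 1) & (y[test] == 1)))
                fp = int(np.sum((pred == 1) & (y[test] == 0)))
                fn = int(np.sum((pred == 0) & (y[test] == 1)))
                tn = int(np.sum((pred == 0) & (y[test] == 0)))
                row = performance_from_confusion(tp, fp, fn, tn)
                if len(np.unique(y[test])) == 2:
                    row["auc"] = roc_auc_score(y[test], prob)
                else:
                    row["auc"] = np.nan
            else:
                if np.ptp(y[train]) == 0:
                    warnings.warn("constant-outcome training fold skipped",
                                  stacklevel=2)
                    continue
                model = xgb.XGBRegressor(random_state=booster_seed,
                                         **self.params)
                model.fit(X[train], y[train])
                pred = model.predict(X[test])
                resid = y[test] - pred
                denom = np.sum((y[test] - y[test].mean()) ** 2)
                row = {
                    "r2": 1 - np.sum(resid**2) / denom if denom > 0 else np.nan,
                    "pearson_r": (stats.pearsonr(y[test], pred)[0]
                                  if np.ptp(pred) > 0 and np.ptp(y[test]) > 0
                                  else np.nan),
                    "rmse": float(np.sqrt(np.mean(resid**2))),
                    "mae": float(np.mean(np.abs(resid))),
                }
            fold_rows.append(row)
            importances.append(self._gain_importance(model))
        if not fold_rows:
            raise ValueError("no usable folds")
        fold_df = pd.DataFrame(fold_rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = fold_df.mean().to_dict()
            sds = fold_df.std(ddof=1).to_dict()
        imp = pd.concat(importances, axis=1).fillna(0.0).mean(axis=1)
        imp = imp.sort_values(ascending=False)
        return ScreeningResults(
            task=self.task, n_obs=len(y), n_features=self.X.shape[1],
            folds=folds, repeats=repeats, nir=self.nir,
            metrics=means, metrics_sd=sds,
            feature_importances=imp, fold_metrics=fold_df,
        )

    def _gain_importance(self, model) -> pd.Series:
        booster = model.get_booster()
        booster.feature_names = list(self.X.columns)
        raw = booster.get_score(importance_type="gain")
        s = pd.Series({c: raw.get(c, 0.0) for c in self.X.columns})
        total = s.sum()
        return s / total if total > 0 else s


def feature_importance(results: ScreeningResults) -> pd.Series:
    """Ranked, normalized gain importances of a fitted model ensemble."""
    if results.feature_importances is None:
        raise ValueError("model ensemble has not been fitted")
    return results.feature_importances
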