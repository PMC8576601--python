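"""Univariate association screening and covariate-adjusted regression.

The screen computes Spearman rank correlations (midrank ties, two-sided
asymptotic p) between each biomarker and the average PHQ-9 score on
pairwise-complete observations, with Benjamini-Hochberg FDR adjustment.
Hierarchical regression fits block-nested OLS models of the outcome on
one biomarker plus cumulative covariate blocks (listwise deletion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman_screen(features: pd.DataFrame, outcome: pd.Series,
                    min_n: int = 10) -> pd.DataFrame:
    """Spearman/FDR screen of every biomarker against the outcome.

    Returns a frame indexed by biomarker with columns ``rho``, ``p``,
    ``q`` (BH-adjusted) and ``n``. Features that are constant or have
    fewer than ``min_n`` complete pairs are excluded with a warning.
    """
    outcome = outcome.reindex(features.index)
    rows = {}
    dropped = []
    for name in features.columns:
        x = features[name]
        ok = x.notna() & outcome.notna()
        n = int(ok.sum())
        if n < min_n or x[ok].nunique() <= 1:
            dropped.append(name)
            continue
        rho, p = stats.spearmanr(x[ok], outcome[ok])
        rows[name] = {"rho": rho, "p": p, "n": n}
    if dropped:
        warnings.warn(f"{len(dropped)} feature(s) excluded from the screen "
                      f"(constant or < {min_n} pairs): {dropped[:5]}...",
                      stacklevel=2)
    out = pd.DataFrame.from_dict(rows, orient="index")
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["n"] = out["n"].astype(int)
    return out


# -- hierarchical regression -------------------------------------------

#: Reference levels for categorical covariates (dropped dummy).
REFERENCE_LEVELS = {
    "gender": "female",
    "ethnicity": "chinese",
    "marital": "married",
    "education": "below_degree",
    "self_rated_health": "excellent",
}

#: Default cumulative covariate blocks: sociodemographics first, then
#: lifestyle/health/sleep/loneliness confounders.
DEFAULT_BLOCKS = (
    ("age", "gender", "ethnicity", "marital", "education", "income"),
    ("alcohol", "smoking", "self_rated_health", "loneliness",
     "sleep_hygiene", "sleep_quality", "sleepiness"),
)


@dataclass
class RegressionResult:
    """One block-nested model's biomarker coefficient."""

    model_id: int
    beta: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    covariates: tuple
    scale_note: str = ""


@dataclass
class HierarchicalRegressionResults:
    biomarker: str
    results: list = field(default_factory=list)
    models: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "model": r.model_id, "beta": r.beta, "ci_low": r.ci_low,
            "ci_high": r.ci_high, "p": r.p, "n": r.n,
            "covariates": "+".join(r.covariates) if r.covariates else "none",
        } for r in self.results]).set_index("model")

    def summary(self) -> str:
        lines = [f"Hierarchical regression of outcome on {self.biomarker}"]
        for r in self.results:
            lines.append(
                f"  model {r.model_id} (n={r.n}, +{len(r.covariates)} cov): "
                f"beta={r.beta:.4g} [{r.ci_low:.4g}, {r.ci_high:.4g}], "
                f"p={r.p:.3g}{r.scale_note}")
        return "\n".join(lines)


class HierarchicalRegression:
    """Block-nested OLS of a continuous outcome on a single biomarker.

    Model 1 contains the biomarker alone; model k adds the k-1 first
    covariate blocks cumulatively. Categorical covariates are dummy
    coded against documented reference levels.

    Parameters
    ----------
    data : DataFrame
        One row per participant; must contain the outcome, the
        biomarker, and every covariate named in ``blocks``.
    outcome, biomarker : str
        Column names.
    blocks : sequence of sequences, optional
        Cumulative covariate blocks (default: sociodemographics, then
        lifestyle/health/sleep confounders).
    per_10pct : bool
        When the biomarker is proportion-like (on a [0, 1]-type scale),
        report the coefficient per 10% change, i.e. beta * 0.1.
    """

    def __init__(self, data: pd.DataFrame, outcome: str, biomarker: str,
                 blocks=DEFAULT_BLOCKS, per_10pct: bool = False):
        self.data = data
        self.outcome = outcome
        self.biomarker = biomarker
        self.blocks = tuple(tuple(b) for b in blocks)
        self.per_10pct = per_10pct

    def _design(self, covariates) -> pd.DataFrame:
        cols = [self.outcome, self.biomarker, *covariates]
        df = self.data[list(dict.fromkeys(cols))].dropna()
        X = pd.DataFrame(index=df.index)
        X[self.biomarker] = df[self.biomarker].astype(float)
        for cov in covariates:
            col = df[cov]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                ref = REFERENCE_LEVELS.get(cov)
                levels = sorted(col.astype(str).unique())
                if ref in levels:
                    levels.remove(ref)
                    levels = [ref] + levels
                for lv in levels[1:]:
                    X[f"{cov}[{lv}]"] = (col.astype(str) == lv).astype(float)
            else:
                X[cov] = col.astype(float)
        return df[self.outcome].astype(float), sm.add_constant(X)

    def fit(self, alpha: float = 0.05) -> HierarchicalRegressionResults:
        out = HierarchicalRegressionResults(self.biomarker)
        cumulative = []
        for model_id in range(len(self.blocks) + 1):
            if model_id > 0:
                cumulative.extend(self.blocks[model_id - 1])
            y, X = self._design(tuple(cumulative))
            rank = np.linalg.matrix_rank(X.to_numpy())
            if rank < X.shape[1]:
                bad = _collinear_columns(X)
                raise ValueError(
                    f"rank-deficient design in model {model_id + 1}; "
                    f"collinear columns: {bad}")
            if len(y) <= X.shape[1]:
                raise ValueError(
                    f"model {model_id + 1}: n={len(y)} does not exceed the "
                    f"parameter count {X.shape[1]}")
            res = sm.OLS(y, X).fit()
            scale = 0.1 if self.per_10pct else 1.0
            ci = res.conf_int(alpha=alpha).loc[self.biomarker]
            out.results.append(RegressionResult(
                model_id=model_id + 1,
                beta=res.params[self.biomarker] * scale,
                ci_low=ci[0] * scale, ci_high=ci[1] * scale,
                p=res.pvalues[self.biomarker], n=int(res.nobs),
                covariates=tuple(cumulative),
                scale_note=" (per 10% change)" if self.per_10pct else "",
            ))
            out.models.append(res)
        return out


def _collinear_columns(X: pd.DataFrame) -> list:
    """Name columns involved in exact collinearity (diagnostic only)."""
    bad = []
    arr = X.to_numpy()
    base_rank = np.linalg.matrix_rank(arr)
    for j, name in enumerate(X.columns):
        reduced = np.delete(arr, j, axis=1)
        if np.linalg.matrix_rank(reduced) == base_rank:
            bad.append(name)
    return bad
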