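"""PHQ-9 scoring, depression labels, severity cross-tabulation and
contrasted subsampling.

Four cutoff rules define the depressed group from the two assessments:

* rule A — total >= 10 at either assessment (the conventional screen);
* rule B — total >= 8 at both assessments;
* rule C — average total >= 8;
* rule D — top 20% by average total vs bottom 20% (others excluded).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

SEVERITY_BINS = (0, 5, 10, 15, 28)
SEVERITY_LABELS = ("normal", "mild", "moderate", "moderately_severe")

RULES = ("A", "B", "C", "D")


def score_phq9(items) -> int:
    """Total of the nine 0-3 items."""
    items = list(items)
    if len(items) != 9:
        raise ValueError("PHQ-9 has exactly 9 items")
    for v in items:
        if not (isinstance(v, (int, np.integer)) and 0 <= v <= 3):
            raise ValueError(f"PHQ-9 items must be integers in 0..3, got {v!r}")
    return int(sum(items))


def assign_label(t1, t2, rule: str, avg_quantiles=None) -> str:
    """Depression label for one participant under a cutoff rule.

    ``avg_quantiles`` (low, high) is required for rule D and gives the
    bottom/top 20% bounds of the cohort's average scores. A missing
    assessment yields ``excluded`` with a warning.
    """
    if t1 is None or t2 is None or not np.isfinite(t1) or not np.isfinite(t2):
        warnings.warn("missing PHQ-9 assessment: participant excluded",
                      stacklevel=2)
        return "excluded"
    avg = (t1 + t2) / 2.0
    if rule == "A":
        return "depressed" if (t1 >= 10 or t2 >= 10) else "healthy"
    if rule == "B":
        return "depressed" if (t1 >= 8 and t2 >= 8) else "healthy"
    if rule == "C":
        return "depressed" if avg >= 8 else "healthy"
    if rule == "D":
        if avg_quantiles is None:
            raise ValueError("rule D requires cohort average-score quantiles")
        lo, hi = avg_quantiles
        if avg >= hi:
            return "depressed"
        if avg <= lo:
            return "healthy"
        return "excluded"
    raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")


def assign_labels(outcomes: pd.DataFrame, rule: str) -> pd.Series:
    """Vectorized label assignment for a cohort outcomes table.

    Rule D quantile ties are broken deterministically by participant id:
    exactly ``floor(0.2 n)`` participants enter each extreme group, in
    average-score order with id as tiebreak.
    """
    t1, t2 = outcomes["phq9_t1"], outcomes["phq9_t2"]
    avg = (t1 + t2) / 2.0
    if rule == "A":
        dep = (t1 >= 10) | (t2 >= 10)
        return pd.Series(np.where(dep, "depressed", "healthy"), outcomes.index)
    if rule == "B":
        dep = (t1 >= 8) & (t2 >= 8)
        return pd.Series(np.where(dep, "depressed", "healthy"), outcomes.index)
    if rule == "C":
        return pd.Series(np.where(avg >= 8, "depressed", "healthy"),
                         outcomes.index)
    if rule == "D":
        n = len(outcomes)
        k = int(np.floor(0.2 * n))
        order = avg.to_frame("avg").assign(pid=outcomes.index.astype(str))
        order = order.sort_values(["avg", "pid"]).index
        labels = pd.Series("excluded", index=outcomes.index)
        labels.loc[order[:k]] = "healthy"
        labels.loc[order[n - k:]] = "depressed"
        return labels
    raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")


class SeverityCrosstab:
    """4x4 cross-tabulation of PHQ-9 severity categories at T1 x T2.

    Categories: normal 0-4, mild 5-9, moderate 10-14, moderately
    severe >= 15.
    """

    def __init__(self, counts):
        counts = np.asarray(counts, dtype=int)
        if counts.shape != (4, 4) or (counts < 0).any():
            raise ValueError("counts must be a nonnegative 4x4 matrix")
        self.counts = counts

    @classmethod
    def from_records(cls, outcomes: pd.DataFrame) -> "SeverityCrosstab":
        c1 = np.digitize(outcomes["phq9_t1"], SEVERITY_BINS[1:-1])
        c2 = np.digitize(outcomes["phq9_t2"], SEVERITY_BINS[1:-1])
        counts = np.zeros((4, 4), dtype=int)
        np.add.at(counts, (c1, c2), 1)
        return cls(counts)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def n_either_at_least_moderate(self) -> int:
        """Participants with a total >= 10 at either assessment."""
        below = self.counts[:2, :2].sum()
        return self.grand_total - int(below)

    def n_both_at_least_moderate(self) -> int:
        """Participants with totals >= 10 at both assessments."""
        return int(self.counts[2:, 2:].sum())

    def either_prevalence_pct(self) -> float:
        return 100.0 * self.n_either_at_least_moderate() / self.grand_total

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=SEVERITY_LABELS,
                          columns=SEVERITY_LABELS)
        df["total"] = self.row_margins
        df.loc["total"] = list(self.col_margins) + [self.grand_total]
        return df


def contrasted_subsample(outcomes: pd.DataFrame, rule: str, seed: int,
                         healthy_surplus: int | None = None) -> pd.DataFrame:
    """Balanced depressed-vs-minimal-symptom subsample for a cutoff rule.

    For rules A-C the depressed group is taken from the rule's labels and
    healthy candidates are restricted to average scores in (0, 4]
    (zero-average participants excluded as unreliable responders), then
    randomly downsampled without replacement to the depressed count plus
    ``healthy_surplus`` (default 2 for rule A, mirroring the 38-vs-40
    design, 0 otherwise). Rule D takes the stated score ranges: healthy
    average in [0.5, 1.5], depressed average in [7.5, 14].

    Returns the subsampled outcomes with a ``label`` column; the same
    seed reproduces the subset exactly.
    """
    avg = outcomes["phq9_avg"]
    rng = np.random.default_rng(seed)
    if rule == "D":
        dep = outcomes[(avg >= 7.5) & (avg <= 14.0)]
        healthy = outcomes[(avg >= 0.5) & (avg <= 1.5)]
        n = min(len(dep), len(healthy))
        dep = dep.iloc[np.sort(rng.choice(len(dep), n, replace=False))]
        healthy = healthy.iloc[np.sort(rng.choice(len(healthy), n, replace=False))]
    else:
        labels = assign_labels(outcomes, rule)
        dep = outcomes[labels == "depressed"]
        pool = outcomes[(labels == "healthy") & (avg > 0) & (avg <= 4)]
        if healthy_surplus is None:
            healthy_surplus = 2 if rule == "A" else 0
        n_healthy = len(dep) + healthy_surplus
        if len(pool) < len(dep):
            raise ValueError(
                f"rule {rule}: only {len(pool)} eligible healthy participants "
                f"for {len(dep)} depressed (shortfall {len(dep) - len(pool)})")
        n_healthy = min(n_healthy, len(pool))
        healthy = pool.iloc[np.sort(rng.choice(len(pool), n_healthy,
                                               replace=False))]
    out = pd.concat([dep.assign(label="depressed"),
                     healthy.assign(label="healthy")])
    return out
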