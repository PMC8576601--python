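"""Cohort configuration for the synthetic-data generator."""

from __future__ import annotations

from dataclasses import dataclass, field


class ConfigurationError(ValueError):
    """Raised when a cohort or pipeline configuration is invalid."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a simulated wearable cohort.

    Parameters
    ----------
    n_participants : int
        Cohort size (>= 2).
    days_per_participant : int
        Tracked days per participant. Default 14 — the average tracking
        length of the working-adult cohort the generator emulates.
    depressed_fraction : float
        Fraction of participants drawn from the shifted-severity
        ("depressed") group. Default 0.15 (~14% screen-positive under the
        either-assessment >=10 rule).
    wear_compliance : float
        Target fraction of minutes with the device worn. Non-wear is
        injected as contiguous blocks that remove heart-rate samples
        first, so the HR-based completeness rule is exercised. Default 0.85.
    phq9_test_retest_r : float
        Target Pearson correlation between the two PHQ-9 totals
        (test-retest over ~2 weeks). Default 0.73.
    effect_sizes : dict[str, float]
        Mapping biomarker name -> planted effect size, in cohort-SD units
        of the target biomarker per SD of latent severity (see
        :func:`actimood.synthetic.plant_effects` for supported names).
    hr_interval_s : int
        Heart-rate sampling interval in seconds (5 or 10). Default 10.
    seed : int
        RNG seed; the same seed and config reproduce streams exactly.
    """

    n_participants: int
    days_per_participant: int = 14
    depressed_fraction: float = 0.15
    wear_compliance: float = 0.85
    phq9_test_retest_r: float = 0.73
    effect_sizes: dict = field(default_factory=dict)
    hr_interval_s: int = 10
    seed: int = 0
    # Monday, so weekday/weekend structure is deterministic.
    start: str = "2021-06-07"

    def __post_init__(self):
        if self.n_participants < 2:
            raise ConfigurationError("n_participants must be >= 2")
        if self.days_per_participant < 1:
            raise ConfigurationError("days_per_participant must be >= 1")
        for name in ("depressed_fraction", "wear_compliance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not -1.0 <= self.phq9_test_retest_r <= 1.0:
            raise ConfigurationError("phq9_test_retest_r must be in [-1, 1]")
        if self.hr_interval_s not in (5, 10):
            raise ConfigurationError("hr_interval_s must be 5 or 10")
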