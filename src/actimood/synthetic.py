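"""Synthetic wearable cohort generator with plantable depression effects.

The generator emulates the data a consumer wrist tracker produces for a
working-adult cohort: per-minute steps and METs, heart rate at 5-10 s
intervals, 30-s sleep-stage epochs for one nightly episode, contiguous
non-wear gaps (which remove heart-rate samples first, exercising the
HR-based completeness rule), and two PHQ-9 assessments per participant
with a configurable test-retest correlation.

Group effects are planted through a small set of interpretable latent
knobs (day-to-day template jitter, nocturnal heart-rate noise, activity
bout rate, sleep schedule shift). Effect sizes are expressed per
standard deviation of the latent severity scale, so the depressed group
inherits the shift through its severity gap and the effect remains
detectable by a severity-correlated screen (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import CohortConfig, ConfigurationError
from .streams import MINUTES_PER_DAY, SECONDS_PER_DAY, ParticipantStreams

# -- latent severity / PHQ-9 calibration constants --------------------
# Chosen once so the simulated cohort matches the descriptive statistics
# of the emulated study population: mean PHQ-9 total ~4, ~14%
# screen-positive under the either-assessment >=10 rule, retest r ~0.73.
_PHQ_A = 0.85          # log-scale intercept of the expected total
_PHQ_B = 0.60          # log-scale loading of latent severity
_SEVERITY_SHIFT = 2.4  # latent severity shift of the depressed group

# Hourly step-rate templates (steps/minute, hour 0..23). Weekdays have a
# commute-like two-peak shape; weekends a single broad midday plateau.
_TEMPLATE_WD = np.array(
    [0.2, 0.2, 0.2, 0.2, 0.3, 0.5, 2, 12, 30, 12, 8, 10,
     14, 10, 8, 8, 10, 14, 28, 14, 8, 5, 2, 0.5]
)
_TEMPLATE_WE = np.array(
    [0.3, 0.3, 0.2, 0.2, 0.2, 0.3, 0.5, 1, 4, 10, 16, 20,
     22, 20, 16, 12, 10, 10, 12, 10, 8, 5, 2, 1]
)

SUPPORTED_EFFECTS = ("IS.st.wd", "NHR.0406.cv", "peaks.st", "sleep.midpoint")


@dataclass(frozen=True)
class LatentProfile:
    """Per-participant latent parameters driving stream synthesis."""

    severity: float = 0.0            # standardized latent severity
    activity_level: float = 1.0      # multiplier on the step templates
    hr_baseline: float = 66.0        # bpm
    hr_circ_amp: float = 8.0         # bpm, circadian peak-trough half-range
    hr_activity_gain: float = 0.08   # bpm per concurrent step/min
    hr_noise_sd: float = 2.0         # stationary SD of AR(1) noise, bpm
    hr_ar_phi: float = 0.9           # AR(1) coefficient at sample scale
    night_hr_noise_sd: float = 1.5   # extra nocturnal (0-6 AM) noise SD, bpm
    sleep_onset_h: float = 23.3      # mean bedtime, hours since midnight
    sleep_duration_h: float = 7.4    # mean episode length, hours
    onset_jitter_sd: float = 0.5     # night-to-night SD of onset, hours
    duration_jitter_sd: float = 0.5  # night-to-night SD of duration, hours
    template_jitter_sd_wd: float = 0.5  # log-SD of day-hour template jitter
    template_jitter_sd_we: float = 0.5
    bout_rate: float = 4.0           # expected discrete activity bouts/day
    bout_height: float = 100.0       # extra steps/min during a bout
    midpoint_shift_h: float = 0.0    # rigid shift of the sleep schedule

    def __post_init__(self):
        if self.activity_level < 0 or self.bout_rate < 0:
            raise ConfigurationError("activity level and bout rate must be >= 0")
        if not 0 < self.sleep_duration_h < 24:
            raise ConfigurationError("sleep duration must be in (0, 24) hours")

    def step_template(self, weekday: bool) -> np.ndarray:
        base = _TEMPLATE_WD if weekday else _TEMPLATE_WE
        return base * self.activity_level


def plant_effects(profile: LatentProfile, effects: dict, severity: float | None = None
                  ) -> LatentProfile:
    """Return a copy of ``profile`` with group effects applied.

    Each supported effect maps one biomarker to a latent knob:

    * ``IS.st.wd`` — weekday day-to-day template jitter (negative effect
      sizes increase jitter, lowering interdaily stability);
    * ``NHR.0406.cv`` — nocturnal heart-rate noise SD;
    * ``peaks.st`` — expected number of discrete daily activity bouts;
    * ``sleep.midpoint`` — rigid shift of the sleep schedule, in hours
      per unit effect.

    ``severity`` scales the shift (defaults to 1, i.e. the shift at one
    standard deviation of latent severity). An unknown effect name
    raises :class:`ConfigurationError` listing the supported names.
    """
    if severity is None:
        severity = 1.0
    out = profile
    for name, e in effects.items():
        s = e * severity
        if name == "IS.st.wd":
            out = dataclasses.replace(
                out, template_jitter_sd_wd=out.template_jitter_sd_wd * np.exp(-0.6 * s)
            )
        elif name == "NHR.0406.cv":
            out = dataclasses.replace(
                out, night_hr_noise_sd=out.night_hr_noise_sd * np.exp(0.5 * s)
            )
        elif name == "peaks.st":
            out = dataclasses.replace(out, bout_rate=out.bout_rate * np.exp(0.35 * s))
        elif name == "sleep.midpoint":
            out = dataclasses.replace(out, midpoint_shift_h=out.midpoint_shift_h + s)
        else:
            raise ConfigurationError(
                f"unknown effect {name!r}; supported effects: {SUPPORTED_EFFECTS}"
            )
    return out


# -- latent severity and outcomes -------------------------------------

def _draw_latents(config: CohortConfig, rng: np.random.Generator):
    n = config.n_participants
    n_dep = int(round(n * config.depressed_fraction))
    depressed = np.zeros(n, dtype=bool)
    depressed[rng.permutation(n)[:n_dep]] = True
    severity = rng.normal(size=n) + _SEVERITY_SHIFT * depressed
    f = config.depressed_fraction
    mu_pop = _SEVERITY_SHIFT * f
    sd_pop = np.sqrt(1.0 + _SEVERITY_SHIFT**2 * f * (1 - f))
    severity_std = (severity - mu_pop) / sd_pop
    return depressed, severity, severity_std


def _phq9_noise_sd(config: CohortConfig) -> float:
    """Noise SD yielding the configured test-retest correlation.

    The two totals share the latent expected score ``mu = exp(a + b*sev)``
    and differ by independent Gaussian noise; the correlation equals
    Var(mu) / (Var(mu) + sd^2), so ``sd^2 = Var(mu) * (1 - r) / r`` with
    Var(mu) evaluated analytically for the lognormal mixture.
    """
    r = config.phq9_test_retest_r
    if r <= 0:
        raise ConfigurationError(
            "phq9_test_retest_r must be positive: the shared-latent mechanism "
            "cannot produce non-positive retest correlations"
        )
    f = config.depressed_fraction
    a, b, d = _PHQ_A, _PHQ_B, _SEVERITY_SHIFT
    e1 = (1 - f) * np.exp(a + b**2 / 2) + f * np.exp(a + b * d + b**2 / 2)
    e2 = (1 - f) * np.exp(2 * a + 2 * b**2) + f * np.exp(2 * a + 2 * b * d + 2 * b**2)
    var_mu = e2 - e1**2
    if r >= 1:
        return 0.0
    return float(np.sqrt(var_mu * (1 - r) / r))


def generate_outcomes(config: CohortConfig, rng: np.random.Generator | None = None,
                      latents=None) -> pd.DataFrame:
    """Draw PHQ-9 assessments and covariates for the cohort.

    Returns one row per participant with the two PHQ-9 totals, their
    average, the true planted group, the standardized latent severity,
    and numeric/categorical covariates. Callable standalone (streams are
    not needed to study the outcome model).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    if latents is None:
        latents = _draw_latents(config, rng)
    depressed, severity, severity_std = latents
    n = config.n_participants

    mu = np.exp(_PHQ_A + _PHQ_B * severity)
    sd = _phq9_noise_sd(config)
    t1 = np.clip(np.round(mu + rng.normal(0, sd, n) if sd else mu), 0, 27).astype(int)
    t2 = np.clip(np.round(mu + rng.normal(0, sd, n) if sd else mu), 0, 27).astype(int)

    age = np.clip(np.round(rng.normal(33, 8.6, n)), 21, 64).astype(int)
    gender = rng.choice(["female", "male"], n, p=[0.64, 0.36])
    ethnicity = rng.choice(["chinese", "malay", "indian", "other"], n,
                           p=[0.79, 0.08, 0.08, 0.05])
    marital = rng.choice(["single", "married", "other"], n, p=[0.61, 0.36, 0.03])
    education = rng.choice(["degree", "below_degree"], n, p=[0.89, 0.11])
    income = rng.choice([1, 2, 3, 4], n, p=[0.35, 0.25, 0.25, 0.15])
    alcohol = (rng.random(n) < 0.59).astype(int)
    smoking = (rng.random(n) < 0.06).astype(int)
    health = rng.choice(["excellent", "very_good", "good", "fair"], n,
                        p=[0.064, 0.393, 0.464, 0.079])
    # Instrument totals enter the analysis as numbers only; weak severity
    # coupling makes them behave like the confounders they are.
    loneliness = np.clip(np.round(40 + 4 * severity + rng.normal(0, 6, n)), 20, 80)
    sleep_quality = np.clip(np.round(5 + 1.2 * severity + rng.normal(0, 2, n)), 0, 21)
    sleep_hygiene = np.clip(np.round(30 + 2 * severity + rng.normal(0, 5, n)), 13, 65)
    sleepiness = np.clip(np.round(7 + 0.8 * severity + rng.normal(0, 3, n)), 0, 24)

    return pd.DataFrame({
        "pid": [f"P{i:04d}" for i in range(n)],
        "group": np.where(depressed, "depressed", "healthy"),
        "severity": severity_std,
        "phq9_t1": t1,
        "phq9_t2": t2,
        "phq9_avg": (t1 + t2) / 2.0,
        "age": age,
        "gender": gender,
        "ethnicity": ethnicity,
        "marital": marital,
        "education": education,
        "income": income,
        "alcohol": alcohol,
        "smoking": smoking,
        "self_rated_health": health,
        "loneliness": loneliness,
        "sleep_hygiene": sleep_hygiene,
        "sleep_quality": sleep_quality,
        "sleepiness": sleepiness,
    }).set_index("pid")


# -- stream synthesis --------------------------------------------------

# Sleep-stage block dynamics (30-s epochs): stage selection probabilities
# and mean block lengths in epochs for the semi-Markov body of the night.
_STAGE_P = {"light": 0.40, "deep": 0.18, "rem": 0.17, "wake": 0.25}
_STAGE_MEAN_EP = {"light": 40, "deep": 24, "rem": 20, "wake": 6}


def _night_stage_sequence(n_epochs: int, rng: np.random.Generator) -> np.ndarray:
    """Semi-Markov stage sequence for one night: SOL wake run, then
    alternating stage blocks with a small wake fraction."""
    stages = np.empty(n_epochs, dtype=object)
    sol = min(int(rng.geometric(1 / 24.0)), max(n_epochs // 4, 1))
    stages[:sol] = "wake"
    pos = sol
    names = list(_STAGE_P)
    probs = np.array([_STAGE_P[s] for s in names])
    first = True
    while pos < n_epochs:
        stage = names[rng.choice(len(names), p=probs)]
        if first and stage == "wake":   # sleep onset ends the latency run
            continue
        first = False
        dur = max(int(rng.geometric(1.0 / _STAGE_MEAN_EP[stage])), 1)
        stages[pos:pos + dur] = stage
        pos += dur
    return stages


def _draw_gaps(config: CohortConfig, n_days: int, rng: np.random.Generator):
    """Daily non-wear gaps (minute-aligned) hitting the target compliance.

    Short gaps (charging/shower, 18-150 min) never break the 20-h day
    rule; long gaps (forgotten device) always do. The mixture weight is
    solved so the expected removed time matches ``1 - wear_compliance``.
    """
    target_h = 24.0 * (1.0 - config.wear_compliance)
    e_short, e_long = 1.4, 10.25
    gaps = []
    for d in range(n_days):
        if target_h <= 0:
            continue
        if target_h <= e_short:
            if rng.random() >= target_h / e_short:
                continue
            dur_h = rng.uniform(0.3, 2.5)
        else:
            q = min((target_h - e_short) / (e_long - e_short), 1.0)
            if rng.random() < q:
                dur_h = rng.uniform(4.5, 16.0)
            else:
                dur_h = rng.uniform(0.3, 2.5)
        start_min = d * MINUTES_PER_DAY + int(rng.uniform(7, 20) * 60)
        end_min = min(start_min + int(round(dur_h * 60)), n_days * MINUTES_PER_DAY)
        gaps.append((start_min * 60, end_min * 60))
    return gaps


def _synthesize_streams(pid: str, profile: LatentProfile, config: CohortConfig,
                        rng: np.random.Generator) -> ParticipantStreams:
    D = config.days_per_participant
    n_min = D * MINUTES_PER_DAY
    start = pd.Timestamp(config.start)
    dow = (start.dayofweek + np.arange(D)) % 7
    weekday = dow < 5

    # -- sleep schedule: one episode per night, assigned to the wake-day
    sleep_t_parts, sleep_stage_parts = [], []
    sleep_minute = np.zeros(n_min, dtype=bool)
    for d in range(1, D):
        onset_h = (profile.sleep_onset_h + profile.midpoint_shift_h
                   + rng.normal(0, profile.onset_jitter_sd))
        dur_h = np.clip(profile.sleep_duration_h
                        + rng.normal(0, profile.duration_jitter_sd), 4.0, 11.0)
        onset_s = int(round(((d - 1) * 24 + onset_h) * 3600 / 30)) * 30
        n_ep = int(round(dur_h * 120))
        end_s = min(onset_s + n_ep * 30, D * SECONDS_PER_DAY)
        n_ep = (end_s - onset_s) // 30
        if n_ep < 8:
            continue
        stages = _night_stage_sequence(n_ep, rng)
        sleep_t_parts.append(onset_s + 30 * np.arange(n_ep))
        sleep_stage_parts.append(stages)
        sleep_minute[onset_s // 60: end_s // 60] = True
    if sleep_t_parts:
        sleep_t = np.concatenate(sleep_t_parts)
        sleep_stage = np.concatenate(sleep_stage_parts)
    else:
        sleep_t = np.array([], dtype=int)
        sleep_stage = np.array([], dtype=object)

    # -- steps: template x day-hour jitter, overdispersed counts, bouts
    jitter_sd = np.where(weekday, profile.template_jitter_sd_wd,
                         profile.template_jitter_sd_we)[:, None]
    templ = np.where(weekday[:, None],
                     profile.step_template(True)[None, :],
                     profile.step_template(False)[None, :])     # (D, 24)
    jit = np.exp(rng.normal(0, 1, (D, 24)) * jitter_sd - jitter_sd**2 / 2)
    lam = np.repeat((templ * jit).reshape(-1), 60)               # per minute
    gamma_mix = rng.gamma(0.5, 2.0, n_min)                       # mean 1, NB-like
    steps = rng.poisson(lam * gamma_mix).astype(float)
    bout_extra_met = np.zeros(n_min)
    for d in range(D):
        for _ in range(rng.poisson(profile.bout_rate)):
            m0 = d * MINUTES_PER_DAY + int(rng.uniform(9.0, 20.5) * 60)
            dur = int(rng.uniform(8, 16))
            m1 = min(m0 + dur, n_min)
            steps[m0:m1] += rng.poisson(profile.bout_height, m1 - m0)
            bout_extra_met[m0:m1] += rng.uniform(0.0, 2.5)
    steps[sleep_minute] = 0.0
    np.clip(steps, 0, 250, out=steps)

    # -- METs: resting baseline + step coupling + bout intensity
    mets = 1.15 + 0.022 * steps + bout_extra_met + rng.normal(0, 0.08, n_min)
    mets[sleep_minute] = 1.0
    np.clip(mets, 0.8, 15.0, out=mets)

    # -- heart rate: baseline + circadian dip + activity coupling + AR(1)
    dt = config.hr_interval_s
    n_s = D * SECONDS_PER_DAY // dt
    t_s = np.arange(n_s, dtype=np.int64) * dt
    hour = (t_s / 3600.0) % 24.0
    circ = -profile.hr_circ_amp * np.cos(2 * np.pi * (hour - 16.5) / 24.0)
    minute_idx = t_s // 60
    coupling = profile.hr_activity_gain * steps[minute_idx]
    sigma_eta = profile.hr_noise_sd * np.sqrt(1 - profile.hr_ar_phi**2)
    ar = lfilter([1.0], [1.0, -profile.hr_ar_phi],
                 rng.normal(0, sigma_eta, n_s))
    hr = profile.hr_baseline + circ + coupling + ar
    hr[sleep_minute[minute_idx]] -= 4.0
    night = hour < 6.0
    hr[night] += rng.normal(0, profile.night_hr_noise_sd, int(night.sum()))
    np.clip(hr, 25.0, 240.0, out=hr)

    # -- non-wear: remove heart-rate samples inside gap blocks
    gaps = _draw_gaps(config, D, rng)
    keep = np.ones(n_s, dtype=bool)
    for g0, g1 in gaps:
        keep[(t_s >= g0) & (t_s < g1)] = False

    return ParticipantStreams(
        pid=pid, start=start, n_days=D,
        steps=steps, mets=mets,
        hr_t=t_s[keep], hr=hr[keep],
        sleep_t=sleep_t, sleep_stage=sleep_stage,
        wear_gaps=gaps,
    )


def _base_profile(rng: np.random.Generator, severity_std: float) -> LatentProfile:
    return LatentProfile(
        severity=float(severity_std),
        activity_level=float(np.exp(rng.normal(0, 0.25))),
        hr_baseline=float(rng.normal(66, 4)),
        sleep_onset_h=float(rng.normal(23.3, 0.4)),
        sleep_duration_h=float(np.clip(rng.normal(7.4, 0.35), 5.5, 9.5)),
        bout_height=float(rng.normal(100, 10)),
    )


def generate_cohort(config: CohortConfig):
    """Generate a full synthetic cohort.

    Returns
    -------
    streams : dict[str, ParticipantStreams]
        Raw wearable streams keyed by participant id.
    outcomes : pandas.DataFrame
        One row per participant: PHQ-9 totals, true group, severity and
        covariates (see :func:`generate_outcomes`).
    """
    root = np.random.SeedSequence(config.seed)
    ss_outcomes, ss_streams = root.spawn(2)
    rng_out = np.random.default_rng(ss_outcomes)
    latents = _draw_latents(config, rng_out)
    outcomes = generate_outcomes(config, rng_out, latents)

    _, _, severity_std = latents
    streams = {}
    child_seeds = ss_streams.spawn(config.n_participants)
    for i, pid in enumerate(outcomes.index):
        rng_i = np.random.default_rng(child_seeds[i])
        profile = _base_profile(rng_i, severity_std[i])
        profile = plant_effects(profile, config.effect_sizes,
                                severity=severity_std[i])
        streams[pid] = _synthesize_streams(pid, profile, config, rng_i)
    return streams, outcomes
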