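"""Heart-rate biomarkers: RHR, window statistics, RMSSD, delta HR."""

import numpy as np
import pytest

from actimood.heart_rate import (
    delta_heart_rate,
    heart_rate_summary,
    resting_heart_rate,
    rmssd,
    window_hr_stats,
)
from actimood.streams import MINUTES_PER_DAY, ParticipantStreams

import oracles


def make_streams(hr_t, hr, steps=None, n_days=1):
    n_min = n_days * MINUTES_PER_DAY
    return ParticipantStreams(
        pid="H01", start="2021-06-07", n_days=n_days,
        steps=steps if steps is not None else np.zeros(n_min),
        mets=np.ones(n_min),
        hr_t=np.asarray(hr_t, dtype=np.int64),
        hr=np.asarray(hr, dtype=float),
        sleep_t=np.array([], dtype=np.int64),
        sleep_stage=np.array([], dtype=object),
    )


def full_day_samples(value=70.0, interval=10, n_days=1):
    t = np.arange(0, n_days * 86400, interval, dtype=np.int64)
    return t, np.full(len(t), float(value))


class TestRHR:
    def test_constant_hr_zero_steps(self):
        t, hr = full_day_samples(70.0)
        s = make_streams(t, hr)
        assert resting_heart_rate(s, [0]) == pytest.approx(70.0)

    def test_walking_windows_excluded(self):
        t, hr = full_day_samples(60.0)
        steps = np.zeros(MINUTES_PER_DAY)
        # walking 08:00-12:00 with elevated HR
        walk_min = (np.arange(MINUTES_PER_DAY) >= 480) & \
                   (np.arange(MINUTES_PER_DAY) < 720)
        steps[walk_min] = 100.0
        hr = hr.copy()
        hr[(t >= 480 * 60) & (t < 720 * 60)] = 120.0
        s = make_streams(t, hr, steps=steps)
        assert resting_heart_rate(s, [0]) == pytest.approx(60.0)

    def test_no_qualifying_window_missing(self):
        t, hr = full_day_samples(70.0)
        s = make_streams(t, hr, steps=np.ones(MINUTES_PER_DAY))
        assert np.isnan(resting_heart_rate(s, [0]))


class TestWindows:
    def test_constant_night(self):
        t, hr = full_day_samples(55.0, n_days=3)
        s = make_streams(t, hr, n_days=3)
        out = window_hr_stats(s, np.arange(3), (4, 6))
        assert out["mean"] == pytest.approx(55.0)
        assert out["sd"] == pytest.approx(0.0)
        assert out["cv"] == pytest.approx(0.0)

    def test_two_sample_window_hand_computation(self):
        t = np.array([4 * 3600, 5 * 3600], dtype=np.int64)
        hr = np.array([50.0, 60.0])
        s = make_streams(t, hr)
        out = window_hr_stats(s, [0], (4, 6))
        assert out["mean"] == pytest.approx(55.0)
        assert out["sd"] == pytest.approx(np.std([50, 60], ddof=1))
        assert out["cv"] == pytest.approx(out["sd"] / 55.0)

    def test_cv_scale_invariance(self, rng):
        t = np.sort(rng.choice(86400, 500, replace=False)).astype(np.int64)
        hr = rng.normal(60, 5, 500) + 40
        s1 = make_streams(t, hr)
        s2 = make_streams(t, hr * 1.7)
        for win in ((0, 2), (2, 4), (4, 6), (14, 16)):
            c1 = window_hr_stats(s1, [0], win)["cv"]
            c2 = window_hr_stats(s2, [0], win)["cv"]
            assert c1 == pytest.approx(c2, rel=1e-12)


class TestRMSSD:
    def test_constant_zero(self):
        t, hr = full_day_samples(70.0)
        s = make_streams(t, hr)
        assert rmssd(s, [0], "raw") == 0.0

    def test_alternating_two(self):
        t = np.arange(0, 4000, 10, dtype=np.int64)
        hr = np.where(np.arange(len(t)) % 2 == 0, 60.0, 62.0)
        s = make_streams(t, hr)
        assert rmssd(s, [0], "raw") == pytest.approx(2.0)

    def test_oracle_agreement(self, rng):
        for _ in range(40):
            n = int(rng.integers(5, 200))
            t = np.arange(n, dtype=np.int64) * 10
            hr = rng.normal(70, 5, n)
            s = make_streams(t, hr)
            assert rmssd(s, [0], "raw") == pytest.approx(
                oracles.rmssd_oracle(hr.tolist()), rel=1e-12)

    def test_gap_breaks_successiveness(self):
        # two runs separated by an hour; the jump must not contribute
        t = np.concatenate([np.arange(0, 600, 10),
                            np.arange(7200, 7800, 10)]).astype(np.int64)
        hr = np.concatenate([np.full(60, 60.0), np.full(60, 100.0)])
        s = make_streams(t, hr)
        assert rmssd(s, [0], "raw") == 0.0

    def test_hourly_mode(self):
        t, hr = full_day_samples(70.0)
        hr = hr + (t // 3600)  # hourly means 70, 71, ..., 93
        s = make_streams(t, hr)
        assert rmssd(s, [0], "hourly") == pytest.approx(1.0)


class TestDelta:
    def test_arithmetic(self):
        assert delta_heart_rate(74.0, 60.0) == pytest.approx(14.0)

    def test_missing_propagates(self):
        assert np.isnan(delta_heart_rate(np.nan, 60.0))

    def test_sedentary_participant_near_zero(self):
        t, hr = full_day_samples(68.0)
        s = make_streams(t, hr)
        out = heart_rate_summary(s, [0])
        assert out["deltaHR"] == pytest.approx(0.0, abs=1e-9)

    def test_summary_names_complete(self):
        t, hr = full_day_samples(68.0)
        out = heart_rate_summary(make_streams(t, hr), [0])
        for k in ("HR", "RHR", "deltaHR", "NHR.0406.cv", "DHR.cv",
                  "RMSSD.raw", "RMSSD.hourly"):
            assert k in out


class TestPlantedNightVariability:
    def test_night_noise_effect_raises_0406_sd(self):
        from actimood import CohortConfig, generate_cohort, plant_effects
        from actimood.synthetic import LatentProfile, _synthesize_streams
        import numpy as np
        cfg = CohortConfig(n_participants=2, days_per_participant=4,
                           wear_compliance=1.0, seed=9)
        base = LatentProfile()
        bumped = plant_effects(base, {"NHR.0406.cv": 1.0})
        assert bumped.night_hr_noise_sd > base.night_hr_noise_sd
        rng1 = np.random.default_rng(7)
        rng2 = np.random.default_rng(7)
        s0 = _synthesize_streams("a", base, cfg, rng1)
        s1 = _synthesize_streams("b", bumped, cfg, rng2)
        v0 = window_hr_stats(s0, np.arange(4), (4, 6))["sd"]
        v1 = window_hr_stats(s1, np.arange(4), (4, 6))["sd"]
        assert v1 > v0
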