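"""Synthetic cohort generator: determinism, configuration, planted
effects and outcome calibration."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from actimood import (
    CohortConfig,
    ConfigurationError,
    generate_cohort,
    generate_outcomes,
    plant_effects,
)
from actimood.synthetic import LatentProfile, _synthesize_streams


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        dict(n_participants=1),
        dict(n_participants=5, days_per_participant=0),
        dict(n_participants=5, depressed_fraction=1.2),
        dict(n_participants=5, wear_compliance=-0.1),
        dict(n_participants=5, phq9_test_retest_r=1.5),
        dict(n_participants=5, hr_interval_s=7),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            CohortConfig(**kwargs)


class TestDeterminism:
    def test_same_seed_identical_streams(self):
        cfg = CohortConfig(n_participants=3, days_per_participant=3, seed=5)
        s1, o1 = generate_cohort(cfg)
        s2, o2 = generate_cohort(cfg)
        assert o1.equals(o2)
        for pid in s1:
            np.testing.assert_array_equal(s1[pid].steps, s2[pid].steps)
            np.testing.assert_array_equal(s1[pid].hr, s2[pid].hr)
            np.testing.assert_array_equal(s1[pid].hr_t, s2[pid].hr_t)
            np.testing.assert_array_equal(s1[pid].sleep_stage,
                                          s2[pid].sleep_stage)

    def test_different_seed_differs(self):
        c1 = CohortConfig(n_participants=3, days_per_participant=3, seed=5)
        c2 = dataclasses.replace(c1, seed=6)
        s1, _ = generate_cohort(c1)
        s2, _ = generate_cohort(c2)
        assert not np.array_equal(s1["P0000"].steps, s2["P0000"].steps)


class TestOutcomes:
    def test_retest_correlation_near_target(self):
        cfg = CohortConfig(n_participants=500, seed=17)
        out = generate_outcomes(cfg)
        r = stats.pearsonr(out["phq9_t1"], out["phq9_t2"])[0]
        assert abs(r - 0.73) <= 0.05

    def test_totals_in_range_and_average(self):
        out = generate_outcomes(CohortConfig(n_participants=300, seed=2))
        assert out["phq9_t1"].between(0, 27).all()
        assert out["phq9_t2"].between(0, 27).all()
        assert np.allclose(out["phq9_avg"],
                           (out["phq9_t1"] + out["phq9_t2"]) / 2)

    def test_depressed_fraction_respected(self):
        out = generate_outcomes(CohortConfig(n_participants=200,
                                             depressed_fraction=0.25, seed=3))
        assert (out["group"] == "depressed").sum() == 50

    def test_depressed_score_higher(self):
        out = generate_outcomes(CohortConfig(n_participants=400, seed=4))
        dep = out[out.group == "depressed"]["phq9_avg"].mean()
        heal = out[out.group == "healthy"]["phq9_avg"].mean()
        assert dep > heal + 3


class TestPlantEffects:
    def test_empty_effects_identity(self):
        p = LatentProfile()
        assert plant_effects(p, {}) == p

    def test_unknown_effect_lists_supported(self):
        with pytest.raises(ConfigurationError, match="IS.st.wd"):
            plant_effects(LatentProfile(), {"bogus": 1.0})

    def test_night_hr_knob_direction(self):
        p = plant_effects(LatentProfile(), {"NHR.0406.cv": 1.0})
        assert p.night_hr_noise_sd > LatentProfile().night_hr_noise_sd

    def test_is_knob_direction(self):
        p = plant_effects(LatentProfile(), {"IS.st.wd": -1.0})
        assert p.template_jitter_sd_wd > LatentProfile().template_jitter_sd_wd

    def test_midpoint_shift_one_hour(self):
        p = plant_effects(LatentProfile(), {"sleep.midpoint": 1.0})
        assert p.midpoint_shift_h == pytest.approx(1.0)

    def test_planted_is_effect_detected_downstream(self):
        """A -1 SD weekday-IS effect produces a significant negative
        group difference in the extracted biomarker."""
        from actimood.features import binned_steps
        from actimood.circadian import interdaily_stability
        from actimood.qc import completeness_mask, filter_days
        cfg = CohortConfig(n_participants=40, days_per_participant=10,
                           wear_compliance=1.0, seed=21,
                           effect_sizes={"IS.st.wd": -1.0})
        streams, out = generate_cohort(cfg)
        is_vals = {}
        for pid, s in streams.items():
            rep = completeness_mask(s)
            days = filter_days(rep)
            wd = s.weekday_mask()
            days = days[wd[days]]
            mat = binned_steps(s, rep.complete_minute, days, 60)
            is_vals[pid] = interdaily_stability(mat)
        vals = np.array([is_vals[p] for p in out.index])
        dep = (out["group"] == "depressed").to_numpy()
        t, p = stats.ttest_ind(vals[dep], vals[~dep])
        assert t < 0 and p < 0.05

    def test_wear_compliance_scales_gaps(self):
        full = CohortConfig(n_participants=3, days_per_participant=5,
                            wear_compliance=1.0, seed=8)
        partial = dataclasses.replace(full, wear_compliance=0.8)
        s_full, _ = generate_cohort(full)
        s_part, _ = generate_cohort(partial)
        assert all(len(s.wear_gaps) == 0 for s in s_full.values())
        assert any(len(s.wear_gaps) > 0 for s in s_part.values())


class TestStreamShape:
    def test_sampling_interval(self):
        cfg = CohortConfig(n_participants=2, days_per_participant=2,
                           wear_compliance=1.0, hr_interval_s=5, seed=1)
        streams, _ = generate_cohort(cfg)
        s = streams["P0000"]
        assert np.all(np.diff(s.hr_t) == 5)
        assert len(s.steps) == 2 * 1440

    def test_steps_zero_during_sleep(self):
        cfg = CohortConfig(n_participants=2, days_per_participant=3,
                           wear_compliance=1.0, seed=2)
        streams, _ = generate_cohort(cfg)
        s = streams["P0000"]
        for t0, stage in zip(s.sleep_t, s.sleep_stage):
            assert s.steps[t0 // 60] == 0.0
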