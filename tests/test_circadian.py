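"""Nonparametric rhythm metrics, peak detection and the extended cosinor."""

import numpy as np
import pytest

from actimood import circadian as circ
from actimood.circadian import (
    ExtendedCosinorModel,
    _cosinor_curve,
    day_lag_autocorrelation,
    detect_peak_signals,
    fit_extended_cosinor,
    interdaily_cv,
    interdaily_stability,
    intradaily_variability,
    m10_l5_ra,
    peaks_per_day,
)

import oracles


class TestClosedForms:
    def test_is_one_for_identical_days(self, rng):
        day = rng.gamma(2, 50, 24)
        x = np.tile(day, (3, 1))
        assert interdaily_stability(x) == pytest.approx(1.0, abs=1e-12)

    def test_iv_alternating_two_days(self):
        x = np.tile([0.0, 2.0], 24)  # 48 hourly points over 2 days
        assert intradaily_variability(x) == pytest.approx(4.0, abs=1e-12)

    def test_ac_periodic_series(self):
        day = np.arange(24, dtype=float) ** 1.3
        x = np.tile(day, 3)
        # exactly periodic series: AC = (N - k) / N
        assert day_lag_autocorrelation(x, 24) == pytest.approx(48 / 72,
                                                               abs=1e-12)

    def test_ra_arithmetic(self):
        # profile engineered so M10 = 200 and L5 = 50
        profile = np.concatenate([np.full(10, 200.0), np.full(9, 125.0),
                                  np.full(5, 50.0)])
        x = np.tile(profile, (2, 1))
        m10, l5, ra = m10_l5_ra(x)
        assert (m10, l5) == (200.0, 50.0)
        assert ra == pytest.approx(0.6, abs=1e-12)

    def test_ra_edges(self):
        const = np.tile(np.full(24, 7.0), (2, 1))
        _, _, ra = m10_l5_ra(const)
        assert ra == pytest.approx(0.0, abs=1e-12)
        square = np.tile(np.r_[np.zeros(8), np.full(10, 100.0), np.zeros(6)],
                         (2, 1))
        assert m10_l5_ra(square)[2] == pytest.approx(1.0)

    def test_icv_identical_days_zero(self):
        day = np.linspace(10, 100, 24)
        assert interdaily_cv(np.tile(day, (4, 1))) == pytest.approx(0.0)

    def test_icv_single_varying_hour(self):
        x = np.tile(np.full(24, 50.0), (2, 1))
        x[0, 5], x[1, 5] = 90.0, 110.0
        sd = np.std([90.0, 110.0], ddof=1)
        assert interdaily_cv(x) == pytest.approx(sd / (100.0 * 24), rel=1e-12)


class TestOracleAgreement:
    """Exact agreement with brute-force evaluations on random instances."""

    @pytest.mark.parametrize("metric", ["is", "iv", "icv", "ra", "ac"])
    def test_formula_oracles(self, metric, rng):
        for _ in range(60):
            d = int(rng.integers(2, 6))
            days = rng.gamma(2.0, 30.0, (d, 24)) + 1.0
            flat = days.reshape(-1)
            if metric == "is":
                got = interdaily_stability(days)
                want = oracles.is_oracle(days.tolist())
            elif metric == "iv":
                got = intradaily_variability(days)
                want = oracles.iv_oracle(flat.tolist())
            elif metric == "icv":
                got = interdaily_cv(days)
                want = oracles.icv_oracle(days.tolist())
            elif metric == "ra":
                got = m10_l5_ra(days)[2]
                want = oracles.m10_l5_ra_oracle(days.tolist())[2]
            else:
                got = day_lag_autocorrelation(flat, 24)
                want = oracles.ac_oracle(flat.tolist(), 24)
            assert got == pytest.approx(want, rel=1e-12)

    def test_iv_smooth_vs_shuffled(self, rng):
        t = np.arange(48)
        smooth = 50 + 30 * np.sin(2 * np.pi * t / 24)
        shuffled = smooth.reshape(2, 24).copy()
        for row in shuffled:
            rng.shuffle(row)
        assert intradaily_variability(smooth) < intradaily_variability(shuffled)

    def test_ac_iid_noise_near_zero(self, rng):
        hits = 0
        for _ in range(50):
            x = rng.normal(0, 1, 24 * 6)
            if abs(day_lag_autocorrelation(x, 24)) < 3 / np.sqrt(len(x)):
                hits += 1
        assert hits >= 45

    def test_ac_antiphase_negative(self):
        day = np.sin(2 * np.pi * np.arange(24) / 24)
        x = np.concatenate([day, -day, day, -day])
        assert day_lag_autocorrelation(x, 24) < 0


class TestInvariances:
    def test_is_bounds_and_shift_invariance(self, rng):
        days = rng.gamma(2.0, 30.0, (5, 24))
        is_v = interdaily_stability(days)
        assert 0.0 <= is_v <= 1.0 + 1e-12
        shifted = np.roll(days, 5, axis=1)  # same circular shift every day
        assert interdaily_stability(shifted) == pytest.approx(is_v, rel=1e-9)
        assert intradaily_variability(np.roll(days.reshape(-1), 5)) >= 0
        assert m10_l5_ra(shifted)[2] == pytest.approx(m10_l5_ra(days)[2],
                                                      rel=1e-9)
        assert interdaily_cv(shifted) == pytest.approx(interdaily_cv(days),
                                                       rel=1e-9)

    def test_constant_series_undefined(self):
        const = np.full((3, 24), 5.0)
        assert np.isnan(interdaily_stability(const))
        assert np.isnan(intradaily_variability(const))
        assert np.isnan(day_lag_autocorrelation(const.reshape(-1), 24))

    def test_is_variance_split_monte_carlo(self, rng):
        profile = 100 + 80 * np.sin(2 * np.pi * np.arange(24) / 24)
        vals = []
        for _ in range(40):
            noise = rng.normal(0, 40, (14, 24))
            vals.append(interdaily_stability(profile[None, :] + noise))
        var_profile = np.var(profile)
        expected = var_profile / (var_profile + 40**2)
        assert np.mean(vals) == pytest.approx(expected, rel=0.1)

    def test_missing_hours_reduce_to_complete_pairs(self):
        days = np.arange(48, dtype=float).reshape(2, 24) ** 1.1
        days[0, 3] = np.nan
        iv = intradaily_variability(days)
        assert np.isfinite(iv)
        # removing a point cannot be reproduced by the complete formula,
        # but the estimator must stay finite and positive
        assert iv > 0


class TestPeakDetection:
    def test_flat_series_no_peaks(self):
        mean, sd = peaks_per_day(np.full(96 * 3, 10.0), 96)
        assert mean == 0.0 and sd == 0.0

    def test_isolated_spikes_counted(self):
        base = np.full(96 * 4, 10.0)
        spikes = np.zeros(96 * 4)
        for d in range(4):
            for pos in (30, 55, 80):
                spikes[d * 96 + pos] = 60.0
        mean, sd = peaks_per_day(base + spikes, 96)
        assert mean == 3.0
        assert sd == 0.0

    def test_threshold_monotonicity(self, rng):
        y = rng.gamma(2, 20, 96 * 5)
        counts = []
        for thr in (4.0, 3.0, 2.0, 1.0):
            sig = detect_peak_signals(y, threshold=thr)
            starts = np.diff(np.r_[0, sig]) == 1
            counts.append(int(starts.sum()))
        assert counts == sorted(counts)

    def test_short_series_raises(self):
        with pytest.raises(ValueError):
            detect_peak_signals(np.ones(5), lag=12)


class TestExtendedCosinor:
    TRUE = dict(floor=40.0, height=180.0, acro=14.3, alpha=0.4, beta=8.0)

    def _series(self, noise_sd=0.0, rng=None, step=0.5, days=3):
        t = np.arange(0, 24 * days, step)
        y = _cosinor_curve(t, self.TRUE["floor"], self.TRUE["height"],
                           self.TRUE["acro"], self.TRUE["alpha"],
                           self.TRUE["beta"])
        if noise_sd:
            y = y + rng.normal(0, noise_sd, len(y))
        return t, y

    def test_noiseless_parameter_recovery(self):
        t, y = self._series()
        fit = fit_extended_cosinor(t, y, tol=1e-14)
        assert fit.converged
        got = (fit.floor, fit.height, fit.acrophase, fit.alpha, fit.beta)
        want = tuple(self.TRUE.values())
        for g, w in zip(got, want):
            assert abs(g - w) / abs(w) < 1e-3

    def test_mesor_amplitude_consistency(self):
        t, y = self._series()
        fit = fit_extended_cosinor(t, y)
        grid = np.arange(0, 24, 1 / 60)
        curve = fit.predict(grid)
        assert fit.mesor == pytest.approx(curve.mean())
        assert fit.amplitude == pytest.approx(curve.max() - fit.mesor,
                                              rel=1e-9)
        assert 0.0 <= fit.acrophase < 24.0

    def test_time_shift_moves_acrophase(self):
        t, y = self._series()
        base = fit_extended_cosinor(t, y)
        shifted = fit_extended_cosinor(t + 5.0, y)
        assert shifted.acrophase == pytest.approx(
            (base.acrophase + 5.0) % 24.0, abs=1e-3)

    def test_pseudo_f_decreases_with_noise(self, rng):
        t, clean = self._series()
        unit = rng.normal(0, 1, len(clean))
        fs = []
        for sd in (5, 10, 20, 40, 80):
            fit = ExtendedCosinorModel(t, clean + sd * unit).fit()
            fs.append(fit.pseudo_f)
        assert all(a > b for a, b in zip(fs, fs[1:]))

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            ExtendedCosinorModel(np.arange(48.0), np.full(48, 3.0))

    def test_summary_mentions_parameters(self):
        t, y = self._series()
        text = fit_extended_cosinor(t, y).summary()
        for word in ("mesor", "amplitude", "acrophase", "pseudo-F"):
            assert word in text
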