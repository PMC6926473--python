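import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import curve_fit

import oscbias as ob
from oscbias.spectrum import FitError


def _series(t, y):
    n = len(t)
    return ob.BinnedSeries(
        np.asarray(t), np.asarray(y), np.ones(n, int), np.ones(n, int),
        np.ones(n, bool), "criterion", (0.2, 1.2),
    )


class TestFitSinusoid:
    def test_exact_recovery(self, bin_centers):
        t = bin_centers
        y = 0.05 * np.cos(2 * np.pi * 9.4 * t + np.deg2rad(172)) + 0.1
        fit = ob.fit_sinusoid((t, y), 9.4)
        assert fit.amp == pytest.approx(0.05, abs=1e-6)
        assert fit.phase_deg == pytest.approx(172.0, abs=1e-6)
        assert fit.offset == pytest.approx(0.1, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-6)

    def test_constant_series_null(self, bin_centers):
        fit = ob.fit_sinusoid((bin_centers, np.full(100, 0.3)), 9.4)
        assert fit.amp == pytest.approx(0.0, abs=1e-8)
        assert fit.r2 == pytest.approx(0.0, abs=1e-8)

    def test_matches_nonlinear_least_squares_oracle(self, bin_centers):
        """The closed-form linear fit equals an independent nonlinear optimizer."""
        rng = np.random.default_rng(3)
        t = bin_centers
        y = 0.04 * np.cos(2 * np.pi * 7.3 * t + 0.7) + 0.02 + 0.03 * rng.standard_normal(100)

        def model(t, A, phi, a0):
            return A * np.cos(2 * np.pi * 7.3 * t + phi) + a0

        popt, _ = curve_fit(model, t, y, p0=[0.05, 0.5, 0.0])
        A, phi = popt[0], popt[1]
        if A < 0:
            A, phi = -A, phi + np.pi
        fit = ob.fit_sinusoid((t, y), 7.3)
        assert fit.amp == pytest.approx(A, rel=1e-6)
        assert np.cos(np.deg2rad(fit.phase_deg) - phi) == pytest.approx(1.0, abs=1e-8)
        assert fit.offset == pytest.approx(popt[2], rel=1e-6)

    def test_negative_amplitude_normalized(self, bin_centers):
        y = -0.05 * np.cos(2 * np.pi * 9.4 * bin_centers + 0.3)
        fit = ob.fit_sinusoid((bin_centers, y), 9.4)
        assert fit.amp > 0
        assert fit.phase_deg == pytest.approx(np.rad2deg(0.3) + 180, abs=1e-6)

    def test_undefined_bins_dropped(self, bin_centers):
        y = 0.05 * np.cos(2 * np.pi * 9.4 * bin_centers)
        s = _series(bin_centers, y)
        s.defined[10:20] = False
        s.values[10:20] = np.nan
        fit = ob.fit_sinusoid(s, 9.4)
        assert fit.n_bins == 90
        assert fit.amp == pytest.approx(0.05, abs=1e-8)

    def test_too_few_bins_rejected(self):
        with pytest.raises(FitError):
            ob.fit_sinusoid((np.array([0.2, 0.3, 0.4]), np.zeros(3)), 9.4)

    @given(st.floats(-0.5, 0.5))
    def test_r2_invariant_to_constant_shift(self, c):
        t = 0.2 + 0.01 * (np.arange(100) + 0.5)
        rng = np.random.default_rng(0)
        y = 0.03 * np.cos(2 * np.pi * 6.0 * t) + 0.02 * rng.standard_normal(100)
        f0 = ob.fit_sinusoid((t, y), 6.0)
        f1 = ob.fit_sinusoid((t, y + c), 6.0)
        assert f1.r2 == pytest.approx(f0.r2, abs=1e-9)
        assert f1.amp == pytest.approx(f0.amp, abs=1e-9)

    @given(st.floats(-0.05, 0.05))
    def test_time_shift_rotates_phase(self, dt):
        t = 0.2 + 0.01 * (np.arange(100) + 0.5)
        f = 8.0
        y = 0.05 * np.cos(2 * np.pi * f * t + 1.0)
        y_shift = 0.05 * np.cos(2 * np.pi * f * (t + dt) + 1.0)
        a = ob.fit_sinusoid((t, y), f)
        b = ob.fit_sinusoid((t, y_shift), f)
        assert b.amp == pytest.approx(a.amp, rel=1e-6)
        expected = np.deg2rad(a.phase_deg) + 2 * np.pi * f * dt
        assert np.cos(np.deg2rad(b.phase_deg) - expected) == pytest.approx(1.0, abs=1e-8)


class TestScan:
    def test_default_grid_81_fits(self, bin_centers):
        scan = ob.scan_frequencies((bin_centers, np.cos(bin_centers)), ob.frequency_grid())
        assert len(scan.fits) == 81

    def test_restricted_grid_6_fits(self):
        assert len(ob.frequency_grid(9.1, 9.6, 0.1)) == 6

    def test_injected_frequency_recovered(self, bin_centers):
        rng = np.random.default_rng(5)
        y = 0.06 * np.cos(2 * np.pi * 9.4 * bin_centers + 0.4) + 0.01 * rng.standard_normal(100)
        scan = ob.scan_frequencies((bin_centers, y), ob.frequency_grid())
        assert scan.best.freq == pytest.approx(9.4, abs=0.1)

    def test_empty_grid_rejected(self, bin_centers):
        with pytest.raises(ValueError):
            ob.scan_frequencies((bin_centers, np.cos(bin_centers)), [])


class TestPermutationMaxR2:
    def test_corrected_p_monotone_in_observed(self, small_dataset):
        null = ob.permutation_max_r2(small_dataset, "criterion", n_perm=150, seed=0)
        order = np.argsort(null.observed)
        assert (np.diff(null.corrected_p[order]) <= 1e-12).all()

    def test_strong_oscillation_detected(self, default_dataset):
        subs = ob.congruency_split(default_dataset, "1back")
        null = ob.permutation_max_r2(subs["congruent"], "criterion", n_perm=200, seed=1)
        assert null.p_at(9.4) < 0.05

    def test_raw_vs_add_one_convention(self, small_dataset):
        kw = dict(measure="criterion", n_perm=120, seed=4)
        a = ob.permutation_max_r2(small_dataset, add_one=True, **kw)
        b = ob.permutation_max_r2(small_dataset, add_one=False, **kw)
        np.testing.assert_allclose(a.corrected_p, (b.corrected_p * 120 + 1) / 121)

    def test_small_n_perm_warns(self, small_dataset):
        with pytest.warns(UserWarning):
            ob.permutation_max_r2(small_dataset, "criterion", n_perm=50, seed=0)


class TestBootstrap2D:
    def test_congruent_confidence_region_excludes_origin(self, default_dataset):
        subs = ob.congruency_split(default_dataset, "totally")
        boot = ob.bootstrap_2d(subs["congruent"], "criterion", freq=9.4, n_boot=200, seed=2)
        assert boot.p_two_tailed < 0.05
        # 95% of samples project positively on the mean direction
        u = np.array(boot.original.components) / boot.original.amp
        assert np.quantile(boot.samples_xy @ u, 0.025) > 0

    def test_seed_reproducibility(self, small_dataset):
        a = ob.bootstrap_2d(small_dataset, "criterion", freq=9.4, n_boot=50, seed=9)
        b = ob.bootstrap_2d(small_dataset, "criterion", freq=9.4, n_boot=50, seed=9)
        np.testing.assert_array_equal(a.samples_xy, b.samples_xy)


class TestAICCompare:
    def _fit(self, rss):
        return ob.SinusoidFit(freq=9.4, amp=0.1, phase_deg=0, offset=0, rss=rss, r2=0.5, n_bins=100)

    def test_identical_fits_ratio_one(self):
        cmp = ob.aic_compare(self._fit(1.0), self._fit(1.0))
        assert cmp.relative_likelihood == pytest.approx(1.0)

    def test_delta_two_gives_ratio_e(self):
        # n·ln(RSS_b) − n·ln(RSS_a) = 2  ⇒  RSS_b = RSS_a·exp(2/100)
        cmp = ob.aic_compare(self._fit(1.0), self._fit(np.exp(2 / 100)), n=100, k=2)
        assert cmp.relative_likelihood == pytest.approx(np.e, rel=1e-12)
        assert cmp.better == "a"

    def test_nonpositive_rss_rejected(self):
        with pytest.raises(ValueError):
            ob.aic_compare(self._fit(0.0), self._fit(1.0))
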