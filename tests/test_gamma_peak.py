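import numpy as np
import pytest
from scipy.stats import spearmanr

from v1gamma import gamma_peak as gp
from v1gamma.spectral import PowerSpectrum

GRID = np.geomspace(20.0, 140.0, 64)


def bump_delta(f, slope=0.2, center=55.0, height=0.3, sd=5.0):
    f = np.asarray(f, dtype=float)
    return -slope * (np.log(f) - np.log(60.0)) + height * np.exp(
        -0.5 * ((f - center) / sd) ** 2
    )


class TestDeltaPower:
    def _spec(self, power, fmax=500.0):
        freqs = np.linspace(0.0, fmax, len(np.atleast_2d(power)[0]))
        return PowerSpectrum(freqs, power)

    def test_equal_spectra_give_zero(self, rng):
        base = self._spec(rng.random(251) + 0.5)
        d = gp.delta_power(self._spec(np.tile(base.power, (3, 1))), base)
        assert np.allclose(d.delta, 0.0, atol=1e-12)

    def test_natural_log_convention(self, rng):
        base = self._spec(rng.random(251) + 0.5)
        d = gp.delta_power(self._spec(np.e * base.power), base)
        assert np.allclose(d.delta, 1.0)

    def test_power_law_resampling_exact(self):
        freqs = np.linspace(1.0, 500.0, 2000)
        stim = PowerSpectrum(freqs, 5.0 * freqs**-2.7)
        base = PowerSpectrum(freqs, 2.0 * freqs**-2.2)
        d = gp.delta_power(stim, base)
        # log-log interpolation is exact for power laws
        expected = np.log(5.0 / 2.0) - 0.5 * np.log(d.frequencies)
        assert np.allclose(d.delta[0], expected, atol=1e-6)

    def test_nonpositive_power_rejected(self):
        freqs = np.linspace(0.0, 500.0, 251)
        bad = PowerSpectrum(freqs, np.zeros(251))
        with pytest.raises(ValueError, match="nonpositive"):
            gp.delta_power(bad, bad)


class TestOrderSelection:
    def test_exact_cubic_selects_low_order_with_zero_residual(self):
        x = np.log10(GRID)
        y = 0.3 * x**3 - x + 0.2
        d = gp.DetrendedSpectrum(GRID, np.tile(y, (8, 1)), "baseline_ratio")
        order = gp.select_poly_order(d, rng=0)
        assert order <= 3
        fit = np.polynomial.Polynomial.fit(x, y, 3)
        assert np.max(np.abs(fit(x) - y)) < 1e-10

    def test_pure_noise_selects_low_orders(self):
        orders = []
        for s in range(60):
            d = gp.DetrendedSpectrum(
                GRID, np.random.default_rng(s).normal(0, 0.1, (20, 64)),
                "baseline_ratio",
            )
            orders.append(gp.select_poly_order(d, rng=s))
        assert np.median(orders) <= 3

    def test_deterministic_given_seed(self, rng):
        d = gp.DetrendedSpectrum(GRID, rng.normal(0, 0.1, (10, 64)), "baseline_ratio")
        assert gp.select_poly_order(d, rng=5) == gp.select_poly_order(d, rng=5)

    def test_too_few_trials_rejected(self):
        d = gp.DetrendedSpectrum(GRID, np.zeros((3, 64)), "baseline_ratio")
        with pytest.raises(ValueError, match="4 trials"):
            gp.select_poly_order(d, rng=0)


class TestPeakFit:
    def test_flat_delta_reports_no_peak(self):
        d = gp.DetrendedSpectrum(GRID, np.zeros((4, 64)), "baseline_ratio")
        peak = gp.fit_gamma_peak(d, 1)
        assert peak.no_peak and peak.amplitude_fold == 1.0
        assert np.isnan(peak.peak_freq)

    def test_gaussian_bump_matches_dense_grid_oracle(self, rng):
        dense = np.geomspace(20.0, 140.0, 40001)
        oracle = gp._peak_from_curve(dense, bump_delta(dense))
        trials = bump_delta(GRID) + rng.normal(0, 0.05, (20, 64))
        d = gp.DetrendedSpectrum(GRID, trials, "baseline_ratio")
        order = gp.select_poly_order(d, rng=1)
        peak = gp.fit_gamma_peak(d, order)
        assert peak.peak_freq == pytest.approx(oracle.peak_freq, abs=2.0)
        assert peak.amplitude_fold == pytest.approx(oracle.amplitude_fold, rel=0.10)
        assert peak.bandwidth == 2.0 * (peak.peak_freq - peak.left_min_freq)

    def test_taller_of_two_bumps_wins(self):
        for s in range(30):
            rng = np.random.default_rng(s)
            y = (
                bump_delta(GRID, center=40.0, height=0.3, slope=0.1)
                + 0.1 * np.exp(-0.5 * ((GRID - 70.0) / 5.0) ** 2)
            )
            d = gp.DetrendedSpectrum(
                GRID, y + rng.normal(0, 0.03, (12, 64)), "baseline_ratio"
            )
            peak = gp.fit_gamma_peak(d, gp.select_poly_order(d, rng=s))
            assert abs(peak.peak_freq - 40.0) < 8.0

    def test_search_outside_fit_range_rejected(self):
        d = gp.DetrendedSpectrum(GRID, np.zeros((4, 64)), "baseline_ratio")
        with pytest.raises(ValueError, match="search"):
            gp.fit_gamma_peak(d, 3, search=(10.0, 80.0))

    def test_amplitude_monotone_in_bump_height(self):
        heights = [0.1, 0.2, 0.3, 0.4, 0.5]
        mean_amp = []
        for h in heights:
            amps = []
            for s in range(25):
                rng = np.random.default_rng(1000 * s + int(h * 10))
                d = gp.DetrendedSpectrum(
                    GRID,
                    bump_delta(GRID, height=h) + rng.normal(0, 0.05, (12, 64)),
                    "baseline_ratio",
                )
                peak = gp.fit_gamma_peak(d, gp.select_poly_order(d, rng=s))
                amps.append(peak.amplitude_fold)
            mean_amp.append(np.mean(amps))
        rho = spearmanr(heights, mean_amp).statistic
        assert rho > 0.95

    def test_no_peak_honesty_on_structureless_spectra(self):
        flagged, folds = 0, []
        n_runs = 60
        for s in range(n_runs):
            d = gp.DetrendedSpectrum(
                GRID, np.random.default_rng(s).normal(0, 0.1, (30, 64)),
                "baseline_ratio",
            )
            peak = gp.fit_gamma_peak(d, gp.select_poly_order(d, rng=s))
            flagged += peak.no_peak
            folds.append(peak.amplitude_fold)
        assert flagged >= 0.90 * n_runs
        assert np.median(folds) == 1.0


class TestOneOverF:
    def test_exact_power_law_residual_tiny(self):
        f = np.linspace(1.0, 200.0, 400)
        d, diag = gp.one_over_f_correct(PowerSpectrum(f, 3.0 * f**-2.3))
        assert np.max(np.abs(d.delta)) < 1e-3
        assert diag.converged

    def test_bump_recovered_after_correction(self, rng):
        f = np.linspace(1.0, 200.0, 400)
        p = 3.0 * f**-2.3 * np.exp(0.4 * np.exp(-0.5 * ((f - 55.0) / 5.0) ** 2))
        trials = p * np.exp(rng.normal(0, 0.05, (10, 400)))
        d, _ = gp.one_over_f_correct(PowerSpectrum(f, trials))
        peak = gp.fit_gamma_peak(d, gp.select_poly_order(d, rng=0))
        assert peak.peak_freq == pytest.approx(55.0, abs=2.0)

    def test_bleed_in_handled_better_than_loglog_line(self):
        f = np.linspace(1.0, 200.0, 400)
        p = 3.0 * f**-2.3 + 1e-5 * np.exp(f / 60.0)  # high-frequency upturn
        d_hybrid, _ = gp.one_over_f_correct(PowerSpectrum(f, p), model="hybrid")
        d_line, _ = gp.one_over_f_correct(PowerSpectrum(f, p), model="loglin")
        sel = (d_hybrid.frequencies >= 90.0) & (d_hybrid.frequencies <= 140.0)
        assert (
            np.abs(d_hybrid.delta[0, sel]).mean()
            < np.abs(d_line.delta[0, sel]).mean()
        )

    def test_variant_agreement_on_stationary_baseline(self):
        """Baseline-ratio and 1/f-corrected amplitudes agree in rank across
        conditions when the baseline is stationary."""
        f = np.linspace(1.0, 200.0, 400)
        base = 3.0 * f**-2.3
        heights = [0.1, 0.25, 0.4, 0.55]
        rng = np.random.default_rng(0)
        a_ratio, a_1f = [], []
        for h in heights:
            p = base * np.exp(h * np.exp(-0.5 * ((f - 55.0) / 5.0) ** 2))
            stim = PowerSpectrum(f, p * np.exp(rng.normal(0, 0.03, (10, 400))))
            bspec = PowerSpectrum(f, base * np.exp(rng.normal(0, 0.03, (10, 400))))
            a_ratio.append(gp.extract_gamma(stim, bspec, rng=1).amplitude_fold)
            a_1f.append(gp.extract_gamma(stim, variant="one_over_f", rng=1).amplitude_fold)
        assert np.corrcoef(a_ratio, a_1f)[0, 1] > 0.9
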