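import numpy as np
import pandas as pd
import pytest

from v1gamma import colorimetry as cm


@pytest.fixture(scope="module")
def cones():
    return cm.fit_cone_curves(cm.synthetic_cone_fundamentals())


class TestConeCurves:
    def test_degree7_polynomial_refit_exact(self):
        wl = np.linspace(400.0, 700.0, 80)
        poly = np.polynomial.Polynomial([0.2, 1e-3, -2e-6], domain=[400, 700])
        y = poly(wl)
        y = (y - y.min()) / (y.max() - y.min())
        tab = pd.DataFrame({"wavelength": wl, "L": y})
        fitted = cm.fit_cone_curves(tab)
        assert np.max(np.abs(fitted.sensitivity("L", wl) - y / y.max())) < 1e-8

    def test_curves_normalized_to_unit_maximum(self, cones):
        for cone in cm.CONE_NAMES:
            vals = cones.sensitivity(cone)
            assert vals.max() == pytest.approx(1.0, abs=2e-3)
            assert vals.min() >= 0.0

    def test_gaussian_toy_peak_recovered(self):
        wl = np.linspace(400.0, 700.0, 100)
        tab = pd.DataFrame(
            {"wavelength": wl, "M": np.exp(-0.5 * ((wl - 530.0) / 40.0) ** 2)}
        )
        fitted = cm.fit_cone_curves(tab)
        assert fitted.peak_wavelength("M") == pytest.approx(530.0, abs=5.0)

    def test_too_few_samples_rejected(self):
        tab = pd.DataFrame({"wavelength": np.arange(5.0), "L": np.ones(5)})
        with pytest.raises(ValueError, match="10 wavelength"):
            cm.fit_cone_curves(tab)


class TestAdaptationCoefficients:
    def test_monochromatic_line_at_peak_gives_one(self, cones):
        peak = cones.peak_wavelength("M")
        grid = cm.WAVELENGTHS
        e = np.zeros_like(grid)
        e[np.argmin(np.abs(grid - peak))] = 1.0
        tri = cm.adaptation_coefficients(
            cm.SpectralPowerDistribution(grid, e), cones
        )
        assert tri.Madapt == pytest.approx(1.0, abs=1e-3)

    def test_flat_spd_gives_curve_mean(self, cones):
        flat = cm.SpectralPowerDistribution(
            cm.WAVELENGTHS, np.ones_like(cm.WAVELENGTHS)
        )
        tri = cm.adaptation_coefficients(flat, cones)
        assert tri.Ladapt == pytest.approx(
            cones.sensitivity("L").mean(), rel=1e-6
        )

    def test_spd_outside_s_support_gives_zero(self, cones):
        grid = cm.WAVELENGTHS
        e = np.where(grid > 650.0, 1.0, 0.0)  # S cone silent there
        tri = cm.adaptation_coefficients(
            cm.SpectralPowerDistribution(grid, e), cones
        )
        assert tri.Sadapt < 1e-6

    def test_scale_invariance(self, cones):
        spd = cm.background_spd("yellow")
        a = cm.adaptation_coefficients(spd, cones)
        scaled = cm.SpectralPowerDistribution(spd.wavelengths, 37.0 * spd.energy)
        b = cm.adaptation_coefficients(scaled, cones)
        assert a.as_dict() == pytest.approx(b.as_dict())

    def test_zero_mass_rejected(self, cones):
        empty = cm.SpectralPowerDistribution(
            cm.WAVELENGTHS, np.zeros_like(cm.WAVELENGTHS)
        )
        with pytest.raises(ValueError, match="zero-mass"):
            cm.adaptation_coefficients(empty, cones)


class TestGammaRatio:
    @pytest.mark.parametrize(
        "a, b, expected", [(2.0, 2.0, 0.0), (20.0, 2.0, 1.0), (1.0, 2.0, -0.30103)]
    )
    def test_log10_ratio(self, a, b, expected):
        assert cm.gamma_ratio(a, b) == pytest.approx(expected, abs=1e-5)

    def test_antisymmetry_and_domain(self):
        assert cm.gamma_ratio(3.0, 1.5) == pytest.approx(-cm.gamma_ratio(1.5, 3.0))
        with pytest.raises(ValueError):
            cm.gamma_ratio(0.0, 1.0)


class TestAdaptationModel:
    def _predictors(self, rng, n=12):
        cones = cm.fit_cone_curves(cm.synthetic_cone_fundamentals())
        prim = cm.monitor_primaries()
        rows = []
        for _ in range(n):
            w = rng.uniform(0.05, 1.0, 3)
            e = sum(wi * p.energy for wi, p in zip(w, prim.values()))
            tri = cm.adaptation_coefficients(
                cm.SpectralPowerDistribution(cm.WAVELENGTHS, e), cones
            )
            rows.append(tri.as_dict())
        return pd.DataFrame(rows)

    def test_noiseless_exact_recovery(self, rng):
        pred = self._predictors(rng)
        y = 1.0 * pred["M"] - 0.5 * pred["L"]
        fit = cm.fit_adaptation_model(y, pred, ("M", "L"))
        assert fit.coefficients["M"] == pytest.approx(1.0, abs=1e-10)
        assert fit.coefficients["L"] == pytest.approx(-0.5, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noisy_recovery_within_three_se(self, rng):
        failures = 0
        for _ in range(50):
            pred = self._predictors(rng)
            y = 1.0 * pred["M"] - 0.5 * pred["L"] + rng.normal(0, 0.05, len(pred))
            fit = cm.fit_adaptation_model(y, pred, ("M", "L"))
            ok = (
                abs(fit.coefficients["M"] - 1.0) < 3 * fit.stderr["M"]
                and abs(fit.coefficients["L"] + 0.5) < 3 * fit.stderr["L"]
            )
            failures += not ok
        assert failures <= 2  # ~99.7% coverage per coefficient

    def test_constant_ratios_give_zero_slopes(self, rng):
        pred = self._predictors(rng)
        y = np.full(len(pred), 0.7)
        fit = cm.fit_adaptation_model(y, pred, ("M", "L"))
        assert fit.coefficients["M"] == pytest.approx(0.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-9)

    def test_rank_deficient_design_rejected(self):
        pred = pd.DataFrame({"M": [0.3] * 6, "L": [0.3] * 6, "S": [0.1] * 6})
        with pytest.raises(ValueError, match="rank"):
            cm.fit_adaptation_model(np.zeros(6), pred, ("M", "L"))

    def test_too_few_observations_rejected(self, rng):
        pred = self._predictors(rng, n=3)
        with pytest.raises(ValueError, match="observations"):
            cm.fit_adaptation_model(np.zeros(3), pred, ("M", "L"))


class TestDkl:
    def test_background_maps_to_origin(self):
        bg = np.array([0.8, 0.6, 0.3])
        c = cm.dkl_coordinates(bg, bg)
        assert (c.lum, c.rg, c.by) == (0.0, 0.0, 0.0)

    def test_uniform_scaling_is_pure_luminance(self):
        bg = np.array([0.8, 0.6, 0.3])
        c = cm.dkl_coordinates(1.1 * bg, bg)
        assert c.rg == pytest.approx(0.0, abs=1e-14)
        assert c.by == pytest.approx(0.0, abs=1e-14)
        assert c.lum > 0

    def test_l_cone_increment_signs(self):
        bg = np.array([1.0, 1.0, 1.0])
        stim = np.array([1.1, 1.0, 1.0])
        c = cm.dkl_coordinates(stim, bg)
        assert c.rg > 0 and c.by < 0 and c.lum > 0

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            cm.dkl_coordinates(np.ones(3), np.array([1.0, 0.0, 1.0]))
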