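"""DKL cone contrasts and the cone-adaptation regression for gamma ratios.

Two colorimetric computations feed the analysis of full-screen-background
(FSB) effects on gamma oscillations:

* DKL coordinates: a stimulus is expressed as Weber cone contrasts relative
  to the background, w = (stim_LMS - bg_LMS)/bg_LMS, then projected onto
  the luminance (L+M), red-green (L-M) and blue-yellow (S-(L+M)) axes.
* Cone-adaptation coefficients: each background's spectral power
  distribution (SPD), normalized to unit mass, is projected onto normalized
  cone sensitivity curves (wavelength-wise inner product), giving
  S/M/L-adaptation scalars. The log10 ratio of gamma amplitudes between two
  hues (e.g. red/green) across backgrounds is then regressed on the
  relevant adaptation coefficients by OLS (red-green: M and L; blue-yellow:
  S and L) with an intercept.

Cone sensitivity curves are represented as order-7 polynomial fits over
wavelength, normalized to a maximum of 1 with negative lobes clipped. A
synthetic macaque-like cone fundamental set (log-Gaussian lobes at standard
S/M/L peak wavelengths) is bundled for self-contained runs; measured
tabulated sensitivities can be substituted via :func:`fit_cone_curves`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

WAVELENGTHS = np.arange(390.0, 731.0, 1.0)
CONE_NAMES = ("S", "M", "L")


@dataclass
class SpectralPowerDistribution:
    wavelengths: np.ndarray
    energy: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.energy = np.asarray(self.energy, dtype=float)
        if np.any(self.energy < 0):
            raise ValueError("spectral energy must be nonnegative")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be increasing")

    def resampled(self, grid=WAVELENGTHS) -> "SpectralPowerDistribution":
        e = np.interp(grid, self.wavelengths, self.energy, left=0.0, right=0.0)
        return SpectralPowerDistribution(grid, e, self.label)

    def unit_mass(self) -> "SpectralPowerDistribution":
        total = self.energy.sum()
        if total <= 0:
            raise ValueError("zero-mass spectral power distribution")
        return SpectralPowerDistribution(self.wavelengths, self.energy / total, self.label)


@dataclass
class ConeSystem:
    """Order-7 polynomial cone sensitivity curves, max-normalized.

    Each cone carries its own support (the wavelength range where the
    tabulated sensitivity is materially nonzero); the polynomial is zeroed
    outside it so extrapolation wiggles of the degree-7 fit cannot
    reintroduce sensitivity where the cone is silent.
    """

    coefficients: dict  # cone -> np.polynomial.Polynomial
    support: tuple = (WAVELENGTHS[0], WAVELENGTHS[-1])
    cone_support: dict = field(default_factory=dict)

    def sensitivity(self, cone: str, wavelengths=WAVELENGTHS) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        vals = self.coefficients[cone](wl)
        vals = np.clip(vals, 0.0, None)
        lo, hi = self.cone_support.get(cone, self.support)
        return np.where((wl >= lo) & (wl <= hi), vals, 0.0)

    def peak_wavelength(self, cone: str) -> float:
        wl = np.arange(self.support[0], self.support[1] + 0.25, 0.25)
        return float(wl[np.argmax(self.sensitivity(cone, wl))])


@dataclass
class AdaptationTriple:
    Sadapt: float
    Madapt: float
    Ladapt: float

    def __post_init__(self):
        if min(self.Sadapt, self.Madapt, self.Ladapt) < 0:
            raise ValueError("adaptation coefficients must be nonnegative")

    def as_dict(self) -> dict:
        return {"S": self.Sadapt, "M": self.Madapt, "L": self.Ladapt}


@dataclass
class DklCoordinates:
    lum: float  # L+M
    rg: float  # L-M
    by: float  # S-(L+M)


@dataclass
class AdaptationModelFit:
    coefficients: dict
    intercept: float
    r_squared: float
    f_pvalue: float
    conf_int: dict
    predictors: tuple
    stderr: dict = field(default_factory=dict)


def synthetic_cone_fundamentals(grid=WAVELENGTHS) -> pd.DataFrame:
    """Synthetic macaque-like cone sensitivities (tabulated).

    A constructed stand-in, not measured data: each cone is a log-Gaussian
    lobe at the standard peak wavelength (S ~ 430 nm, M ~ 535 nm,
    L ~ 565 nm) with realistic asymmetric bandwidth, normalized to max 1.
    """
    wl = np.asarray(grid, dtype=float)
    peaks = {"S": (430.0, 0.055), "M": (535.0, 0.075), "L": (565.0, 0.080)}
    out = {"wavelength": wl}
    for cone, (peak, width) in peaks.items():
        s = np.exp(-0.5 * (np.log(wl / peak) / width) ** 2)
        out[cone] = s / s.max()
    return pd.DataFrame(out)


def fit_cone_curves(tabulated: pd.DataFrame, order: int = 7) -> ConeSystem:
    """Order-7 polynomial fit per cone, normalized to maximum 1.

    ``tabulated`` has a ``wavelength`` column plus one column per cone.
    Negative excursions of the fit are clipped at evaluation time.
    """
    wl = tabulated["wavelength"].to_numpy(dtype=float)
    if len(wl) < 10:
        raise ValueError("need at least 10 wavelength samples per cone")
    coeffs, cone_support = {}, {}
    support = (float(wl.min()), float(wl.max()))
    dense = np.arange(support[0], support[1] + 0.25, 0.25)
    for cone in tabulated.columns:
        if cone == "wavelength":
            continue
        y = tabulated[cone].to_numpy(dtype=float)
        poly = np.polynomial.Polynomial.fit(wl, y, order)
        live = wl[y > 1e-3 * y.max()]
        lo, hi = float(live.min()), float(live.max())
        inside = (dense >= lo) & (dense <= hi)
        peak = np.clip(poly(dense[inside]), 0.0, None).max()
        coeffs[cone] = poly / peak
        cone_support[cone] = (lo, hi)
    return ConeSystem(coeffs, support, cone_support)


def adaptation_coefficients(
    spd: SpectralPowerDistribution, cones: ConeSystem
) -> AdaptationTriple:
    """Inner product of the unit-mass SPD with each normalized cone curve."""
    s = spd.resampled().unit_mass()
    vals = {
        cone: float(np.sum(s.energy * cones.sensitivity(cone, s.wavelengths)))
        for cone in CONE_NAMES
    }
    return AdaptationTriple(vals["S"], vals["M"], vals["L"])


def cone_activations(spd: SpectralPowerDistribution, cones: ConeSystem) -> np.ndarray:
    """Absolute (non-normalized) LMS activations of an SPD."""
    s = spd.resampled()
    return np.array(
        [float(np.sum(s.energy * cones.sensitivity(c, s.wavelengths))) for c in ("L", "M", "S")]
    )


def gamma_ratio(gamma_a: float, gamma_b: float) -> float:
    """log10 ratio of two gamma fold-amplitudes."""
    if gamma_a <= 0 or gamma_b <= 0:
        raise ValueError("gamma amplitudes must be positive")
    return float(np.log10(gamma_a / gamma_b))


def fit_adaptation_model(
    ratios, predictors: pd.DataFrame, predictor_set=("M", "L")
) -> AdaptationModelFit:
    """OLS regression of gamma ratios on cone-adaptation coefficients.

    ``predictors`` holds one row per background with columns S, M, L (e.g.
    from :func:`adaptation_coefficients`); ``predictor_set`` picks the
    columns (red-green model: M and L; blue-yellow: S and L; optionally all
    three).
    """
    y = np.asarray(ratios, dtype=float)
    x = predictors.loc[:, list(predictor_set)].to_numpy(dtype=float)
    if len(y) < len(predictor_set) + 2:
        raise ValueError("need at least n_predictors + 2 observations")
    design = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, design).fit()
    names = ("const",) + tuple(predictor_set)
    ci = fit.conf_int()
    # a constant response has no variance to explain
    r2 = float(fit.rsquared) if np.var(y) > 0 else 0.0
    return AdaptationModelFit(
        coefficients={n: float(c) for n, c in zip(names[1:], fit.params[1:])},
        intercept=float(fit.params[0]),
        r_squared=max(0.0, r2),
        f_pvalue=float(fit.f_pvalue),
        conf_int={n: tuple(ci[i]) for i, n in enumerate(names)},
        predictors=tuple(predictor_set),
        stderr={n: float(s) for n, s in zip(names, fit.bse)},
    )


def dkl_coordinates(stim_lms, bg_lms) -> DklCoordinates:
    """Weber cone contrasts of a stimulus, projected onto the DKL axes.

    ``stim_lms``/``bg_lms`` are (L, M, S) activations. Projection
    convention: L+M = (wL + wM)/2, L-M = wL - wM, S-(L+M) = wS - (wL + wM)/2.
    """
    stim = np.asarray(stim_lms, dtype=float)
    bg = np.asarray(bg_lms, dtype=float)
    if np.any(bg <= 0):
        raise ValueError("background cone activations must be positive")
    w = (stim - bg) / bg  # Weber contrasts (wL, wM, wS)
    lum = (w[0] + w[1]) / 2.0
    return DklCoordinates(lum=float(lum), rg=float(w[0] - w[1]), by=float(w[2] - lum))


def gaussian_spd(center: float, width: float, label: str = "", grid=WAVELENGTHS):
    e = np.exp(-0.5 * ((grid - center) / width) ** 2)
    return SpectralPowerDistribution(grid, e, label)


def monitor_primaries(grid=WAVELENGTHS) -> dict:
    """Synthetic LCD-like primary spectra (Gaussian lobes)."""
    return {
        "R": gaussian_spd(615.0, 18.0, "R", grid),
        "G": gaussian_spd(545.0, 25.0, "G", grid),
        "B": gaussian_spd(455.0, 20.0, "B", grid),
    }


def background_spd(hue: str, gray_over_white: float = 0.35, grid=WAVELENGTHS):
    """SPD of a full-screen background hue from the synthetic primaries.

    Gray is the sum of the unit-mass R, G and B primary spectra scaled by
    the gray/white energy ratio.
    """
    prim = monitor_primaries(grid)
    mixes = {
        "red": {"R": 1.0},
        "green": {"G": 1.0},
        "blue": {"B": 1.0},
        "yellow": {"R": 0.6, "G": 0.6},
        "cyan": {"G": 0.6, "B": 0.6},
        "magenta": {"R": 0.6, "B": 0.6},
        "orange": {"R": 0.8, "G": 0.3},
        "white": {"R": 1.0, "G": 1.0, "B": 1.0},
    }
    if hue == "gray":
        e = sum(prim[k].unit_mass().energy for k in "RGB") * gray_over_white
        return SpectralPowerDistribution(grid, e, "gray")
    if hue == "black":
        # residual monitor glow: tiny flat emission
        return SpectralPowerDistribution(grid, np.full_like(grid, 1e-4, dtype=float), "black")
    if hue not in mixes:
        raise ValueError(f"unknown background hue {hue!r}")
    e = sum(w * prim[k].energy for k, w in mixes[hue].items())
    return SpectralPowerDistribution(grid, e, hue)
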