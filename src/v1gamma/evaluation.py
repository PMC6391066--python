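"""Calibration and recovery experiments exercising the full pipeline.

Each function runs one self-contained experiment on synthetic data -
generating the inputs, executing the analysis under test, and measuring the
outcome - and returns a small dict of scalar results. They are used by the
test suite and by ``scripts/acceptance.py`` to recompute the package's
headline numbers from scratch at fixed problem sizes.
"""

from __future__ import annotations

import numpy as np
from scipy.special import i0, i1

from . import colorimetry, firing, gamma_peak, spectral, stats, synth
from .coupling import ppc_from_phases
from .pipeline import dissociation_experiment


def _rng(seed):
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# gamma-peak algorithm vs dense-grid oracle


def analytic_delta(f, slope=0.2, center=55.0, height=0.3, sd=5.0):
    """Analytic detrended spectrum: log-log trend + Gaussian gamma bump."""
    f = np.asarray(f, dtype=float)
    return -slope * (np.log(f) - np.log(60.0)) + height * np.exp(
        -0.5 * ((f - center) / sd) ** 2
    )


def gamma_oracle_agreement(seed=0, n_trials=20, noise_sd=0.05) -> dict:
    """Cross-validated polynomial fit vs brute-force evaluation of the same
    peak-extraction steps on the analytic curve (dense grid)."""
    rng = _rng(seed)
    grid = np.geomspace(*gamma_peak.FIT_RANGE, gamma_peak.N_GRID)
    dense = np.geomspace(*gamma_peak.FIT_RANGE, 40001)
    freq_errors, amp_errors = [], []
    for center, height in ((45.0, 0.2), (55.0, 0.3), (65.0, 0.4)):
        truth = analytic_delta(dense, center=center, height=height)
        oracle = gamma_peak._peak_from_curve(dense, truth)
        trials = analytic_delta(grid, center=center, height=height) + rng.normal(
            0.0, noise_sd, (n_trials, len(grid))
        )
        d = gamma_peak.DetrendedSpectrum(grid, trials, "baseline_ratio")
        order = gamma_peak.select_poly_order(d, rng=rng.integers(2**31))
        peak = gamma_peak.fit_gamma_peak(d, order)
        freq_errors.append(abs(peak.peak_freq - oracle.peak_freq))
        amp_errors.append(
            abs(peak.amplitude_fold - oracle.amplitude_fold) / oracle.amplitude_fold
        )
    return {
        "max_peak_freq_error_hz": float(max(freq_errors)),
        "max_amplitude_rel_error": float(max(amp_errors)),
    }


# ---------------------------------------------------------------------------
# PPC closed form and trial-count unbiasedness


def vonmises_ppc_expected(kappa: float) -> float:
    return float((i1(kappa) / i0(kappa)) ** 2) if kappa > 0 else 0.0


def ppc_calibration(seed=0, kappas=(0.0, 0.5, 1.0, 2.0), n_runs=200, n_trials=100):
    """Empirical mean PPC of von Mises phases vs the Bessel-ratio closed form."""
    rng = _rng(seed)
    out = {}
    for k in kappas:
        vals = np.array(
            [
                ppc_from_phases(
                    rng.vonmises(0.0, k, n_trials)
                    if k > 0
                    else rng.uniform(-np.pi, np.pi, n_trials)
                )
                for _ in range(n_runs)
            ]
        )
        se = vals.std(ddof=1) / np.sqrt(n_runs)
        target = vonmises_ppc_expected(k)
        out[k] = {
            "mean": float(vals.mean()),
            "target": target,
            "se": float(se),
            "z": float(abs(vals.mean() - target) / se),
        }
    return out


def ppc_trial_count_bias(seed=0, kappa=1.0, n_runs=2000, sizes=(10, 100)) -> dict:
    """Mean PPC at small vs large trial counts (should agree: unbiasedness)."""
    rng = _rng(seed)
    means, ses = [], []
    for n in sizes:
        vals = np.array(
            [ppc_from_phases(rng.vonmises(0.0, kappa, n)) for _ in range(n_runs)]
        )
        means.append(vals.mean())
        ses.append(vals.std(ddof=1) / np.sqrt(n_runs))
    gap = abs(means[0] - means[1])
    se = float(np.hypot(*ses))
    return {
        "mean_small": float(means[0]),
        "mean_large": float(means[1]),
        "gap": float(gap),
        "gap_se": se,
        "z": float(gap / se),
    }


# ---------------------------------------------------------------------------
# headline dissociation on full synthetic sessions


def dissociation_rate(seed=0, n_sessions=100, n_trials=10) -> dict:
    """Fraction of sessions reproducing gamma(uniform) > gamma(mismatch) AND
    rate_modulation(mismatch) > rate_modulation(uniform)."""
    rng = _rng(seed)
    session_seeds = rng.integers(0, 2**31, size=n_sessions)
    both = gamma_ok = rate_ok = 0
    for s in session_seeds:
        r = dissociation_experiment(int(s), n_trials=n_trials)
        gamma_ok += r["gamma_dissociation"]
        rate_ok += r["rate_dissociation"]
        both += r["gamma_dissociation"] and r["rate_dissociation"]
    return {
        "both_rate": both / n_sessions,
        "gamma_rate": gamma_ok / n_sessions,
        "rate_mod_rate": rate_ok / n_sessions,
        "n_sessions": n_sessions,
    }


# ---------------------------------------------------------------------------
# resampling statistics calibration


def bootstrap_sem_calibration(seed=0, n=100, sigma=1.0, n_replicates=50, b=1000):
    """Bootstrap SEM of a Gaussian mean vs the analytic sigma/sqrt(n)."""
    rng = _rng(seed)
    sems = [
        stats.bootstrap_sem(rng.normal(0.0, sigma, n), b=b, rng=rng).sem
        for _ in range(n_replicates)
    ]
    analytic = sigma / np.sqrt(n)
    return {
        "mean_sem": float(np.mean(sems)),
        "analytic": float(analytic),
        "rel_error": float(abs(np.mean(sems) - analytic) / analytic),
    }


def permutation_calibration(
    seed=0, n_experiments=200, n_bins=50, n_trials=20, n_permutations=1000,
    effect_sd=10.0,
) -> dict:
    """Family-wise error on null experiments and power on a single-bin shift."""
    rng = _rng(seed)
    false_pos = 0
    for _ in range(n_experiments):
        a = rng.standard_normal((n_trials, n_bins))
        b = rng.standard_normal((n_trials, n_bins))
        res = stats.permutation_test_corrected(
            a, b, n_permutations=n_permutations, rng=rng.integers(2**31)
        )
        false_pos += res.significant.any()
    detected = others_controlled = 0
    for _ in range(n_experiments):
        a = rng.standard_normal((n_trials, n_bins))
        b = rng.standard_normal((n_trials, n_bins))
        a[:, 0] += effect_sd
        res = stats.permutation_test_corrected(
            a, b, n_permutations=n_permutations, rng=rng.integers(2**31)
        )
        detected += bool(res.significant[0])
        others_controlled += not res.significant[1:].any()
    return {
        "family_wise_error": false_pos / n_experiments,
        "power_single_bin": detected / n_experiments,
        "other_bins_clean_rate": others_controlled / n_experiments,
    }


# ---------------------------------------------------------------------------
# microsaccade detector and censoring


def _spaced_times(rng, n, lo, hi, gap=0.15):
    while True:
        t = np.sort(rng.uniform(lo, hi, n))
        if n < 2 or np.diff(t).min() > gap:
            return t


def detector_calibration(
    seed=0, n_trials=200, n_saccades=5, duration=1.8, amplitude=0.3,
    match_window=0.02,
) -> dict:
    """Recall and false-alarm rate against injected microsaccades."""
    rng = _rng(seed)
    hits = false_alarms = injected = 0
    total_time = 0.0
    for _ in range(n_trials):
        inj = _spaced_times(rng, n_saccades, 0.1, duration - 0.2)
        gaze, _ = synth.simulate_eye(duration, inj, rng, amplitude=amplitude)
        events = firing.detect_microsaccades(gaze, synth.EYE_RATE)
        injected += len(inj)
        total_time += duration
        matched = set()
        for e in events:
            d = np.abs(inj - e.onset)
            j = int(np.argmin(d))
            if d[j] <= match_window and j not in matched:
                matched.add(j)
                hits += 1
            elif d[j] > match_window:
                false_alarms += 1
    return {
        "recall": hits / injected,
        "false_alarm_rate_per_s": false_alarms / total_time,
    }


def _short_epoch_gamma(lfp_trials, fs, onset, windows, rng_seed):
    """Gamma fold-change from 100 ms Hann epochs (stimulus vs baseline)."""
    stim_specs, base_specs = [], []
    n_epoch = int(round(0.1 * fs))
    for k, trial in enumerate(lfp_trials):
        for t0, t1 in windows[k]:
            i0 = int(round(t0 * fs))
            seg = trial[i0 : i0 + n_epoch]
            if len(seg) < n_epoch:
                continue
            ps = spectral.short_epoch_psd(seg, fs)
            (stim_specs if t0 >= onset else base_specs).append(ps.power)
    freqs = spectral.short_epoch_psd(np.zeros(n_epoch), fs).frequencies
    stim = spectral.PowerSpectrum(freqs, np.stack(stim_specs), 1, 0.1)
    base = spectral.PowerSpectrum(freqs, np.stack(base_specs), 1, 0.1)
    d = gamma_peak.delta_power(stim, base)
    order = gamma_peak.select_poly_order(d, rng=rng_seed)
    return gamma_peak.fit_gamma_peak(d, order)


def censoring_effect(seed=0, n_trials=30) -> dict:
    """Gamma fold-change with vs without microsaccade censoring when no
    saccades were injected (should be nearly unchanged)."""
    rng = _rng(seed)
    cond = synth.ConditionSpec("uniform", gamma_amplitude=3.0, gamma_decay_rate=0.0)
    fs = synth.LFP_RATE
    duration, onset = 1.8, 0.5
    trials, censored_windows, full_windows = [], [], []
    for _ in range(n_trials):
        lfp, _ = synth.simulate_lfp_trial(cond, duration, rng, onset=onset)
        trials.append(lfp)
        gaze, _ = synth.simulate_eye(duration, [], rng)
        events = firing.detect_microsaccades(gaze, synth.EYE_RATE)
        base_eps = firing.censor_after_microsaccades(onset, events, start=0.0)
        stim_eps = firing.censor_after_microsaccades(
            duration, events, start=onset + 0.3
        )
        censored_windows.append(base_eps + stim_eps)
        full_windows.append(
            firing.censor_after_microsaccades(onset, [], start=0.0)
            + firing.censor_after_microsaccades(duration, [], start=onset + 0.3)
        )
    full = _short_epoch_gamma(trials, fs, onset, full_windows, int(rng.integers(2**31)))
    cens = _short_epoch_gamma(
        trials, fs, onset, censored_windows, int(rng.integers(2**31))
    )
    return {
        "fold_full": full.amplitude_fold,
        "fold_censored": cens.amplitude_fold,
        "rel_change": abs(cens.amplitude_fold - full.amplitude_fold)
        / full.amplitude_fold,
    }


# ---------------------------------------------------------------------------
# cone-adaptation model recovery


def _random_backgrounds(rng, n):
    prim = colorimetry.monitor_primaries()
    spds = []
    for i in range(n):
        w = rng.uniform(0.05, 1.0, 3)
        e = sum(wi * p.energy for wi, p in zip(w, prim.values()))
        e = e + rng.uniform(0.0, 0.1) * np.mean(e)  # broadband pedestal
        spds.append(
            colorimetry.SpectralPowerDistribution(colorimetry.WAVELENGTHS, e, f"bg{i}")
        )
    return spds


def adaptation_model_recovery(seed=0, n_backgrounds=16, noise_sd=0.05) -> dict:
    """Generate gamma ratios from fixed cone-adaptation coefficients (sign
    structure: red-green M+, L-; blue-yellow S-, L+) and refit by OLS."""
    import pandas as pd

    rng = _rng(seed)
    cones = colorimetry.fit_cone_curves(colorimetry.synthetic_cone_fundamentals())
    triples = [
        colorimetry.adaptation_coefficients(s, cones)
        for s in _random_backgrounds(rng, n_backgrounds)
    ]
    pred = pd.DataFrame([t.as_dict() for t in triples])
    models = {
        "red_green": {"truth": {"M": 2.0, "L": -1.0}, "set": ("M", "L")},
        "blue_yellow": {"truth": {"S": -1.23, "L": 1.24}, "set": ("S", "L")},
    }
    out = {}
    for name, model_def in models.items():
        truth = model_def["truth"]
        y = sum(truth[c] * pred[c] for c in truth) + rng.normal(
            0.0, noise_sd, n_backgrounds
        )
        fit = colorimetry.fit_adaptation_model(y, pred, model_def["set"])
        zs = {
            c: abs(fit.coefficients[c] - truth[c]) / fit.stderr[c] for c in truth
        }
        lo, hi = fit.conf_int["const"]
        out[name] = {
            "max_coef_z": float(max(zs.values())),
            "signs_correct": all(
                np.sign(fit.coefficients[c]) == np.sign(truth[c]) for c in truth
            ),
            "intercept_ci_covers_zero": bool(lo <= 0.0 <= hi),
            "r_squared": fit.r_squared,
        }
    return out


# ---------------------------------------------------------------------------
# DKL identities


def dkl_identity_checks() -> dict:
    """Exact identities of the DKL projection (machine precision)."""
    bg = np.array([0.7, 0.5, 0.2])
    same = colorimetry.dkl_coordinates(bg, bg)
    scaled = colorimetry.dkl_coordinates(1.1 * bg, bg)
    return {
        "identity_max_abs": float(
            max(abs(same.lum), abs(same.rg), abs(same.by))
        ),
        "scaling_chromatic_max_abs": float(max(abs(scaled.rg), abs(scaled.by))),
        "scaling_luminance": scaled.lum,
    }
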