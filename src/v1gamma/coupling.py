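"""Spike-field locking via the pairwise phase consistency (PPC).

Per trial, the cross-spectral density between the MU envelope of one
electrode and the LFP of a neighboring electrode is estimated with the same
multitaper settings as the power spectra, then normalized to unit modulus so
only the cross-spectral phase remains. The PPC over trials,

    PPC(f) = mean over trial pairs (j != k) of cos(phi_j - phi_k)
           = (|sum_j exp(i phi_j)|^2 - N) / (N (N - 1)),

is free of the trial-count bias that affects ordinary coherence. Pairs are
restricted to direct grid neighbors (4-neighborhood) at the same electrode
depth; same-electrode pairs are excluded because spike bleed-in into the
local LFP produces artifactual coherence. Across-session SEM is computed by
plain standard error, never by bootstrap (bootstrap resamples repeat
identical trials, which trivially inflates PPC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

from .preprocess import TrialEpoch
from .spectral import taper_count


@dataclass
class PhaseSpectrum:
    """Per-trial unit phasors of the MU-LFP cross-spectrum."""

    frequencies: np.ndarray
    unit_phasors: np.ndarray  # (n_trials, n_freq) complex, |.| = 1
    trial_ids: list
    pair_id: tuple = (-1, -1)

    def __post_init__(self):
        self.unit_phasors = np.atleast_2d(np.asarray(self.unit_phasors))


@dataclass
class PPCSpectrum:
    frequencies: np.ndarray
    ppc: np.ndarray
    n_trials: int
    pair_id: tuple = (-1, -1)


def _tapered_fft(x, sampling_rate, half_bandwidth):
    n = len(x)
    duration = n / sampling_rate
    k = taper_count(duration, half_bandwidth)
    if k < 1:
        raise ValueError("bandwidth too small for epoch")
    tapers = windows.dpss(n, duration * half_bandwidth, Kmax=k)
    tapers = tapers / np.sqrt((tapers**2).sum(axis=1, keepdims=True))
    return np.fft.rfft(tapers * x[None, :], axis=-1)


def trial_cross_spectrum(
    mu: TrialEpoch,
    lfp: TrialEpoch,
    half_bandwidth: float = 5.0,
    allow_same_electrode: bool = False,
) -> np.ndarray:
    """Taper-averaged, modulus-normalized cross-spectrum of one trial.

    Returns (frequencies, unit phasors). Same-electrode combinations raise
    unless explicitly overridden (test use only).
    """
    if mu.channel_id == lfp.channel_id and not allow_same_electrode:
        raise ValueError("MU-LFP combinations from the same electrode are excluded")
    if len(mu.samples) != len(lfp.samples) or mu.sampling_rate != lfp.sampling_rate:
        raise ValueError("epochs must share duration and sampling rate")
    fm = _tapered_fft(mu.samples - mu.samples.mean(), mu.sampling_rate, half_bandwidth)
    fl = _tapered_fft(lfp.samples - lfp.samples.mean(), lfp.sampling_rate, half_bandwidth)
    cross = np.mean(np.conj(fm) * fl, axis=0)
    mod = np.abs(cross)
    mod[mod == 0] = 1.0
    freqs = np.fft.rfftfreq(len(mu.samples), d=1.0 / mu.sampling_rate)
    return freqs, cross / mod


def phase_spectrum(
    mu_epochs: list, lfp_epochs: list, half_bandwidth: float = 5.0, **kw
) -> PhaseSpectrum:
    """Stack per-trial unit phasors for one MU-LFP pair."""
    phasors, freqs = [], None
    for m, l in zip(mu_epochs, lfp_epochs):
        freqs, ph = trial_cross_spectrum(m, l, half_bandwidth, **kw)
        phasors.append(ph)
    pair = (mu_epochs[0].channel_id, lfp_epochs[0].channel_id)
    return PhaseSpectrum(freqs, np.stack(phasors), [m.trial_id for m in mu_epochs], pair)


def ppc(phases: PhaseSpectrum) -> PPCSpectrum:
    """Pairwise phase consistency over trials at each frequency."""
    z = phases.unit_phasors
    n = z.shape[0]
    if n < 2:
        raise ValueError("PPC undefined for fewer than 2 trials")
    s = np.abs(z.sum(axis=0)) ** 2
    val = (s - n) / (n * (n - 1))
    return PPCSpectrum(phases.frequencies, val, n, phases.pair_id)


def ppc_from_phases(angles: np.ndarray) -> float:
    """PPC of a 1-D array of phase angles (radians)."""
    z = np.exp(1j * np.asarray(angles, dtype=float))
    n = len(z)
    if n < 2:
        raise ValueError("PPC undefined for fewer than 2 trials")
    return float((np.abs(z.sum()) ** 2 - n) / (n * (n - 1)))


def select_pairs(
    positions: np.ndarray,
    depths: np.ndarray = None,
    sites: list = None,
    spacing: float = 1.0,
) -> list:
    """All MU-LFP pairs of direct grid neighbors at the same depth.

    ``positions`` are grid coordinates (units of ``spacing``); adjacency is
    the 4-neighborhood (distance exactly one grid step). Returns ordered
    (mu_site, lfp_site) tuples for every site in ``sites`` (default: all).
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2:
        raise ValueError("channel grid coordinates are required")
    n = len(pos)
    depths = np.zeros(n) if depths is None else np.asarray(depths)
    sites = range(n) if sites is None else sites
    pairs = []
    for i in sites:
        for j in range(n):
            if j == i or depths[j] != depths[i]:
                continue
            if np.isclose(np.linalg.norm(pos[j] - pos[i]), spacing):
                pairs.append((int(i), int(j)))
    return pairs


def ppc_per_site(ppc_by_pair: dict) -> dict:
    """Average PPC spectra over each MU site's valid LFP partners."""
    out = {}
    sites = sorted({mu for mu, _ in ppc_by_pair})
    for s in sites:
        specs = [v for (mu, _), v in ppc_by_pair.items() if mu == s]
        out[s] = PPCSpectrum(
            specs[0].frequencies,
            np.mean([v.ppc for v in specs], axis=0),
            specs[0].n_trials,
            (s, -1),
        )
    return out


def sem_across_sessions(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Plain SEM across sessions (the PPC error estimate)."""
    v = np.asarray(values, dtype=float)
    return v.std(axis=axis, ddof=1) / np.sqrt(v.shape[axis])
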