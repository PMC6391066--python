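"""Multitaper and Hann spectral estimation with the study's normalizations.

Power spectra of 0.3-0.5 s trial epochs are estimated with DPSS (Slepian)
multitapers giving +/-5 Hz smoothing; the taper count follows the Shannon
number convention K = floor(2 T W) - 1 (4 tapers for a 0.5 s epoch at
W = 5 Hz, 2 for 0.3 s). Three normalizations are supported:

* ``baseline_total`` -- divide all spectra of an electrode by the scalar
  total baseline power above a frequency floor (default 25 Hz), which
  removes per-electrode gain while preserving per-bin comparisons.
* ``fold_change`` -- divide single-trial stimulus spectra by the trial- and
  condition-averaged baseline spectrum; 1 means no change, with a dB view
  10*log10(ratio).
* raw one-sided density in arbitrary units (gains cancel downstream).

Time-frequency maps use a sliding 0.3 s Hann window stepped by 50 ms, and
very short (100 ms) epochs around fixational eye movements use a Hann taper
zero-padded to 1 s (interpolating the spectrum to a 1 Hz grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import windows


@dataclass
class PowerSpectrum:
    """Tapered spectral estimate(s) on a common frequency grid.

    ``power`` may be 1-D (one spectrum) or 2-D (n_spectra x n_freq).
    """

    frequencies: np.ndarray
    power: np.ndarray
    n_tapers: int = 1
    epoch_duration: float = 0.0
    normalization: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    def mean(self) -> "PowerSpectrum":
        p = self.power if self.power.ndim == 1 else self.power.mean(axis=0)
        return PowerSpectrum(
            self.frequencies, p, self.n_tapers, self.epoch_duration, self.normalization
        )

    def band(self, lo: float, hi: float) -> np.ndarray:
        return (self.frequencies >= lo) & (self.frequencies <= hi)


@dataclass
class TimeFrequencyMap:
    times: np.ndarray
    frequencies: np.ndarray
    values: np.ndarray  # (n_times, n_freq)
    window: float
    step: float


def taper_count(duration: float, half_bandwidth: float) -> int:
    """Number of DPSS tapers: K = floor(2*T*W) - 1."""
    return int(np.floor(2.0 * duration * half_bandwidth)) - 1


def multitaper_psd(
    samples: np.ndarray, sampling_rate: float, half_bandwidth: float = 5.0
) -> PowerSpectrum:
    """One-sided multitaper PSD of one epoch or a stack of epochs.

    ``samples`` is (n_samples,) or (n_epochs, n_samples). Per-taper
    periodograms are averaged; the estimate satisfies Parseval
    (sum(power) * df ~ taper-weighted variance).
    """
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    n = x.shape[-1]
    duration = n / sampling_rate
    k = taper_count(duration, half_bandwidth)
    if k < 1:
        raise ValueError(
            f"bandwidth too small for epoch: 2*{duration:g}*{half_bandwidth:g}-1 < 1"
        )
    nw = duration * half_bandwidth
    tapers = windows.dpss(n, nw, Kmax=k)  # (k, n)
    tapers = tapers / np.sqrt((tapers**2).sum(axis=1, keepdims=True))
    # (n_epochs, k, n_freq)
    spec = np.fft.rfft(x[:, None, :] * tapers[None, :, :], axis=-1)
    psd = (np.abs(spec) ** 2) / sampling_rate
    psd[..., 1:] *= 2.0
    if n % 2 == 0:
        psd[..., -1] /= 2.0
    psd = psd.mean(axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    if psd.shape[0] == 1:
        psd = psd[0]
    return PowerSpectrum(freqs, psd, n_tapers=k, epoch_duration=duration)


def normalize_by_baseline_total(
    spectra: PowerSpectrum, baseline: PowerSpectrum, floor_hz: float = 25.0
) -> tuple:
    """Divide stimulus and baseline spectra by total baseline power > floor.

    The divisor is the mean-over-epochs baseline power summed (integrated)
    above ``floor_hz``; both returned objects share it, so raw per-bin
    comparisons across conditions stay valid.
    """
    base_mean = baseline.mean().power
    sel = baseline.frequencies > floor_hz
    df = np.median(np.diff(baseline.frequencies))
    total = float(np.sum(base_mean[sel]) * df)
    if total <= 0:
        raise ValueError("zero total baseline power above floor")
    out_s = PowerSpectrum(
        spectra.frequencies,
        spectra.power / total,
        spectra.n_tapers,
        spectra.epoch_duration,
        "baseline_total",
        {"floor_hz": floor_hz, "divisor": total},
    )
    out_b = PowerSpectrum(
        baseline.frequencies,
        baseline.power / total,
        baseline.n_tapers,
        baseline.epoch_duration,
        "baseline_total",
        {"floor_hz": floor_hz, "divisor": total},
    )
    return out_s, out_b


def fold_change(stim: PowerSpectrum, base_mean: PowerSpectrum) -> PowerSpectrum:
    """Per-frequency ratio of stimulus power to the mean baseline spectrum."""
    if stim.frequencies.shape != base_mean.frequencies.shape or not np.allclose(
        stim.frequencies, base_mean.frequencies
    ):
        raise ValueError("frequency grid mismatch between stimulus and baseline")
    base = base_mean.mean().power
    if np.any(base <= 0):
        raise ValueError("baseline power must be positive")
    return PowerSpectrum(
        stim.frequencies,
        stim.power / base,
        stim.n_tapers,
        stim.epoch_duration,
        "fold_change",
    )


def to_db(ratio: np.ndarray) -> np.ndarray:
    """dB view of a power ratio: 10*log10(ratio)."""
    return 10.0 * np.log10(np.asarray(ratio, dtype=float))


def from_db(db: np.ndarray) -> np.ndarray:
    return 10.0 ** (np.asarray(db, dtype=float) / 10.0)


def tfr(
    samples: np.ndarray,
    sampling_rate: float,
    window: float = 0.3,
    step: float = 0.05,
    t_start: float = 0.0,
) -> TimeFrequencyMap:
    """Sliding Hann-tapered power; times are window centers."""
    x = np.asarray(samples, dtype=float)
    nwin = int(round(window * sampling_rate))
    nstep = int(round(step * sampling_rate))
    if len(x) < nwin:
        raise ValueError("trace shorter than analysis window")
    starts = np.arange(0, len(x) - nwin + 1, nstep)
    taper = windows.hann(nwin, sym=False)
    u = np.sum(taper**2)
    segs = np.stack([x[s : s + nwin] for s in starts]) * taper
    spec = np.abs(np.fft.rfft(segs, axis=-1)) ** 2 / (sampling_rate * u)
    spec[..., 1:] *= 2.0
    if nwin % 2 == 0:
        spec[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(nwin, d=1.0 / sampling_rate)
    times = t_start + (starts + nwin / 2.0) / sampling_rate
    return TimeFrequencyMap(times, freqs, spec, window, step)


def short_epoch_psd(
    samples: np.ndarray,
    sampling_rate: float,
    epoch_duration: float = 0.1,
    pad_to: float = 1.0,
) -> PowerSpectrum:
    """Hann-tapered PSD of a 100 ms epoch, zero-padded to 1 s.

    Padding interpolates the spectrum onto a ~1 Hz grid without adding
    power (total power is padding-invariant); interpret only f > 20 Hz.
    """
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    n = x.shape[-1]
    if n != int(round(epoch_duration * sampling_rate)):
        raise ValueError(
            f"epoch must be exactly {epoch_duration:g} s "
            f"({int(round(epoch_duration * sampling_rate))} samples), got {n}"
        )
    n_pad = int(round(pad_to * sampling_rate))
    taper = windows.hann(n, sym=False)
    u = np.sum(taper**2)
    spec = np.fft.rfft(x * taper, n=n_pad, axis=-1)
    # density on the finer padded grid; total power (sum * df) is pad-invariant
    psd = (np.abs(spec) ** 2) / (sampling_rate * u)
    psd[..., 1:] *= 2.0
    if n_pad % 2 == 0:
        psd[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n_pad, d=1.0 / sampling_rate)
    if psd.shape[0] == 1:
        psd = psd[0]
    return PowerSpectrum(freqs, psd, n_tapers=1, epoch_duration=epoch_duration)
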