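"""Signal derivation: LFP decimation, line-noise removal, MU envelopes, epoching.

The derivation contracts mirror standard primate electrophysiology practice:
broadband voltage digitized at 24.4140625 kHz is low-pass filtered with an
order-30 FIR (cutoff rate/48) and kept at every 24th sample to form the LFP;
50/100/150 Hz mains components are removed with narrow two-pass Butterworth
band-stops; the multi-unit (MU) envelope comes from 300-6000 Hz band-pass,
rectification and the same low-pass/decimation as the LFP.

All two-pass filters are applied forward-backward (zero net phase). The
decimation FIR is also applied zero-phase, which removes its group delay
while leaving the magnitude response untouched; this is a deliberate
departure from single-pass ``decimate``-style filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

#: Nominal broadband digitization rate in Hz.
BROADBAND_RATE = 24414.0625
#: Decimation factor from broadband to LFP rate.
DECIMATION = 24
#: Decimated LFP rate in Hz (~1017.25).
LFP_RATE = BROADBAND_RATE / DECIMATION

#: Mains band-stop edges in Hz (fundamental plus two harmonics).
LINE_BANDS = ((49.9, 50.1), (99.7, 100.3), (149.5, 150.5))


@dataclass
class Trace:
    """A single-channel time series with its sampling rate."""

    samples: np.ndarray
    sampling_rate: float
    channel_id: int = 0
    provenance: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")


# Semantic aliases used throughout: broadband input, LFP, MU envelope.
BroadbandTrace = Trace
LfpTrace = Trace
MuEnvelope = Trace


@dataclass
class TrialEpoch:
    """A trace segment cut relative to stimulus onset.

    ``t0`` is the segment start in seconds relative to onset (negative for
    baseline epochs).
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float
    duration: float
    condition: str = ""
    trial_id: int = -1
    channel_id: int = 0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.duration <= 0:
            raise ValueError("epoch duration must be positive")


def decimation_fir(order: int = 30, cutoff_frac: float = 0.5 / DECIMATION) -> np.ndarray:
    """Hamming-windowed sinc low-pass used for LFP/MU decimation.

    ``cutoff_frac`` is the cutoff as a fraction of the input sampling rate
    (default rate/48, i.e. half the post-decimation Nyquist band edge).
    """
    return signal.firwin(order + 1, 2.0 * cutoff_frac, window="hamming")


def derive_lfp(x: BroadbandTrace, order: int = 30, q: int = DECIMATION) -> LfpTrace:
    """Low-pass (zero-phase FIR) and decimate a broadband trace to the LFP.

    Raises if the trace is shorter than the filter order.
    """
    if len(x.samples) <= order:
        raise ValueError(f"trace of {len(x.samples)} samples shorter than FIR order {order}")
    taps = decimation_fir(order, 0.5 / q)
    low = signal.filtfilt(taps, [1.0], x.samples)
    return LfpTrace(
        samples=low[::q],
        sampling_rate=x.sampling_rate / q,
        channel_id=x.channel_id,
        provenance=f"{x.provenance}+fir{order}_decim{q}",
    )


def remove_line_noise(x: LfpTrace, bands=LINE_BANDS) -> LfpTrace:
    """Two-pass 4th-order Butterworth band-stops at the mains harmonics.

    The combined forward-backward response |H(f)|^2 (zero phase by
    construction) is applied spectrally: the sub-Hz-wide notches ring for
    seconds, so a sample-domain two-pass filter would contaminate epoch-length
    traces with boundary transients, while the frequency-domain product
    realizes the exact steady-state magnitude response at any trace length.
    """
    if x.sampling_rate <= 2 * max(b[1] for b in bands):
        raise ValueError("sampling rate too low for requested stop bands")
    y = x.samples
    n = len(y)
    freqs = np.fft.rfftfreq(n, d=1.0 / x.sampling_rate)
    resp = np.ones(len(freqs))
    for lo, hi in bands:
        sos = signal.butter(2, [lo, hi], btype="bandstop", fs=x.sampling_rate, output="sos")
        _, h = signal.sosfreqz(sos, worN=freqs, fs=x.sampling_rate)
        resp *= np.abs(h) ** 2
    y = np.fft.irfft(np.fft.rfft(y) * resp, n=n)
    return LfpTrace(
        samples=y,
        sampling_rate=x.sampling_rate,
        channel_id=x.channel_id,
        provenance=f"{x.provenance}+linestop",
    )


def derive_mu(
    x: BroadbandTrace,
    band: tuple = (300.0, 6000.0),
    order: int = 30,
    q: int = DECIMATION,
) -> MuEnvelope:
    """Band-pass, rectify and decimate a broadband trace to the MU envelope.

    The final low-pass/decimation step reuses the LFP contract; small
    negative ripple it introduces is clipped to zero (envelope semantics).
    """
    if len(x.samples) <= order:
        raise ValueError(f"trace of {len(x.samples)} samples shorter than FIR order {order}")
    sos = signal.butter(4, band, btype="bandpass", fs=x.sampling_rate, output="sos")
    rectified = np.abs(signal.sosfiltfilt(sos, x.samples))
    env = derive_lfp(
        Trace(rectified, x.sampling_rate, x.channel_id, x.provenance), order=order, q=q
    )
    return MuEnvelope(
        samples=np.clip(env.samples, 0.0, None),
        sampling_rate=env.sampling_rate,
        channel_id=x.channel_id,
        provenance=f"{x.provenance}+mu{band[0]:g}-{band[1]:g}",
    )


def smooth_rate(samples: np.ndarray, sampling_rate: float, sd: float = 0.020) -> np.ndarray:
    """Gaussian smoothing (SD in seconds, default 20 ms) with edge correction.

    The kernel has unit mass and is truncated at +/-4 SD; edges are
    renormalized by the local kernel mass so a constant input maps to the
    same constant.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    x = np.asarray(samples, dtype=float)
    half = max(1, int(round(4 * sd * sampling_rate)))
    t = np.arange(-half, half + 1) / sampling_rate
    kernel = np.exp(-0.5 * (t / sd) ** 2)
    kernel /= kernel.sum()
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def epoch(
    samples: np.ndarray,
    sampling_rate: float,
    onset: float,
    window: tuple,
    condition: str = "",
    trial_id: int = -1,
    channel_id: int = 0,
) -> TrialEpoch:
    """Cut ``window=[a, b]`` seconds relative to stimulus ``onset`` (s).

    Out-of-range windows raise rather than returning a truncated segment.
    """
    a, b = window
    if b <= a:
        raise ValueError("window must satisfy a < b")
    i0 = int(round((onset + a) * sampling_rate))
    # fix the sample count from the duration so equal-length windows always
    # yield equal-length segments regardless of onset rounding
    i1 = i0 + int(round((b - a) * sampling_rate))
    if i0 < 0 or i1 > len(samples):
        raise ValueError(
            f"epoch window {window} out of range for trial {trial_id} "
            f"({len(samples)} samples at {sampling_rate:g} Hz, onset {onset:g} s)"
        )
    return TrialEpoch(
        samples=np.asarray(samples[i0:i1], dtype=float),
        sampling_rate=sampling_rate,
        t0=a,
        duration=b - a,
        condition=condition,
        trial_id=trial_id,
        channel_id=channel_id,
    )


def bipolar_derivation(lfp: np.ndarray, positions: np.ndarray, spacing: float = 1.0):
    """Optional local bipolar re-reference: subtract each channel's nearest
    grid neighbor. Returns (derived array, pair list); channels without a
    neighbor at one grid step are dropped.
    """
    lfp = np.asarray(lfp)
    pos = np.asarray(positions, dtype=float)
    pairs = []
    for i in range(len(pos)):
        d = np.linalg.norm(pos - pos[i], axis=1)
        j = np.where(np.isclose(d, spacing))[0]
        if len(j):
            pairs.append((i, int(j[0])))
    if not pairs:
        return np.empty((0,) + lfp.shape[1:]), []
    out = np.stack([lfp[..., i, :] - lfp[..., j, :] for i, j in pairs], axis=-2)
    return out, pairs
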