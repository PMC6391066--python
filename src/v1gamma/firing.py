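"""Firing-rate modulation metrics, microsaccade detection, pupil responses.

Rate modulation is ``log10(M_stim / M_base)`` of MU activity, so negative
values mark sustained suppression below baseline. Surround suppression is
the drop in rate modulation relative to the smallest (0.5 deg) stimulus.
Gamma fold-changes between conditions are compared with the modulation
index (A - B)/(A + B) on amplitudes A, B = fold-change - 1.

Microsaccades are detected with a velocity-criterion threshold: gaze is
boxcar-smoothed (+/-5 ms), differentiated over 10 ms, and samples where
|v| on either axis exceeds 6*c are events, with the per-axis, per-trial
criterion c = Median[v^2] - (Median[v])^2 taken exactly in this
variance-like form (the multiplier is configurable). Epochs of 100 ms after
each event are censored before re-epoching for short-window spectra. Pupil
responses are percent change (A - B)/|B| from the 200 ms pre-onset
baseline; tracker units may be negative, hence the absolute denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class RateModulation:
    value: float  # log10 ratio
    stim_window: tuple = (0.0, 0.0)
    base_window: tuple = (0.0, 0.0)
    site: int = -1
    condition: str = ""


@dataclass
class MicrosaccadeEvent:
    onset: float  # s
    offset: float  # s
    axis: str  # "horizontal" | "vertical" | "both"
    peak_velocity: float  # deg/s


@dataclass
class PupilResponse:
    percent_change: np.ndarray
    baseline_window: tuple
    baseline_value: float


def rate_modulation(
    stim_mean: float, base_mean: float, stim_window=(0.3, 1.3), base_window=(-0.5, 0.0),
    site: int = -1, condition: str = "",
) -> RateModulation:
    """log10 of stimulus-period over baseline-period MU activity."""
    if base_mean <= 0:
        raise ValueError("baseline activity must be positive")
    if stim_mean <= 0:
        raise ValueError("stimulus activity must be positive for a log ratio")
    return RateModulation(
        float(np.log10(stim_mean / base_mean)), stim_window, base_window, site, condition
    )


def surround_suppression(mods_by_size: dict, reference: float = 0.5) -> dict:
    """Rate-modulation drop relative to the reference (0.5 deg) size."""
    if reference not in mods_by_size:
        raise ValueError(f"reference size {reference} deg missing")
    ref = mods_by_size[reference]
    ref_v = ref.value if isinstance(ref, RateModulation) else float(ref)
    out = {}
    for size, m in mods_by_size.items():
        v = m.value if isinstance(m, RateModulation) else float(m)
        out[size] = ref_v - v
    return out


def modulation_index(fold_a: float, fold_b: float) -> float:
    """(A - B)/(A + B) on gamma amplitudes A, B = fold-change - 1.

    Fold-changes below 1 (no peak) are clamped to 1 with a warning; both
    amplitudes zero is defined as index 0.
    """
    if fold_a < 1 or fold_b < 1:
        warnings.warn("fold-change below 1 clamped to 1 (no-peak convention)")
    a = max(float(fold_a), 1.0) - 1.0
    b = max(float(fold_b), 1.0) - 1.0
    if a == 0.0 and b == 0.0:
        return 0.0
    return (a - b) / (a + b)


def eye_velocity(
    gaze: np.ndarray, sampling_rate: float, smooth_halfwidth: float = 0.005,
    diff_interval: float = 0.010,
) -> np.ndarray:
    """Robust per-axis eye velocity (deg/s): boxcar +/-5 ms, 10 ms central
    difference. ``gaze`` is (2, n) or (n_eyes, 2, n) (eyes averaged first)."""
    g = np.asarray(gaze, dtype=float)
    if g.ndim == 3:
        g = g.mean(axis=0)
    if g.ndim != 2 or g.shape[0] != 2:
        raise ValueError("gaze must be (2, n_samples) after eye averaging")
    half = max(1, int(round(smooth_halfwidth * sampling_rate)))
    box = np.ones(2 * half + 1) / (2 * half + 1)
    # edge-replicated padding: zero padding would fake velocities at the
    # trace boundaries whenever gaze sits away from zero
    sm = np.stack(
        [np.convolve(np.pad(a, half, mode="edge"), box, mode="valid") for a in g]
    )
    k = max(1, int(round(diff_interval * sampling_rate / 2)))
    if sm.shape[1] <= 2 * k:
        raise ValueError("trace too short for velocity differentiation")
    v = np.zeros_like(sm)
    v[:, k:-k] = (sm[:, 2 * k :] - sm[:, : -2 * k]) / (2 * k / sampling_rate)
    v[:, :k] = v[:, k : k + 1]
    v[:, -k:] = v[:, -k - 1 : -k]
    return v


def velocity_criterion(v: np.ndarray) -> np.ndarray:
    """Per-axis criterion c = Median[v^2] - (Median[v])^2."""
    v = np.atleast_2d(np.asarray(v, dtype=float))
    return np.median(v**2, axis=1) - np.median(v, axis=1) ** 2


def detect_microsaccades(
    gaze: np.ndarray,
    sampling_rate: float,
    multiplier: float = 6.0,
    merge_interval: float = 0.010,
) -> list:
    """Velocity-threshold microsaccade detection on either gaze axis.

    A degenerate axis (c = 0, e.g. constant velocity) is excluded from
    thresholding. Contiguous supra-threshold samples, and events closer
    than ``merge_interval``, merge into one event.
    """
    v = eye_velocity(gaze, sampling_rate)
    c = velocity_criterion(v)
    above = np.zeros(v.shape[1], dtype=bool)
    for ax in range(2):
        if c[ax] > 0:
            above |= np.abs(v[ax]) > multiplier * c[ax]
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    gap = max(1, int(round(merge_interval * sampling_rate)))
    splits = np.flatnonzero(np.diff(idx) > gap)
    runs = np.split(idx, splits + 1)
    events = []
    for run in runs:
        i0, i1 = run[0], run[-1]
        seg = np.abs(v[:, i0 : i1 + 1])
        hor = c[0] > 0 and (seg[0] > multiplier * c[0]).any()
        ver = c[1] > 0 and (seg[1] > multiplier * c[1]).any()
        axis = "both" if (hor and ver) else ("horizontal" if hor else "vertical")
        events.append(
            MicrosaccadeEvent(
                onset=i0 / sampling_rate,
                offset=(i1 + 1) / sampling_rate,
                axis=axis,
                peak_velocity=float(seg.max()),
            )
        )
    return events


def censor_after_microsaccades(
    duration: float,
    events: list,
    pad: float = 0.1,
    epoch_length: float = 0.1,
    start: float = 0.0,
) -> list:
    """Retained [t0, t1) epochs after removing ``pad`` s following each event.

    The kept time is re-tiled into non-overlapping ``epoch_length`` segments
    suitable for short-epoch spectra.
    """
    cuts = sorted((e.onset if hasattr(e, "onset") else float(e)) for e in events)
    keep, t = [], start
    for onset in cuts:
        if onset > t:
            keep.append((t, min(onset, duration)))
        t = max(t, onset + pad)
    if t < duration:
        keep.append((t, duration))
    epochs = []
    for a, b in keep:
        k = a
        while k + epoch_length <= b + 1e-12:
            epochs.append((k, k + epoch_length))
            k += epoch_length
    return epochs


def pupil_response(
    pupil: np.ndarray,
    sampling_rate: float,
    onset: float,
    baseline_window: tuple = (-0.2, 0.0),
) -> PupilResponse:
    """Percent change (A - B)/|B| from the pre-onset baseline mean B."""
    p = np.asarray(pupil, dtype=float)
    if p.ndim == 2:  # binocular -> average eyes
        p = p.mean(axis=0)
    i0 = int(round((onset + baseline_window[0]) * sampling_rate))
    i1 = int(round((onset + baseline_window[1]) * sampling_rate))
    if i0 < 0 or i1 > len(p) or i1 <= i0:
        raise ValueError("baseline window outside trace")
    b = p[i0:i1].mean()
    if b == 0:
        raise ValueError("zero baseline pupil value")
    return PupilResponse((p - b) / abs(b), baseline_window, float(b))
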