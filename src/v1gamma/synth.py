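"""Synthetic V1 session generator with ground truth.

Sessions emulate the statistical structure the downstream analyses assume:

* LFP = 1/f^n Gaussian background + a narrow-band stochastic gamma
  component (white noise band-passed at the condition's peak frequency
  +/- 5 Hz, amplitude-scaled and gated by the stimulus with an exponential
  within-trial decay) + optional 50/100/150 Hz line components + a biphasic
  spike bleed-in kernel convolved with the same channel's spike train.
* Spiking is an inhomogeneous point process whose intensity is a firing
  profile (onset transient, sustained level that may fall below baseline -
  surround suppression) multiplied by a von Mises gain on the instantaneous
  gamma phase with concentration ``locking_kappa``. The MU envelope is the
  spike train passed through the same rectify+low-pass contract as the
  preprocessing module.
* Eye traces are fixational drift/tremor noise with step-plus-overshoot
  microsaccades injected at known times; the pupil shows a stimulus-locked
  constriction in negative tracker-like units.

The gamma component's band-passed-noise construction gives it a realistic
spectral bandwidth, so peak fitting is exercised nontrivially. All scaling
is analytic: the gamma target power spectral density at the peak equals
``gamma_amplitude`` times the (known) background density there, so a
fold-change of about 1 + gamma_amplitude * <envelope^2> is injected.

One seeded generator per session is split per trial by counter, so output
is bit-identical for identical (config, seed) and robust to reordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal
from scipy.signal import hilbert
from scipy.special import i0

from .preprocess import LFP_RATE, decimation_fir
from .session import SessionData

EYE_RATE = 1000.0


@dataclass
class ConditionSpec:
    """Stimulus condition with its injected oscillation and firing profile."""

    label: str
    gamma_amplitude: float = 2.0  # x background PSD at the peak
    gamma_peak_freq: float = 55.0  # Hz
    gamma_decay_rate: float = 0.3  # 1/s within-trial amplitude decay
    rate_baseline: float = 20.0  # spikes/s before onset
    rate_transient: float = 80.0  # spikes/s transient peak
    rate_sustained: float = 15.0  # spikes/s sustained (may be < baseline)
    locking_kappa: float = 0.5  # von Mises concentration of spike phases
    spectral_exponent: float = 2.0  # n of the 1/f^n background
    line_amplitudes: tuple = (0.0, 0.0, 0.0)  # 50/100/150 Hz sinusoid amps
    bleed_amplitude: float = 0.02  # spike bleed-in kernel scale
    pupil_constriction: float = 150.0  # tracker units at steady state

    def validate(self):
        if not (20.0 < self.gamma_peak_freq < 150.0):
            raise ValueError("gamma_peak_freq must lie in (20, 150) Hz")
        if self.locking_kappa < 0:
            raise ValueError("locking_kappa must be >= 0")
        if self.spectral_exponent < 0:
            raise ValueError("spectral_exponent must be >= 0")
        if self.gamma_amplitude < 0:
            raise ValueError("gamma_amplitude must be >= 0")
        if min(self.rate_baseline, self.rate_transient, self.rate_sustained) < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class SimulationConfig:
    conditions: list
    n_trials_per_condition: int = 12
    sampling_rate: float = LFP_RATE
    baseline_duration: float = 0.5
    stimulus_duration: float = 1.3
    grid_shape: tuple = (2, 2)
    grid_spacing: float = 1.0
    saccade_rate: float = 0.5  # injected microsaccades per second
    saccade_amplitude: float = 0.3  # deg
    eye_noise_sd: float = 0.05  # deg tracker noise per sample
    seed: int = 0
    session_id: str = "synthetic"
    monkey: str = "S"

    def validate(self):
        if self.baseline_duration <= 0 or self.stimulus_duration <= 0:
            raise ValueError("durations must be positive")
        if self.n_trials_per_condition < 1:
            raise ValueError("n_trials_per_condition must be >= 1")
        if not self.conditions:
            raise ValueError("conditions must be non-empty")
        for c in self.conditions:
            c.validate()


@dataclass
class SyntheticGroundTruth:
    """Injected parameters per generated trial (immutable record)."""

    trials: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        def clean(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        text = json.dumps(clean(self.trials), indent=1)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text


def background_psd(freqs: np.ndarray, exponent: float, floor_hz: float = 2.0) -> np.ndarray:
    """Target one-sided background density: f^-n, flattened below floor_hz."""
    f = np.maximum(np.asarray(freqs, dtype=float), floor_hz)
    return f ** (-exponent)


def _colored_noise(n: int, fs: float, exponent: float, rng) -> np.ndarray:
    """Gaussian noise whose one-sided PSD is :func:`background_psd`."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    target = background_psd(freqs, exponent)
    target[0] = 0.0
    amp = np.sqrt(target * fs * n / 2.0)
    z = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    z *= np.sqrt(0.5)
    z[0] = z[0].real
    if n % 2 == 0:
        z[-1] = z[-1].real * np.sqrt(2.0)
    return np.fft.irfft(amp * z, n=n)


def _gamma_band_noise(n: int, fs: float, cond: ConditionSpec, rng) -> np.ndarray:
    """Band-passed white noise scaled so its PSD at the peak equals
    gamma_amplitude times the background PSD there."""
    lo = max(1.0, cond.gamma_peak_freq - 5.0)
    hi = min(fs / 2 - 1.0, cond.gamma_peak_freq + 5.0)
    sos = signal.butter(3, [lo, hi], btype="bandpass", fs=fs, output="sos")
    target_peak = cond.gamma_amplitude * background_psd(
        np.array([cond.gamma_peak_freq]), cond.spectral_exponent
    )[0]
    sigma_w = np.sqrt(target_peak * fs / 2.0)
    white = rng.standard_normal(n) * sigma_w
    return signal.sosfiltfilt(sos, white)


def _gamma_envelope(t: np.ndarray, onset: float, decay: float, ramp: float = 0.02):
    env = np.zeros_like(t)
    on = t >= onset
    env[on] = np.exp(-decay * (t[on] - onset))
    if ramp > 0:
        ramp_sel = on & (t < onset + ramp)
        env[ramp_sel] *= (t[ramp_sel] - onset) / ramp
    return env


def rate_profile(
    cond: ConditionSpec, t: np.ndarray, onset: float, latency: float = 0.04,
    transient_sd: float = 0.025,
) -> np.ndarray:
    """Firing intensity: baseline, onset transient, sustained level."""
    r = np.full_like(t, float(cond.rate_baseline))
    on = t >= onset
    r[on] = cond.rate_sustained
    bump = cond.rate_transient - cond.rate_sustained
    if bump > 0:
        r += bump * np.exp(-0.5 * ((t - onset - latency) / transient_sd) ** 2) * on
    return np.clip(r, 0.0, None)


def simulate_spikes(
    rate: np.ndarray,
    fs: float,
    gamma_phase: np.ndarray = None,
    kappa: float = 0.0,
    rng=None,
    preferred_phase: float = 0.0,
) -> np.ndarray:
    """Inhomogeneous Poisson spikes with a von Mises phase gain.

    Intensity = rate(t) * exp(kappa*cos(phase(t) - preferred))/I0(kappa);
    the gain averages to 1 over uniform phase, so the expected count is the
    integral of ``rate``. Sampled by thinning.
    """
    rng = np.random.default_rng(rng)
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate profile must be nonnegative")
    duration = len(rate) / fs
    lam_max = rate.max() * (np.exp(kappa) / i0(kappa) if kappa > 0 else 1.0)
    if lam_max <= 0:
        return np.empty(0)
    n = rng.poisson(lam_max * duration)
    times = np.sort(rng.uniform(0.0, duration, n))
    idx = np.minimum((times * fs).astype(int), len(rate) - 1)
    lam = rate[idx]
    if kappa > 0 and gamma_phase is not None:
        lam = lam * np.exp(kappa * np.cos(gamma_phase[idx] - preferred_phase)) / i0(kappa)
    keep = rng.uniform(0.0, lam_max, n) < lam
    return times[keep]


def mu_envelope_from_spikes(spike_times: np.ndarray, n: int, fs: float, amp: float = 1.0):
    """Spike train -> envelope via the preprocessing rectify+low-pass contract."""
    train = np.zeros(n)
    idx = (np.asarray(spike_times) * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    np.add.at(train, idx, amp)
    taps = decimation_fir()  # same FIR as the LFP low-pass, applied at fs
    env = signal.filtfilt(taps, [1.0], train) if n > 3 * len(taps) else train
    return np.clip(env, 0.0, None)


def bleed_kernel(fs: float, width: float = 0.0015, amp: float = 1.0) -> np.ndarray:
    """Biphasic ~1.5 ms kernel (derivative-of-Gaussian) for spike bleed-in."""
    half = max(2, int(round(2 * width * fs)))
    t = np.arange(-half, half + 1) / fs
    k = -t * np.exp(-0.5 * (t / (width / 2.0)) ** 2)
    peak = np.max(np.abs(k))
    return amp * k / peak if peak > 0 else k


def simulate_lfp_trial(
    cond: ConditionSpec,
    duration: float,
    rng,
    fs: float = LFP_RATE,
    onset: float = 0.5,
    spike_times: np.ndarray = None,
) -> tuple:
    """One LFP trace: colored background + gated gamma + line noise + bleed.

    Returns (lfp, gamma_phase) where ``gamma_phase`` is the instantaneous
    phase (Hilbert) of the gamma component, used to lock spikes.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    cond.validate()
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    lfp = _colored_noise(n, fs, cond.spectral_exponent, rng)
    gamma = _gamma_band_noise(n, fs, cond, rng)
    phase = np.angle(hilbert(gamma))
    if cond.gamma_amplitude > 0:
        lfp = lfp + gamma * _gamma_envelope(t, onset, cond.gamma_decay_rate)
    for f0, a in zip((50.0, 100.0, 150.0), cond.line_amplitudes):
        if a > 0:
            lfp = lfp + a * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
    if spike_times is not None and cond.bleed_amplitude > 0 and len(spike_times):
        train = np.zeros(n)
        idx = (np.asarray(spike_times) * fs).astype(int)
        idx = idx[(idx >= 0) & (idx < n)]
        np.add.at(train, idx, 1.0)
        lfp = lfp + np.convolve(train, bleed_kernel(fs, amp=cond.bleed_amplitude), "same")
    return lfp, phase


def saccade_waveform(fs: float, amplitude: float, duration: float = 0.020, overshoot=0.12):
    """Step-plus-overshoot displacement profile of one microsaccade."""
    n = max(3, int(round(duration * fs)))
    u = np.linspace(0.0, 1.0, n)
    step = 0.5 * (1 - np.cos(np.pi * u))  # smooth 0 -> 1
    over = overshoot * np.sin(np.pi * u)
    return amplitude * (step + over)


def simulate_eye(
    duration: float,
    saccade_times,
    rng,
    fs: float = EYE_RATE,
    onset: float = 0.5,
    amplitude: float = 0.3,
    noise_sd: float = 0.05,
    pupil_baseline: float = -2000.0,
    pupil_constriction: float = 150.0,
) -> tuple:
    """Fixational gaze with injected microsaccades, plus a pupil trace.

    Gaze: slow drift + tracker noise + step-plus-overshoot displacements at
    ``saccade_times`` (random directions). Pupil: negative tracker-like
    units with a smooth stimulus-locked constriction plus noise.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    saccade_times = sorted(float(s) for s in saccade_times)
    if any(s < 0 or s >= duration for s in saccade_times):
        raise ValueError("saccade time outside trace")
    drift = np.cumsum(rng.standard_normal((2, n)) * 2e-4, axis=1)
    gaze = drift + rng.standard_normal((2, n)) * noise_sd
    for s in saccade_times:
        wave = saccade_waveform(fs, amplitude)
        theta = rng.uniform(0, 2 * np.pi)
        i0_ = int(round(s * fs))
        seg = slice(i0_, min(n, i0_ + len(wave)))
        w = wave[: seg.stop - seg.start]
        gaze[0, seg] += np.cos(theta) * w
        gaze[1, seg] += np.sin(theta) * w
        gaze[0, seg.stop :] += np.cos(theta) * wave[-1] if seg.stop < n else 0.0
        gaze[1, seg.stop :] += np.sin(theta) * wave[-1] if seg.stop < n else 0.0
    constr = 1.0 / (1.0 + np.exp(-(t - onset - 0.35) / 0.08))
    constr[t < onset] = 0.0
    pupil = pupil_baseline - pupil_constriction * constr + rng.standard_normal(n) * 2.0
    return gaze, pupil


def simulate_session(config: SimulationConfig) -> tuple:
    """Generate a full session plus its ground-truth record."""
    config.validate()
    fs = config.sampling_rate
    duration = config.baseline_duration + config.stimulus_duration
    onset = config.baseline_duration
    n = int(round(duration * fs))
    rows, cols = config.grid_shape
    n_chan = rows * cols
    positions = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=float)
    depths = np.zeros(n_chan)

    ss = np.random.SeedSequence(config.seed)
    n_total = len(config.conditions) * config.n_trials_per_condition
    children = ss.spawn(n_total)

    lfp = np.empty((n_total, n_chan, n))
    mu = np.empty((n_total, n_chan, n))
    spikes, labels = [], []
    n_eye = int(round(duration * EYE_RATE))
    eye = np.empty((n_total, 2, n_eye))
    pupil = np.empty((n_total, n_eye))
    truth = SyntheticGroundTruth()

    trial = 0
    for cond in config.conditions:
        for _ in range(config.n_trials_per_condition):
            rng = np.random.default_rng(children[trial])
            t = np.arange(n) / fs
            # common gamma component (volume conduction across the grid)
            gamma = _gamma_band_noise(n, fs, cond, rng)
            phase = np.angle(hilbert(gamma))
            env = _gamma_envelope(t, onset, cond.gamma_decay_rate)
            gated = gamma * env if cond.gamma_amplitude > 0 else np.zeros(n)
            rate = rate_profile(cond, t, onset)
            line = np.zeros(n)
            for f0, a in zip((50.0, 100.0, 150.0), cond.line_amplitudes):
                if a > 0:
                    line += a * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
            trial_spikes = []
            for ch in range(n_chan):
                st = simulate_spikes(rate, fs, phase, cond.locking_kappa, rng)
                trial_spikes.append(st)
                bg = _colored_noise(n, fs, cond.spectral_exponent, rng)
                x = bg + gated + line
                if cond.bleed_amplitude > 0 and len(st):
                    train = np.zeros(n)
                    idx = np.minimum((st * fs).astype(int), n - 1)
                    np.add.at(train, idx, 1.0)
                    x = x + np.convolve(
                        train, bleed_kernel(fs, amp=cond.bleed_amplitude), "same"
                    )
                lfp[trial, ch] = x
                mu[trial, ch] = mu_envelope_from_spikes(st, n, fs)
            n_sacc = rng.poisson(config.saccade_rate * duration)
            sacc_times = np.sort(rng.uniform(0.0, duration - 0.03, n_sacc))
            g, p = simulate_eye(
                duration,
                sacc_times,
                rng,
                onset=onset,
                amplitude=config.saccade_amplitude,
                noise_sd=config.eye_noise_sd,
                pupil_constriction=cond.pupil_constriction,
            )
            eye[trial] = g
            pupil[trial] = p
            spikes.append(trial_spikes)
            labels.append(cond.label)
            truth.trials.append(
                {
                    "trial_id": trial,
                    "condition": cond.label,
                    "gamma_amplitude": cond.gamma_amplitude,
                    "gamma_peak_freq": cond.gamma_peak_freq,
                    "gamma_decay_rate": cond.gamma_decay_rate,
                    "locking_kappa": cond.locking_kappa,
                    "rate_sustained": cond.rate_sustained,
                    "rate_baseline": cond.rate_baseline,
                    "spike_counts": [len(s) for s in trial_spikes],
                    "saccade_times": sacc_times,
                    "pupil_constriction": cond.pupil_constriction,
                }
            )
            trial += 1

    sess = SessionData(
        fs_lfp=fs,
        fs_eye=EYE_RATE,
        stim_onset=onset,
        stim_duration=config.stimulus_duration,
        lfp=lfp,
        mu=mu,
        spikes=spikes,
        eye=eye,
        pupil=pupil,
        conditions=pd.DataFrame({"trial_id": np.arange(n_total), "label": labels}),
        channel_positions=positions,
        channel_depths=depths,
        grid_spacing=config.grid_spacing,
        session_id=config.session_id,
        monkey=config.monkey,
    )
    return sess, truth


def standard_conditions() -> list:
    """Default condition set mirroring the study's headline contrasts:
    a chromatic-like uniform surface (strong, decaying gamma, sustained
    suppression below baseline) and an achromatic/mismatch-like condition
    (weak gamma, elevated sustained rate)."""
    line = (0.3, 0.1, 0.05)
    return [
        ConditionSpec(
            "uniform",
            gamma_amplitude=3.0,
            gamma_peak_freq=55.0,
            gamma_decay_rate=0.3,
            rate_baseline=20.0,
            rate_transient=80.0,
            rate_sustained=12.0,
            locking_kappa=0.8,
            line_amplitudes=line,
        ),
        ConditionSpec(
            "mismatch",
            gamma_amplitude=0.5,
            gamma_peak_freq=55.0,
            gamma_decay_rate=0.3,
            rate_baseline=20.0,
            rate_transient=80.0,
            rate_sustained=35.0,
            locking_kappa=0.15,
            line_amplitudes=line,
        ),
    ]


def example_session_configs(seed: int = 0, n_trials: int = 12) -> dict:
    """Named SimulationConfigs mirroring the study's dataset designs.

    ``hue_luminance``: chromatic vs achromatic uniform surfaces;
    ``size_tuning``: 0.5/1/2/6 deg sizes with growing gamma and growing
    surround suppression; ``predictability``: uniform vs center-surround
    mismatch; ``background``: red and green surfaces on differently
    adapting full-screen backgrounds (gamma ratio depends on background).
    """
    line = (0.3, 0.1, 0.05)

    def cond(label, amp, sus, kappa, freq=55.0):
        return ConditionSpec(
            label, gamma_amplitude=amp, gamma_peak_freq=freq,
            rate_sustained=sus, locking_kappa=kappa, line_amplitudes=line,
        )

    hue = [
        cond("red", 3.5, 12.0, 0.9), cond("green", 2.5, 13.0, 0.8, 52.0),
        cond("blue", 2.0, 14.0, 0.7, 50.0), cond("white", 0.6, 25.0, 0.2),
        cond("black", 0.5, 22.0, 0.2),
    ]
    size = [
        cond("size_0.5", 0.3, 45.0, 0.1), cond("size_1", 0.8, 35.0, 0.3),
        cond("size_2", 1.8, 22.0, 0.5), cond("size_6", 3.5, 12.0, 0.9),
    ]
    predict = standard_conditions()
    # the red/green gamma ratio of each background is generated from the
    # cone-adaptation model itself (positive M weight, negative L weight,
    # zero intercept), so the downstream regression has a defined truth
    from .colorimetry import (
        adaptation_coefficients, background_spd, fit_cone_curves,
        synthetic_cone_fundamentals,
    )

    cones = fit_cone_curves(synthetic_cone_fundamentals())
    background = []
    for bg in ("gray", "green", "red", "yellow", "blue", "black", "white"):
        tri = adaptation_coefficients(background_spd(bg), cones)
        # M weight about twice the L magnitude, as for the fitted model
        gamma_ratio = 2.0 * tri.Madapt - 1.0 * tri.Ladapt
        base_amp = 2.4  # geometric-mean gamma amplitude across hues
        red_amp = 1.0 + (base_amp - 1.0) * 10 ** (gamma_ratio / 2.0)
        green_amp = 1.0 + (base_amp - 1.0) * 10 ** (-gamma_ratio / 2.0)
        background.append(cond(f"red_on_{bg}", red_amp, 12.0, 0.8))
        background.append(cond(f"green_on_{bg}", green_amp, 13.0, 0.8, 52.0))
    mk = lambda conds, k: SimulationConfig(
        conditions=conds, n_trials_per_condition=n_trials, grid_shape=(2, 2),
        seed=seed + k, session_id=f"synthetic-{k}",
    )
    return {
        "hue_luminance": mk(hue, 0),
        "size_tuning": mk(size, 1),
        "predictability": mk(predict, 2),
        "background": mk(background, 3),
    }


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["conditions"] = [asdict(c) for c in config.conditions]
    return d
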