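import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import i0, i1

from v1gamma import firing, gamma_peak, spectral, synth


def _flat_condition(**kw):
    defaults = dict(
        gamma_amplitude=0.0, rate_transient=20.0, rate_sustained=20.0,
        rate_baseline=20.0, locking_kappa=0.0,
    )
    defaults.update(kw)
    return synth.ConditionSpec("flat", **defaults)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = synth.SimulationConfig(
            conditions=synth.standard_conditions(), n_trials_per_condition=2,
            grid_shape=(1, 2), seed=42,
        )
        s1, t1 = synth.simulate_session(cfg)
        s2, t2 = synth.simulate_session(cfg)
        assert np.array_equal(s1.lfp, s2.lfp)
        assert np.array_equal(s1.mu, s2.mu)
        assert np.array_equal(s1.eye, s2.eye)
        assert t1.to_json() == t2.to_json()

    def test_ground_truth_one_entry_per_trial(self, small_session):
        sess, truth = small_session
        ids = [t["trial_id"] for t in truth.trials]
        assert ids == list(range(sess.n_trials))


class TestValidation:
    def test_invalid_field_named_in_error(self):
        with pytest.raises(ValueError, match="gamma_peak_freq"):
            synth.ConditionSpec("bad", gamma_peak_freq=10.0).validate()
        with pytest.raises(ValueError, match="durations"):
            synth.SimulationConfig(
                conditions=[_flat_condition()], baseline_duration=-1.0
            ).validate()

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            synth.simulate_spikes(np.array([-1.0, 2.0]), 100.0)

    def test_saccade_outside_trace_rejected(self):
        with pytest.raises(ValueError, match="saccade"):
            synth.simulate_eye(1.0, [1.5], np.random.default_rng(0))


class TestLfpConstruction:
    def test_background_spectral_slope(self):
        exponent = 2.0
        cond = _flat_condition(spectral_exponent=exponent)
        acc = []
        for i in range(200):
            x, _ = synth.simulate_lfp_trial(cond, 1.0, np.random.default_rng(i))
            acc.append(spectral.multitaper_psd(x, synth.LFP_RATE).power)
        f = spectral.multitaper_psd(x, synth.LFP_RATE).frequencies
        sel = (f >= 20) & (f <= 140)
        slope = np.polyfit(np.log(f[sel]), np.log(np.mean(acc, axis=0)[sel]), 1)[0]
        assert slope == pytest.approx(-exponent, abs=0.15)

    def test_gamma_bump_at_requested_frequency(self):
        cond = _flat_condition(gamma_amplitude=3.0, gamma_peak_freq=55.0,
                               gamma_decay_rate=0.0)
        base = _flat_condition()
        acc_s, acc_b = [], []
        for i in range(150):
            xs, _ = synth.simulate_lfp_trial(cond, 1.0, np.random.default_rng(i), onset=0.0)
            xb, _ = synth.simulate_lfp_trial(base, 1.0, np.random.default_rng(10_000 + i))
            acc_s.append(spectral.multitaper_psd(xs, synth.LFP_RATE).power)
            acc_b.append(spectral.multitaper_psd(xb, synth.LFP_RATE).power)
        f = spectral.multitaper_psd(xs, synth.LFP_RATE).frequencies
        ratio = np.mean(acc_s, axis=0) / np.mean(acc_b, axis=0)
        band = (f > 30) & (f < 80)
        assert abs(f[band][np.argmax(ratio[band])] - 55.0) <= 3.0

    def test_power_monotone_in_amplitude(self):
        powers = []
        for amp in (1.0, 2.0):
            cond = _flat_condition(gamma_amplitude=amp, gamma_decay_rate=0.0)
            x, _ = synth.simulate_lfp_trial(
                cond, 1.0, np.random.default_rng(5), onset=0.0
            )
            ps = spectral.multitaper_psd(x, synth.LFP_RATE)
            powers.append(ps.power[ps.band(50.0, 60.0)].sum())
        assert powers[1] > powers[0]

    def test_zero_amplitude_yields_no_peak_downstream(self):
        """With no injected oscillation the peak fitter reports fold 1."""
        cond = _flat_condition()
        stim_acc, base_acc = [], []
        fs = synth.LFP_RATE
        for i in range(30):
            x, _ = synth.simulate_lfp_trial(cond, 1.8, np.random.default_rng(i))
            n0 = int(0.5 * fs)
            base_acc.append(spectral.multitaper_psd(x[:n0], fs).power)
            stim_acc.append(spectral.multitaper_psd(x[n0 : 2 * n0], fs).power)
        f = spectral.multitaper_psd(x[:n0], fs).frequencies
        stim = spectral.PowerSpectrum(f, np.stack(stim_acc))
        base = spectral.PowerSpectrum(f, np.stack(base_acc))
        peak = gamma_peak.extract_gamma(stim, base, rng=0)
        assert peak.no_peak
        assert peak.amplitude_fold == 1.0

    def test_stronger_condition_yields_larger_extracted_fold(self):
        """Conditions with 2x different injected gamma are ordered correctly
        by the full extraction in the vast majority of replicates."""
        fs = synth.LFP_RATE
        n0 = int(0.5 * fs)
        wins = 0
        n_rep = 40
        for rep in range(n_rep):
            folds = []
            for amp in (1.5, 3.0):
                cond = _flat_condition(gamma_amplitude=amp, gamma_decay_rate=0.0)
                stim_acc, base_acc = [], []
                for i in range(20):
                    rng = np.random.default_rng(rep * 1000 + i + (amp == 3.0) * 500)
                    x, _ = synth.simulate_lfp_trial(cond, 1.8, rng, onset=0.5)
                    base_acc.append(spectral.multitaper_psd(x[:n0], fs).power)
                    # two non-overlapping stimulus epochs per trial
                    stim_acc.append(
                        np.mean(
                            [
                                spectral.multitaper_psd(x[n0 + 305 : 2 * n0 + 305], fs).power,
                                spectral.multitaper_psd(x[2 * n0 + 305 : 3 * n0 + 305], fs).power,
                            ],
                            axis=0,
                        )
                    )
                f = spectral.multitaper_psd(x[:n0], fs).frequencies
                peak = gamma_peak.extract_gamma(
                    spectral.PowerSpectrum(f, np.stack(stim_acc)),
                    spectral.PowerSpectrum(f, np.stack(base_acc)),
                    rng=rep,
                )
                folds.append(peak.amplitude_fold)
            wins += folds[1] > folds[0]
        assert wins >= 0.95 * n_rep


class TestSpikes:
    @staticmethod
    def _kappa_from_phases(phases):
        r = np.abs(np.mean(np.exp(1j * phases)))
        return brentq(lambda k: i1(k) / i0(k) - r, 1e-6, 60.0)

    @pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0])
    def test_locking_concentration_recovered(self, kappa):
        fs = synth.LFP_RATE
        t = np.arange(int(40 * fs)) / fs
        phase = np.angle(np.exp(1j * 2 * np.pi * 55.0 * t))
        rate = np.full(len(t), 300.0)
        st = synth.simulate_spikes(rate, fs, phase, kappa, rng=np.random.default_rng(3))
        assert len(st) > 8000
        ph = phase[np.minimum((st * fs).astype(int), len(t) - 1)]
        k_hat = self._kappa_from_phases(ph)
        assert k_hat == pytest.approx(kappa, rel=0.15)

    def test_no_locking_gives_uniform_phases(self):
        fs = synth.LFP_RATE
        t = np.arange(int(5 * fs)) / fs
        phase = np.angle(np.exp(1j * 2 * np.pi * 55.0 * t))
        nonsig = 0
        n_runs = 40
        for s in range(n_runs):
            st = synth.simulate_spikes(
                np.full(len(t), 80.0), fs, phase, 0.0, rng=np.random.default_rng(s)
            )
            ph = phase[np.minimum((st * fs).astype(int), len(t) - 1)]
            n = len(ph)
            r = np.abs(np.mean(np.exp(1j * ph)))
            z = n * r**2
            p = np.exp(-z) * (1 + (2 * z - z**2) / (4 * n))  # Rayleigh test
            nonsig += p > 0.01
        assert nonsig >= 0.95 * n_runs

    def test_extreme_kappa_concentrates_phases(self):
        fs = synth.LFP_RATE
        t = np.arange(int(10 * fs)) / fs
        phase = np.angle(np.exp(1j * 2 * np.pi * 55.0 * t))
        st = synth.simulate_spikes(
            np.full(len(t), 100.0), fs, phase, 50.0, rng=np.random.default_rng(0)
        )
        ph = phase[np.minimum((st * fs).astype(int), len(t) - 1)]
        assert np.percentile(np.abs(ph), 99) < 0.45  # kappa=50: SD ~ 0.14 rad

    def test_poisson_count_oracle(self):
        """kappa=0, constant rate r: mean count matches rT within 3 SE."""
        rate, duration, fs = 37.0, 1.0, 500.0
        counts = [
            len(
                synth.simulate_spikes(
                    np.full(int(duration * fs), rate), fs,
                    rng=np.random.default_rng(s),
                )
            )
            for s in range(1000)
        ]
        expected = rate * duration
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se


class TestEyeAndPupil:
    def test_no_injected_saccades_detector_silent(self):
        false_runs = 0
        for s in range(120):
            gaze, _ = synth.simulate_eye(1.8, [], np.random.default_rng(s))
            false_runs += len(firing.detect_microsaccades(gaze, synth.EYE_RATE)) > 0
        assert false_runs <= 0.01 * 120 + 1

    def test_pupil_constriction_matches_percent_change_formula(self):
        gaze, pupil = synth.simulate_eye(
            3.0, [], np.random.default_rng(0), onset=0.5,
            pupil_baseline=-2000.0, pupil_constriction=150.0,
        )
        resp = firing.pupil_response(pupil, synth.EYE_RATE, onset=0.5)
        late = resp.percent_change[int(2.5 * synth.EYE_RATE) :]
        assert np.mean(late) == pytest.approx(-150.0 / 2000.0, abs=0.01)

    def test_mu_envelope_mean_tracks_rate(self):
        fs = synth.LFP_RATE
        n = int(2.0 * fs)
        st = np.random.default_rng(0).uniform(0, 2.0, 200)
        env = synth.mu_envelope_from_spikes(st, n, fs)
        assert env.min() >= 0.0
        assert env.sum() == pytest.approx(200.0, rel=0.05)  # unit-mass FIR
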