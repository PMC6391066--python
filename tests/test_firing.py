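import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from v1gamma import firing
from v1gamma.synth import EYE_RATE, simulate_eye


class TestRateModulation:
    @pytest.mark.parametrize(
        "stim, base, expected",
        [(5.0, 5.0, 0.0), (50.0, 5.0, 1.0), (2.5, 5.0, -0.30103)],
    )
    def test_log_ratio_values(self, stim, base, expected):
        assert firing.rate_modulation(stim, base).value == pytest.approx(
            expected, abs=1e-5
        )

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            firing.rate_modulation(1.0, 0.0)

    @given(
        a=st.floats(0.1, 1e3), b=st.floats(0.1, 1e3)
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, a, b):
        assert firing.rate_modulation(a, b).value == pytest.approx(
            -firing.rate_modulation(b, a).value, abs=1e-12
        )


class TestSurroundSuppression:
    def test_difference_from_reference_size(self):
        supp = firing.surround_suppression({0.5: 0.4, 6.0: -0.1})
        assert supp[6.0] == pytest.approx(0.5)
        assert supp[0.5] == 0.0

    def test_equal_modulations_give_zeros(self):
        supp = firing.surround_suppression({0.5: 0.2, 1.0: 0.2, 2.0: 0.2})
        assert all(v == 0.0 for v in supp.values())

    def test_missing_reference_is_error_not_nan(self):
        with pytest.raises(ValueError, match="reference"):
            firing.surround_suppression({1.0: 0.2, 6.0: 0.1})


class TestModulationIndex:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(2.0, 2.0, 0.0), (3.0, 1.0, 1.0), (1.5, 1.25, 1.0 / 3.0)],
    )
    def test_values(self, a, b, expected):
        assert firing.modulation_index(a, b) == pytest.approx(expected)

    def test_both_no_peak_defined_as_zero(self):
        assert firing.modulation_index(1.0, 1.0) == 0.0

    def test_subunit_fold_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert firing.modulation_index(0.8, 2.0) == -1.0

    @given(a=st.floats(1.0, 10.0), b=st.floats(1.0, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_antisymmetric(self, a, b):
        m = firing.modulation_index(a, b)
        assert -1.0 <= m <= 1.0
        assert m == pytest.approx(-firing.modulation_index(b, a), abs=1e-12)


class TestMicrosaccadeDetection:
    def test_criterion_hand_computation(self):
        v = np.array([[-1.0, 0.0, 2.0], [0.0, 0.0, 0.0]])
        c = firing.velocity_criterion(v)
        assert c[0] == pytest.approx(1.0)  # median{1,0,4} - median{-1,0,2}^2
        assert c[1] == 0.0

    def test_constant_velocity_axis_degenerate_and_silent(self):
        fs = EYE_RATE
        t = np.arange(int(fs)) / fs
        gaze = np.stack([0.5 * t, np.zeros_like(t)])  # pure constant drift
        events = firing.detect_microsaccades(gaze, fs)
        assert events == []

    def test_offset_and_rotation_invariance(self):
        rng = np.random.default_rng(0)
        inj = [0.3, 0.8, 1.3]
        gaze, _ = simulate_eye(1.8, inj, rng)
        base = firing.detect_microsaccades(gaze, EYE_RATE)
        shifted = firing.detect_microsaccades(gaze + 3.7, EYE_RATE)
        rotated = firing.detect_microsaccades(
            np.stack([-gaze[1], gaze[0]]), EYE_RATE
        )
        assert [e.onset for e in shifted] == [e.onset for e in base]
        assert [e.onset for e in rotated] == [e.onset for e in base]

    def test_recall_on_injected_saccades(self):
        hits = injected = 0
        for s in range(40):
            rng = np.random.default_rng(s)
            inj = np.array([0.3, 0.7, 1.1, 1.5])
            gaze, _ = simulate_eye(1.8, inj, rng)
            events = firing.detect_microsaccades(gaze, EYE_RATE)
            injected += len(inj)
            onsets = np.array([e.onset for e in events]) if events else np.array([])
            for t in inj:
                hits += len(onsets) and np.min(np.abs(onsets - t)) <= 0.02
        assert hits / injected >= 0.95

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="short"):
            firing.detect_microsaccades(np.zeros((2, 8)), EYE_RATE)


class TestCensoring:
    def test_no_events_keeps_full_trial(self):
        epochs = firing.censor_after_microsaccades(1.0, [])
        assert len(epochs) == 10
        assert epochs[0] == (0.0, 0.1) and epochs[-1] == pytest.approx((0.9, 1.0))

    def test_dense_events_remove_everything(self):
        events = [firing.MicrosaccadeEvent(t, t + 0.01, "both", 20.0)
                  for t in np.arange(0.0, 1.0, 0.09)]
        assert firing.censor_after_microsaccades(1.0, events) == []

    def test_single_event_censors_100ms(self):
        events = [firing.MicrosaccadeEvent(0.50, 0.51, "both", 20.0)]
        epochs = firing.censor_after_microsaccades(1.0, events)
        total = sum(b - a for a, b in epochs)
        assert total == pytest.approx(0.9, abs=0.011)
        assert all(b <= 0.50 or a >= 0.60 for a, b in epochs)


class TestPupil:
    def test_flat_trace_zero_response(self):
        p = np.full(1000, -1500.0)
        resp = firing.pupil_response(p, EYE_RATE, onset=0.5)
        assert np.allclose(resp.percent_change, 0.0)

    def test_negative_units_sign_convention(self):
        p = np.full(1000, -100.0)
        p[500:] = -110.0
        resp = firing.pupil_response(p, EYE_RATE, onset=0.5)
        assert resp.percent_change[-1] == pytest.approx(-0.10)

    def test_positive_units(self):
        p = np.full(1000, 50.0)
        p[500:] = 60.0
        resp = firing.pupil_response(p, EYE_RATE, onset=0.5)
        assert resp.percent_change[-1] == pytest.approx(0.20)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            firing.pupil_response(np.zeros(1000), EYE_RATE, onset=0.5)
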