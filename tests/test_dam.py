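"""Acquisition-module logic: amplitude, rolling average, calibration
state machine, threshold and trigger detection."""

import numpy as np
import pytest

from gripsense import dam, evaluation
from gripsense.dam import (
    CalibrationFailure,
    CalibrationProfile,
    DeviceState,
    amplitude_series,
    amplitude_step,
    compute_threshold,
    detect_triggers,
    detection_latency_s,
    rolling_amplitude,
    run_calibration,
)
from gripsense.protocol import make_calibration_stream
from gripsense.sim import EmgRecording, SimConfig, generate_session


class TestAmplitude:
    @pytest.mark.parametrize(
        "prev,curr,expected", [(5, 7, 2), (7, 4, 3), (3.5, 3.5, 0.0), (-2, 2, 4)]
    )
    def test_amplitude_step(self, prev, curr, expected):
        assert amplitude_step(prev, curr) == expected

    def test_series_matches_stepwise(self, rng):
        x = rng.normal(size=50)
        series = amplitude_series(x)
        assert series.size == 49
        for i in range(49):
            assert series[i] == amplitude_step(x[i], x[i + 1])


class TestRollingAmplitude:
    def test_constant_input_constant_output(self):
        out = rolling_amplitude(np.full(500, 3.25))
        np.testing.assert_allclose(out, 3.25)

    def test_hand_computed_window_two(self):
        np.testing.assert_allclose(
            rolling_amplitude(np.array([0.0, 2.0, 4.0]), window=2), [0.0, 1.0, 3.0]
        )

    def test_warmup_uses_prefix_mean(self):
        out = rolling_amplitude(np.arange(1.0, 11.0), window=300)
        np.testing.assert_allclose(out, np.cumsum(np.arange(1.0, 11.0)) / np.arange(1, 11))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rolling_amplitude(np.array([]))

    def test_noise_variance_reduced_by_window(self, rng):
        x = rng.normal(size=200_000)
        out = rolling_amplitude(x, window=300)[300:]
        ratio = np.var(x) / np.var(out)
        assert 240 < ratio < 370  # ~ window-fold reduction for i.i.d. input


class TestThreshold:
    @pytest.mark.parametrize(
        "rest,mx,frac,expected", [(0, 1, 0.60, 0.60), (10, 110, 0.60, 70.0), (2, 6, 1.0, 6.0)]
    )
    def test_interpolation(self, rest, mx, frac, expected):
        assert compute_threshold(rest, mx, frac) == pytest.approx(expected)

    def test_degenerate_anchors_fail(self):
        with pytest.raises(CalibrationFailure):
            compute_threshold(5.0, 5.0)
        with pytest.raises(CalibrationFailure):
            compute_threshold(5.0, 4.0)


class TestCalibration:
    def test_valid_profile_from_synthetic_stream(self, burst_session):
        cfg, _, _ = burst_session
        stream = make_calibration_stream(cfg, seed=99)
        profile, timeline = run_calibration(stream)
        assert profile.max_mean_amplitude > 1.5 * profile.rest_mean_amplitude
        assert (
            profile.rest_mean_amplitude
            <= profile.trigger_threshold
            <= profile.max_mean_amplitude
        )

    def test_state_timeline_durations(self, burst_session):
        cfg, _, _ = burst_session
        stream = make_calibration_stream(cfg, seed=99)
        _, timeline = run_calibration(stream)
        states = {iv.state: iv for iv in timeline}
        assert states[DeviceState.S1].end_s - states[DeviceState.S1].start_s == 5.0
        assert states[DeviceState.S2].end_s - states[DeviceState.S2].start_s == 5.0
        assert states[DeviceState.S3].end_s - states[DeviceState.S3].start_s == 3.0
        assert [iv.state for iv in timeline] == [
            DeviceState.S1, DeviceState.S2, DeviceState.S3, DeviceState.S4
        ]

    def test_led_colors(self):
        assert [s.led_color for s in DeviceState] == ["red", "yellow", "blue", "green"]

    def test_all_zero_stream_fails(self):
        stream = EmgRecording(500.0, np.zeros(500 * 14))
        with pytest.raises(CalibrationFailure):
            run_calibration(stream)

    def test_too_short_stream_rejected(self):
        stream = EmgRecording(500.0, np.random.default_rng(0).normal(size=500 * 5))
        with pytest.raises(ValueError, match="13"):
            run_calibration(stream)

    def test_gain_linearity(self, burst_session):
        cfg, _, _ = burst_session
        stream = make_calibration_stream(cfg, seed=99)
        p1, _ = run_calibration(stream, gain=1.0)
        p2, _ = run_calibration(stream, gain=2.0)
        assert p2.rest_mean_amplitude == pytest.approx(2 * p1.rest_mean_amplitude)
        assert p2.max_mean_amplitude == pytest.approx(2 * p1.max_mean_amplitude)
        assert p2.trigger_threshold == pytest.approx(2 * p1.trigger_threshold)


class TestDetection:
    @pytest.fixture
    def profile(self, burst_session):
        cfg, _, _ = burst_session
        stream = make_calibration_stream(cfg, seed=99)
        return run_calibration(stream)[0]

    def test_quiet_stream_no_triggers(self, rest_session, profile):
        _, rec, _ = rest_session
        events, activity = detect_triggers(rec, profile)
        assert events == []
        assert not activity.any()

    def test_single_burst_single_trigger(self, profile):
        cfg = SimConfig(
            duration_s=10.0, event_onsets_s=[4.0], burst_gain=5.0, seed=13
        )
        rec, _ = generate_session(cfg)
        events, _ = detect_triggers(rec, profile)
        assert len(events) == 1
        assert 4.0 < events[0].time_s < 5.0

    def test_refractory_collapses_close_crossings(self, profile):
        # two bursts 0.2 s apart: crossings closer than the 0.3 s refractory
        fs = 500.0
        t = np.arange(0, 6, 1 / fs)
        rng = np.random.default_rng(0)
        carrier = rng.normal(size=t.size)
        env = np.where((t > 2.0) & (t < 2.1) | (t > 2.3) & (t < 2.4), 50.0, 0.01)
        rec = EmgRecording(fs, carrier * env)
        prof = CalibrationProfile(0.01, 1.0, 0.60, 0.5)
        events, _ = detect_triggers(rec, prof, refractory_s=0.3)
        assert len(events) == 1

    def test_dc_offset_invariance(self, burst_session, profile):
        _, rec, _ = burst_session
        shifted = EmgRecording(rec.sampling_rate_hz, rec.samples + 123.4)
        e1, a1 = detect_triggers(rec, profile)
        e2, a2 = detect_triggers(shifted, profile)
        assert [e.time_s for e in e1] == [e.time_s for e in e2]
        np.testing.assert_array_equal(a1, a2)

    def test_lower_fraction_never_fewer_triggers(self, burst_session, profile):
        _, rec, _ = burst_session
        counts = []
        for frac in (0.9, 0.6, 0.3):
            thr = compute_threshold(
                profile.rest_mean_amplitude, profile.max_mean_amplitude, frac
            )
            p = CalibrationProfile(
                profile.rest_mean_amplitude, profile.max_mean_amplitude, frac, thr
            )
            counts.append(len(detect_triggers(rec, p)[0]))
        assert counts == sorted(counts)

    def test_end_to_end_f1(self, burst_session, profile):
        """Clean sessions (gain >= 4, >= 20 events) detect nearly every
        burst within tolerance of onset + nominal latency."""
        _, rec, truth = burst_session
        events, _ = detect_triggers(rec, profile)
        latency = detection_latency_s(profile)
        aligned = [t + latency for t in truth.event_onsets_s]
        summary, _ = evaluation.match_events(
            aligned, [e.time_s for e in events], tolerance_s=0.2
        )
        assert len(truth) >= 20
        assert summary.f1 >= 0.95
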