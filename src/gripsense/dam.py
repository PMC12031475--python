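"""Wearable acquisition-module logic: calibration state machine and
threshold-based grip-trigger detection.

The on-device algorithm is deliberately simple (it runs on a
microcontroller): the per-sample amplitude is the absolute first
difference of the raw stream, smoothed by a 300-sample rolling average.
Calibration measures that smoothed amplitude at rest and at maximal
squeeze and interpolates a trigger threshold 60% of the way between the
two anchors.  Detection then fires a trigger on each rising crossing of
the same smoothed amplitude, with a refractory period collapsing repeated
crossings inside one squeeze.

Because the amplitude is a difference, the whole chain is invariant to a
DC offset of the raw stream, and scales linearly with any gain applied to
the samples.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .sim import EmgRecording

__all__ = [
    "DeviceState",
    "StateInterval",
    "CalibrationProfile",
    "TriggerEvent",
    "CalibrationFailure",
    "ROLLING_WINDOW",
    "amplitude_series",
    "amplitude_step",
    "rolling_amplitude",
    "compute_threshold",
    "run_calibration",
    "detect_triggers",
    "detection_latency_s",
]

#: Length of the firmware's rolling amplitude average, in samples.
ROLLING_WINDOW = 300

#: Calibration phase durations in seconds: standby, relax, maximal squeeze.
STATE_DURATIONS_S = {"S1": 5.0, "S2": 5.0, "S3": 3.0}


class DeviceState(enum.Enum):
    """Calibration state machine states with their indicator LED colors."""

    S1 = ("standby", "red", 5.0)
    S2 = ("relax", "yellow", 5.0)
    S3 = ("max_squeeze", "blue", 3.0)
    S4 = ("calibrated", "green", None)

    def __init__(self, label: str, led_color: str, duration_s: float | None):
        self.label = label
        self.led_color = led_color
        self.duration_s = duration_s


@dataclass(frozen=True)
class StateInterval:
    state: DeviceState
    start_s: float
    end_s: float


class CalibrationFailure(RuntimeError):
    """Calibration could not separate rest from maximal contraction;
    the caller should retry with a larger analog gain."""


@dataclass(frozen=True)
class CalibrationProfile:
    """Rest / maximal-contraction amplitude anchors and the derived
    trigger threshold (rest + fraction * (max - rest))."""

    rest_mean_amplitude: float
    max_mean_amplitude: float
    threshold_fraction: float = 0.60
    trigger_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.threshold_fraction <= 1):
            raise ValueError("threshold_fraction must be in (0, 1]")
        if self.rest_mean_amplitude < 0 or self.max_mean_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass(frozen=True)
class TriggerEvent:
    """A detected grip trigger (rising threshold crossing time)."""

    time_s: float


def amplitude_step(prev_sample: float, curr_sample: float) -> float:
    """On-board amplitude measure: |curr - prev|."""
    return abs(curr_sample - prev_sample)


def amplitude_series(samples: np.ndarray) -> np.ndarray:
    """Vectorized ``amplitude_step`` over a stream; element i is the
    amplitude of sample i+1, so the series has length len(samples) - 1."""
    samples = np.asarray(samples, dtype=float)
    return np.abs(np.diff(samples))


def rolling_amplitude(amplitudes: np.ndarray, window: int = ROLLING_WINDOW) -> np.ndarray:
    """Causal rolling mean of the amplitude series.

    During warm-up (fewer than ``window`` samples seen) the mean of the
    available prefix is used, so output length equals input length and the
    start of the stream is not biased low by zero-padding.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if amplitudes.size == 0:
        raise ValueError("empty amplitude series")
    csum = np.cumsum(amplitudes)
    out = np.empty_like(csum)
    head = min(window, amplitudes.size)
    out[:head] = csum[:head] / np.arange(1, head + 1)
    if amplitudes.size > window:
        out[window:] = (csum[window:] - csum[:-window]) / window
    return out


def compute_threshold(rest_mean: float, max_mean: float, fraction: float = 0.60) -> float:
    """Trigger threshold interpolated between the calibration anchors."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if max_mean <= rest_mean:
        raise CalibrationFailure(
            f"maximal amplitude {max_mean:.4g} does not exceed rest amplitude "
            f"{rest_mean:.4g}; increase the sensor gain and recalibrate"
        )
    return rest_mean + fraction * (max_mean - rest_mean)


def _state_timeline(fs: float, n_samples: int, start_s: float) -> list[StateInterval]:
    t = start_s
    timeline = []
    for state in (DeviceState.S1, DeviceState.S2, DeviceState.S3):
        timeline.append(StateInterval(state, t, t + state.duration_s))
        t += state.duration_s
    timeline.append(StateInterval(DeviceState.S4, t, start_s + n_samples / fs))
    return timeline


def run_calibration(
    stream: EmgRecording,
    gain: float = 1.0,
    threshold_fraction: float = 0.60,
    separation_factor: float = 1.5,
) -> tuple[CalibrationProfile, list[StateInterval]]:
    """Run the four-state calibration sequence on a raw stream.

    The first 5 s (standby) are discarded; the rest anchor is the mean
    rolling amplitude over the 5 s relax window, the maximal anchor the
    mean over the 3 s squeeze window.  A valid profile requires the
    maximal anchor to exceed ``separation_factor`` times the rest anchor,
    the concrete stand-in for "reliably detecting muscle activity";
    otherwise :class:`CalibrationFailure` asks the caller to raise the
    analog gain and retry.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    fs = stream.sampling_rate_hz
    total_cal_s = sum(STATE_DURATIONS_S.values())
    if stream.duration_s < total_cal_s:
        raise ValueError(
            f"stream covers {stream.duration_s:.2f}s < {total_cal_s:.0f}s calibration"
        )
    scaled = stream.samples * gain
    rolling = rolling_amplitude(amplitude_series(scaled))
    # rolling[i] corresponds to sample i+1 -> time start + (i+1)/fs
    times = stream.start_time_s + (np.arange(rolling.size) + 1) / fs
    t0 = stream.start_time_s
    s2 = (times >= t0 + 5.0) & (times < t0 + 10.0)
    s3 = (times >= t0 + 10.0) & (times < t0 + 13.0)
    rest_mean = float(np.mean(rolling[s2]))
    max_mean = float(np.mean(rolling[s3]))
    if max_mean < separation_factor * rest_mean or max_mean <= rest_mean:
        raise CalibrationFailure(
            f"maximal amplitude {max_mean:.4g} below {separation_factor} x rest "
            f"amplitude {rest_mean:.4g}; increase the sensor gain and recalibrate"
        )
    threshold = compute_threshold(rest_mean, max_mean, threshold_fraction)
    profile = CalibrationProfile(rest_mean, max_mean, threshold_fraction, threshold)
    return profile, _state_timeline(fs, stream.samples.size, stream.start_time_s)


def detect_triggers(
    stream: EmgRecording,
    profile: CalibrationProfile,
    refractory_s: float = 0.3,
    gain: float = 1.0,
) -> tuple[list[TriggerEvent], np.ndarray]:
    """Emit a trigger at each rising crossing of the rolling amplitude
    above the calibrated threshold, suppressing further triggers for
    ``refractory_s``.

    Returns the trigger events and the per-sample binary activity trace
    (the device's green/red muscle-activity indicator; element 0 is always
    inactive since no amplitude exists before the second sample).

    No trigger is emitted before the rolling window has filled (0.6 s at
    defaults): prefix means over a handful of samples are too noisy to
    compare against a threshold calibrated on the full window.
    """
    if refractory_s < 0:
        raise ValueError("refractory_s must be non-negative")
    fs = stream.sampling_rate_hz
    rolling = rolling_amplitude(amplitude_series(stream.samples * gain))
    above = rolling >= profile.trigger_threshold
    activity = np.concatenate(([False], above))
    rising = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    rising = rising[rising >= ROLLING_WINDOW - 1]
    events: list[TriggerEvent] = []
    last = -np.inf
    for i in rising:
        t = stream.start_time_s + (i + 1) / fs
        if t - last >= refractory_s:
            events.append(TriggerEvent(t))
            last = t
    return events, activity


def detection_latency_s(
    profile: CalibrationProfile | None = None,
    window: int = ROLLING_WINDOW,
    fs: float = 500.0,
    threshold_fraction: float | None = None,
) -> float:
    """Nominal trigger latency after a burst onset.

    For a step from rest amplitude to the calibrated maximal amplitude,
    the rolling mean crosses the threshold once a fraction
    ``threshold_fraction`` of the window lies inside the burst, i.e. after
    ``threshold_fraction * window / fs`` seconds (0.36 s at defaults).
    Used when aligning detected triggers to ground-truth burst onsets.
    """
    frac = threshold_fraction
    if frac is None:
        frac = profile.threshold_fraction if profile is not None else 0.60
    return frac * window / fs
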