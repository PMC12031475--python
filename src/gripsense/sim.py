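"""Synthetic surface-EMG session generator.

Produces single-channel 500 Hz sEMG-like streams with known grip-event
ground truth.  The signal model is band-limited Gaussian noise whose power
spectrum is a flat band placed *symmetrically* around a target median
frequency (so the spectral median equals the target by construction),
amplitude-modulated by a rest/burst envelope with trapezoidal ramps.
Muscle fatigue is emulated as a linear percent-per-minute drift of the
target median frequency, realized piecewise-constant per 1 s synthesis
block.

Amplitudes are in arbitrary, zero-mean ADC-like units: the downstream
trigger detector works on sample-to-sample differences and is therefore
offset invariant, so absolute units carry no information.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SimConfig",
    "GroundTruth",
    "EmgRecording",
    "SimulationError",
    "generate_session",
    "generate_cohort",
]


class SimulationError(ValueError):
    """Raised for invalid simulator configurations (overlapping events,
    out-of-band target frequency, non-integer sample counts...)."""


@dataclass(frozen=True)
class EmgRecording:
    """A uniformly sampled raw sEMG stream.

    Attributes
    ----------
    sampling_rate_hz : float
        Sampling rate; the wearable streams at 500 Hz.
    samples : np.ndarray
        Raw signal values in arbitrary ADC-like units.
    start_time_s : float
        Time of the first sample relative to session start.
    """

    sampling_rate_hz: float
    samples: np.ndarray
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("samples must be a 1-D sequence of length >= 2")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.samples.size) / self.sampling_rate_hz


@dataclass(frozen=True)
class GroundTruth:
    """Known grip-event schedule of a simulated session (onset + duration
    per burst), standing in for manually time-marked squeeze events."""

    event_onsets_s: tuple
    event_durations_s: tuple

    def __post_init__(self) -> None:
        onsets = tuple(float(t) for t in self.event_onsets_s)
        durs = tuple(float(d) for d in self.event_durations_s)
        object.__setattr__(self, "event_onsets_s", onsets)
        object.__setattr__(self, "event_durations_s", durs)
        if len(onsets) != len(durs):
            raise ValueError("onsets and durations must have equal length")
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.event_onsets_s)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic sEMG session.

    ``burst_gain`` is the ratio of burst RMS to rest RMS (1 means bursts
    are spectrally present but amplitude-invisible).  ``target_mdf_hz``
    must lie strictly inside (band_low_hz, band_high_hz);
    ``mdf_drift_pct_per_min`` < 0 emulates fatigue.
    """

    duration_s: float
    sampling_rate_hz: float = 500.0
    event_onsets_s: Sequence[float] | None = None
    mean_inter_event_s: float | None = None
    burst_duration_s: float = 1.0
    rest_rms: float = 1.0
    burst_gain: float = 5.0
    band_low_hz: float = 20.0
    band_high_hz: float = 250.0
    target_mdf_hz: float = 100.0
    mdf_drift_pct_per_min: float = 0.0
    ramp_s: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        fs = self.sampling_rate_hz
        if fs <= 0 or self.duration_s <= 0:
            raise SimulationError("sampling rate and duration must be positive")
        n = self.duration_s * fs
        if abs(n - round(n)) > 1e-9:
            raise SimulationError(
                f"duration_s * sampling_rate_hz = {n} is not a whole number of samples"
            )
        if not (0 < self.band_low_hz < self.target_mdf_hz < self.band_high_hz):
            raise SimulationError(
                "target_mdf_hz must satisfy band_low < target_mdf < band_high"
            )
        if self.band_high_hz >= fs / 2 * 1.0001 and self.band_high_hz > fs / 2:
            raise SimulationError("band_high_hz must not exceed the Nyquist frequency")
        if self.rest_rms <= 0 or self.burst_gain < 1:
            raise SimulationError("rest_rms must be > 0 and burst_gain >= 1")
        if self.burst_duration_s <= 0:
            raise SimulationError("burst_duration_s must be positive")
        if self.event_onsets_s is None and self.mean_inter_event_s is None:
            # silent rest-only session is allowed
            pass

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))


def _schedule_events(config: SimConfig, rng: np.random.Generator) -> GroundTruth:
    """Fixed schedule passthrough, or random non-overlapping scheduling."""
    dur = config.burst_duration_s
    if config.event_onsets_s is not None:
        onsets = [float(t) for t in config.event_onsets_s]
        for a, b in zip(onsets, onsets[1:]):
            if b < a + dur:
                raise SimulationError(
                    f"events at {a:.3f}s and {b:.3f}s overlap (burst duration {dur}s)"
                )
        for t in onsets:
            if t < 0 or t + dur > config.duration_s:
                raise SimulationError(f"event at {t:.3f}s falls outside the session")
        return GroundTruth(tuple(onsets), tuple(dur for _ in onsets))
    if config.mean_inter_event_s is None:
        return GroundTruth((), ())
    if config.mean_inter_event_s <= dur:
        raise SimulationError("mean_inter_event_s must exceed burst_duration_s")
    # gap = guaranteed clearance + exponential jitter; no overlap by construction
    min_gap = 0.5 * (config.mean_inter_event_s - dur)
    onsets: list[float] = []
    t = 1.0 + rng.exponential(min_gap)
    while t + dur <= config.duration_s - 0.5:
        onsets.append(t)
        t += dur + min_gap + rng.exponential(config.mean_inter_event_s - dur - min_gap)
    return GroundTruth(tuple(onsets), tuple(dur for _ in onsets))


def _envelope(config: SimConfig, truth: GroundTruth) -> np.ndarray:
    """Trapezoidal rest/burst RMS envelope sampled at the signal rate."""
    fs = config.sampling_rate_hz
    t = np.arange(config.n_samples) / fs
    env = np.full(config.n_samples, config.rest_rms)
    burst = config.burst_gain * config.rest_rms
    ramp = max(config.ramp_s, 1.0 / fs)
    for onset, dur in zip(truth.event_onsets_s, truth.event_durations_s):
        rise = np.clip((t - onset) / ramp, 0.0, 1.0)
        fall = np.clip(((onset + dur) - t) / ramp, 0.0, 1.0)
        shape = np.minimum(rise, fall)
        env = np.maximum(env, config.rest_rms + (burst - config.rest_rms) * shape)
    return env


def _band_for_target(config: SimConfig, target_hz: float) -> tuple[float, float]:
    """Flat spectral band symmetric about ``target_hz`` inside the config band.

    Symmetry makes the spectral median exactly the target.  Half-width is
    capped at 60 Hz, mimicking the concentration of sEMG power in a
    sub-band of the 20-250 Hz range.
    """
    nyq = config.sampling_rate_hz / 2
    half = min(60.0, target_hz - config.band_low_hz, config.band_high_hz - target_hz,
               0.99 * nyq - target_hz)
    if half <= 0:
        raise SimulationError(f"target MDF {target_hz:.1f} Hz too close to band edge")
    return target_hz - half, target_hz + half


def _shaped_block(n: int, fs: float, f_lo: float, f_hi: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise confined to [f_lo, f_hi], via spectral masking."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < f_lo) | (freqs > f_hi)] = 0.0
    block = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(block**2))
    if rms == 0:  # pragma: no cover - band always contains >= 1 bin
        raise SimulationError("spectral band contains no frequency bins")
    return block / rms


def generate_session(config: SimConfig) -> tuple[EmgRecording, GroundTruth]:
    """Synthesize one sEMG session with known ground truth.

    The carrier is generated in 1 s blocks; within each block the target
    median frequency is held constant at its drifted value for the block
    midpoint.  The carrier is normalized to unit RMS per block and then
    multiplied by the rest/burst envelope, so segment RMS matches
    ``rest_rms`` / ``burst_gain * rest_rms`` closely.

    Deterministic: identical config (including seed) gives identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _schedule_events(config, rng)
    fs = config.sampling_rate_hz
    n_total = config.n_samples
    block_n = int(round(fs))  # 1 s blocks
    carrier = np.empty(n_total)
    pos = 0
    while pos < n_total:
        n = min(block_n, n_total - pos)
        t_mid_min = (pos + n / 2) / fs / 60.0
        target = config.target_mdf_hz * (
            1.0 + config.mdf_drift_pct_per_min / 100.0 * t_mid_min
        )
        target = float(np.clip(target, config.band_low_hz * 1.2,
                               config.band_high_hz / 1.02))
        f_lo, f_hi = _band_for_target(config, target)
        carrier[pos:pos + n] = _shaped_block(n, fs, f_lo, f_hi, rng)
        pos += n
    samples = carrier * _envelope(config, truth)
    return EmgRecording(fs, samples), truth


def generate_cohort(
    n_subjects: int,
    config_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    base_config: SimConfig | None = None,
) -> list[tuple[EmgRecording, GroundTruth]]:
    """Generate a cohort of independent synthetic subjects.

    Per-subject seeds derive deterministically from the master seed; the
    numeric fields named in ``config_ranges`` are drawn uniformly inside
    their (low, high) ranges, everything else comes from ``base_config``.
    """
    if n_subjects < 1:
        raise SimulationError("n_subjects must be >= 1")
    config_ranges = config_ranges or {}
    for name, (lo, hi) in config_ranges.items():
        if hi < lo:
            raise SimulationError(f"empty range for {name!r}: ({lo}, {hi})")
    base = base_config or SimConfig(duration_s=60.0)
    sessions = []
    for i in range(n_subjects):
        ss = np.random.SeedSequence([int(seed), i])
        subj_seed = int(ss.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(subj_seed)
        overrides = {
            name: float(rng.uniform(lo, hi)) for name, (lo, hi) in config_ranges.items()
        }
        cfg = replace(base, seed=subj_seed, **overrides)
        sessions.append(generate_session(cfg))
    return sessions


def derived_subject_config(
    base: SimConfig, master_seed: int, index: int,
    config_ranges: dict[str, tuple[float, float]] | None = None,
) -> SimConfig:
    """The exact per-subject config ``generate_cohort`` uses (for tests and
    reproducibility tooling)."""
    config_ranges = config_ranges or {}
    ss = np.random.SeedSequence([int(master_seed), index])
    subj_seed = int(ss.generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(subj_seed)
    overrides = {
        name: float(rng.uniform(lo, hi)) for name, (lo, hi) in config_ranges.items()
    }
    return replace(base, seed=subj_seed, **overrides)
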