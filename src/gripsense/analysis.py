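"""Offline sEMG analysis: bandpass -> normalize -> rectify -> peak
picking, plus spectral median frequency (MDF) and the fatigue statistic.

MDF — the frequency splitting the power spectrum into equal-power halves
— declines as a muscle fatigues, which makes the percent change of MDF
between the last and first gameplay segments the session's fatigue
marker:  100 * (MDF_game3 - MDF_game1) / MDF_game1.

Mean peak amplitude (MPA) is the average height of grip-exertion peaks in
the rectified, normalized envelope; normalization is computed once per
full recording so amplitude differences between segments survive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .sim import EmgRecording

__all__ = [
    "ProcessedSignal",
    "SignalMetrics",
    "FatigueResult",
    "bandpass",
    "normalize_rectify",
    "find_activity_peaks",
    "median_frequency",
    "preprocess",
    "segment_and_summarize",
]


@dataclass(frozen=True)
class ProcessedSignal:
    """Pipeline intermediates for one recording."""

    sampling_rate_hz: float
    filtered: np.ndarray      # band-limited
    normalized: np.ndarray    # in [-1, 1], max |.| == 1
    rectified: np.ndarray     # |normalized|, in [0, 1]
    peak_indices: np.ndarray


@dataclass(frozen=True)
class SignalMetrics:
    """Per-game-segment summary: mean peak amplitude and median frequency."""

    segment_id: str
    mpa: float
    mdf_hz: float
    n_peaks: int


@dataclass(frozen=True)
class FatigueResult:
    """Signed percent change of MDF between the last and first game."""

    pct_change_mdf: float
    mdf_game1_hz: float
    mdf_game3_hz: float


def bandpass(
    x: np.ndarray, fs: float, low: float = 20.0, high: float = 250.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth bandpass.

    The upper edge is clamped just below Nyquist (a 250 Hz edge is
    unrealizable at 500 Hz sampling); applied forward-backward so peak
    timing is phase-true.
    """
    x = np.asarray(x, dtype=float)
    nyq = fs / 2.0
    high = min(high, 0.99 * nyq)
    if not (0 < low < high):
        raise ValueError(f"invalid band [{low}, {high}] Hz at fs={fs} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def normalize_rectify(filtered: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale to [-1, 1] by the global absolute maximum, then rectify."""
    filtered = np.asarray(filtered, dtype=float)
    peak = np.max(np.abs(filtered))
    if peak == 0:
        raise ValueError("all-zero input cannot be normalized")
    normalized = filtered / peak
    return normalized, np.abs(normalized)


def find_activity_peaks(
    rectified: np.ndarray,
    fs: float,
    min_height: float = 0.1,
    min_separation_s: float = 0.5,
) -> np.ndarray:
    """Local maxima of the rectified envelope that plausibly correspond to
    grip exertions: above ``min_height`` and at least ``min_separation_s``
    apart (the taller of two close peaks is kept)."""
    if min_height <= 0 or min_separation_s <= 0:
        raise ValueError("peak parameters must be positive")
    peaks, _ = sps.find_peaks(
        np.asarray(rectified, dtype=float),
        height=min_height,
        distance=max(1, int(round(min_separation_s * fs))),
    )
    return peaks


def _level_crossing(freqs: np.ndarray, cum: np.ndarray, level: float) -> float:
    """Frequency where the normalized cumulative power crosses ``level``,
    linearly interpolated between spectrum bins."""
    i = int(np.searchsorted(cum, level))
    if i == 0:
        return float(freqs[0])
    if i >= cum.size:
        return float(freqs[-1])
    c0, c1 = cum[i - 1], cum[i]
    if c1 == c0:
        return float(freqs[i])
    return float(freqs[i - 1] + (level - c0) / (c1 - c0) * (freqs[i] - freqs[i - 1]))


def median_frequency(segment: np.ndarray, fs: float, nperseg_s: float = 1.0) -> float:
    """Median frequency of a signal segment via a Welch spectrum
    (1 s Hann windows, 50% overlap).

    The MDF is the frequency at which cumulative power reaches half the
    total, linearly interpolated between bins.  To keep the estimate
    well defined when the spectrum has two separated lobes of exactly
    equal power (the cumulative curve plateaus at one half), the crossing
    is evaluated just below and just above the half-power level and the
    two frequencies averaged — the midpoint of the cumulative step.
    Amplitude scaling of the input cancels.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size < fs * 1.0:
        raise ValueError("segment must cover at least 1 s")
    nperseg = min(int(round(nperseg_s * fs)), segment.size)
    freqs, psd = sps.welch(segment, fs=fs, nperseg=nperseg, noverlap=nperseg // 2)
    total = float(np.sum(psd))
    if total <= 0:
        raise ValueError("zero-power segment has no median frequency")
    cum = np.cumsum(psd) / total
    eps = 1e-3
    lo = _level_crossing(freqs, cum, 0.5 - eps)
    hi = _level_crossing(freqs, cum, 0.5 + eps)
    return 0.5 * (lo + hi)


def preprocess(
    recording: EmgRecording,
    low: float = 20.0,
    high: float = 250.0,
    min_peak_height: float = 0.1,
    min_peak_separation_s: float = 0.5,
) -> ProcessedSignal:
    """Run the full per-recording pipeline (bandpass, normalize, rectify,
    peak-pick) and bundle the intermediates."""
    filtered = bandpass(recording.samples, recording.sampling_rate_hz, low, high)
    normalized, rectified = normalize_rectify(filtered)
    peaks = find_activity_peaks(
        rectified, recording.sampling_rate_hz, min_peak_height, min_peak_separation_s
    )
    return ProcessedSignal(
        recording.sampling_rate_hz, filtered, normalized, rectified, peaks
    )


def segment_and_summarize(
    recording: EmgRecording,
    game_boundaries: list[tuple[float, float]],
    low: float = 20.0,
    high: float = 250.0,
    min_peak_height: float = 0.1,
    min_peak_separation_s: float = 0.5,
) -> tuple[list[SignalMetrics], FatigueResult, list[tuple[float, float]]]:
    """Per-game MPA and MDF, the fatigue percent change (last vs first
    game), and the per-minute MDF series across gameplay.

    ``game_boundaries`` are (start_s, end_s) pairs in recording time, in
    order, non-overlapping.  Normalization is computed over the full
    recording; MDF is computed on the bandpassed, pre-normalization
    signal (rectification distorts the spectrum).
    """
    if len(game_boundaries) < 2:
        raise ValueError("need at least two game segments")
    for (a0, a1), (b0, b1) in zip(game_boundaries, game_boundaries[1:]):
        if a1 > b0:
            raise ValueError(f"segments ({a0},{a1}) and ({b0},{b1}) overlap")
    fs = recording.sampling_rate_hz
    processed = preprocess(recording, low, high, min_peak_height, min_peak_separation_s)
    peak_times = recording.start_time_s + (processed.peak_indices + 0.0) / fs

    metrics: list[SignalMetrics] = []
    minute_mdf: list[tuple[float, float]] = []
    for gi, (t0, t1) in enumerate(game_boundaries, start=1):
        i0 = int(round((t0 - recording.start_time_s) * fs))
        i1 = int(round((t1 - recording.start_time_s) * fs))
        if i0 < 0 or i1 > recording.samples.size or i1 <= i0:
            raise ValueError(f"segment ({t0},{t1}) outside the recording")
        seg_filtered = processed.filtered[i0:i1]
        in_seg = (peak_times >= t0) & (peak_times < t1)
        heights = processed.rectified[processed.peak_indices[in_seg]]
        mpa = float(np.mean(heights)) if heights.size else float("nan")
        mdf = median_frequency(seg_filtered, fs)
        metrics.append(SignalMetrics(f"Game {gi}", mpa, mdf, int(heights.size)))
        # per-minute MDF series (scatter input for fatigue-over-time plots)
        n_min = int((t1 - t0) // 60)
        for m in range(n_min):
            j0 = i0 + int(m * 60 * fs)
            j1 = min(i0 + int((m + 1) * 60 * fs), i1)
            minute_mdf.append(
                (t0 + m * 60 + 30.0, median_frequency(processed.filtered[j0:j1], fs))
            )
    mdf1 = metrics[0].mdf_hz
    mdf3 = metrics[-1].mdf_hz
    fatigue = FatigueResult(100.0 * (mdf3 - mdf1) / mdf1, mdf1, mdf3)
    return metrics, fatigue, minute_mdf
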