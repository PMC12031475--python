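"""CSV schemas shared by all pipeline stages.

Every artifact is UTF-8 CSV with a header row and dot-decimal floats;
times are seconds from session start.  Readers validate the schema
strictly: missing columns, non-numeric cells (including locale-style
decimal commas) and non-monotone timestamps raise :class:`FormatError`
rather than being silently coerced.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .sim import EmgRecording, GroundTruth

__all__ = [
    "FormatError",
    "write_emg_csv",
    "read_emg_csv",
    "write_ground_truth_csv",
    "read_ground_truth_csv",
    "write_triggers_csv",
    "read_triggers_csv",
    "write_stream_csv",
    "write_session_log_csvs",
    "write_segments_csv",
    "read_segments_csv",
    "read_useq_csv",
]


class FormatError(ValueError):
    """A CSV artifact does not conform to its schema."""


def _read_checked(path, required: list[str], monotone: list[str] | None = None) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # parse-level failure
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    for col in required:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            raise FormatError(
                f"{path}: column {col!r} contains non-numeric values "
                "(decimal commas are not accepted; use dot decimals)"
            )
        df[col] = coerced
    for col in monotone or []:
        if np.any(np.diff(df[col].to_numpy()) < 0):
            raise FormatError(f"{path}: column {col!r} must be non-decreasing")
    return df


def write_emg_csv(path, recording: EmgRecording) -> None:
    pd.DataFrame(
        {"time_s": recording.times_s, "raw": recording.samples}
    ).to_csv(path, index=False)


def read_emg_csv(path) -> EmgRecording:
    df = _read_checked(path, ["time_s", "raw"], monotone=["time_s"])
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise FormatError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise FormatError(f"{path}: non-uniform sampling interval")
    fs = 1.0 / float(np.mean(dt))
    return EmgRecording(fs, df["raw"].to_numpy(), start_time_s=float(t[0]))


def write_ground_truth_csv(path, truth: GroundTruth) -> None:
    pd.DataFrame(
        {"onset_s": truth.event_onsets_s, "duration_s": truth.event_durations_s}
    ).to_csv(path, index=False)


def read_ground_truth_csv(path) -> GroundTruth:
    df = _read_checked(path, ["onset_s", "duration_s"], monotone=["onset_s"])
    return GroundTruth(tuple(df["onset_s"]), tuple(df["duration_s"]))


def write_triggers_csv(path, trigger_times_s) -> None:
    pd.DataFrame({"time_s": list(trigger_times_s)}).to_csv(path, index=False)


def read_triggers_csv(path) -> list[float]:
    df = _read_checked(path, ["time_s"], monotone=["time_s"])
    return [float(t) for t in df["time_s"]]


def write_stream_csv(path, recording: EmgRecording, activity: np.ndarray) -> None:
    """The wearable's transmitted packet content: raw value plus the 0/1
    trigger/activity flag, per sample."""
    pd.DataFrame(
        {
            "time_s": recording.times_s,
            "raw": recording.samples,
            "trigger": np.asarray(activity, dtype=int),
        }
    ).to_csv(path, index=False)


def write_session_log_csvs(out_dir, log, prefix: str = "") -> dict[str, Path]:
    """Write the game's three metric spreadsheets: clicks.csv,
    difficulty_changes.csv, outcomes.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["clicks"] = out_dir / f"{prefix}clicks.csv"
    pd.DataFrame({"time_s": log.click_times_s}).to_csv(paths["clicks"], index=False)
    paths["difficulty_changes"] = out_dir / f"{prefix}difficulty_changes.csv"
    pd.DataFrame(
        log.difficulty_changes, columns=["time_s", "old_level", "new_level"]
    ).to_csv(paths["difficulty_changes"], index=False)
    paths["outcomes"] = out_dir / f"{prefix}outcomes.csv"
    pd.DataFrame(log.outcomes, columns=["time_s", "kind"]).to_csv(
        paths["outcomes"], index=False
    )
    return paths


def write_segments_csv(path, boundaries: list[tuple[float, float]]) -> None:
    pd.DataFrame(
        [
            {"game_id": i + 1, "start_s": a, "end_s": b}
            for i, (a, b) in enumerate(boundaries)
        ]
    ).to_csv(path, index=False)


def read_segments_csv(path) -> list[tuple[float, float]]:
    df = _read_checked(path, ["game_id", "start_s", "end_s"], monotone=["start_s"])
    return [(float(r.start_s), float(r.end_s)) for r in df.itertuples()]


def read_useq_csv(path) -> pd.DataFrame:
    """Respondent x question Likert table with columns Q1..Q6."""
    return _read_checked(path, [f"Q{i}" for i in range(1, 7)])
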