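"""Structured session configuration binding all pipeline stages.

The default protocol mirrors the feasibility-study layout: calibration,
then three 5 min games separated by 3 min rests (15 min of play, ~21 min
in total), all driven by a single master seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .game import GameConfig
from .sim import SimConfig

__all__ = ["DamConfig", "AnalysisConfig", "ProtocolLayout", "SessionConfig"]


@dataclass(frozen=True)
class DamConfig:
    threshold_fraction: float = 0.60
    refractory_s: float = 0.3
    gain: float = 1.0
    separation_factor: float = 1.5


@dataclass(frozen=True)
class AnalysisConfig:
    band_low_hz: float = 20.0
    band_high_hz: float = 250.0
    min_peak_height: float = 0.1
    min_peak_separation_s: float = 0.5


@dataclass(frozen=True)
class ProtocolLayout:
    n_games: int = 3
    game_duration_s: float = 300.0
    rest_s: float = 180.0

    def game_boundaries(self) -> list[tuple[float, float]]:
        bounds = []
        t = 0.0
        for _ in range(self.n_games):
            bounds.append((t, t + self.game_duration_s))
            t += self.game_duration_s + self.rest_s
        return bounds

    @property
    def total_duration_s(self) -> float:
        return self.n_games * self.game_duration_s + (self.n_games - 1) * self.rest_s


@dataclass(frozen=True)
class SessionConfig:
    simulator: SimConfig = field(
        default_factory=lambda: SimConfig(
            duration_s=1260.0, mean_inter_event_s=10.0, burst_gain=5.0
        )
    )
    dam: DamConfig = field(default_factory=DamConfig)
    game: GameConfig = field(default_factory=GameConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    protocol: ProtocolLayout = field(default_factory=ProtocolLayout)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.simulator.duration_s - self.protocol.total_duration_s) > 1e-9:
            object.__setattr__(
                self,
                "simulator",
                replace(self.simulator, duration_s=self.protocol.total_duration_s),
            )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SessionConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        sections = {
            "simulator": SimConfig,
            "dam": DamConfig,
            "game": GameConfig,
            "analysis": AnalysisConfig,
            "protocol": ProtocolLayout,
        }
        for name, cls_ in sections.items():
            if name in raw:
                valid = {f.name for f in fields(cls_)}
                unknown = set(raw[name]) - valid
                if unknown:
                    raise ValueError(f"unknown keys in {name!r}: {sorted(unknown)}")
                kwargs[name] = cls_(**raw[name])
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        return cls(**kwargs)
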