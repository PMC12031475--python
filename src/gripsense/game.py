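"""Headless adaptive jump-and-run game engine.

Re-creation of the rehabilitation game's rules without any rendering: a
character runs at a level-dependent speed, grip triggers make it jump
over spawned obstacles (small or large) and collect coins, three lives
absorb mistakes, and a success-rate window drives automatic difficulty
transitions between three levels.  All state advances on a fixed-step
simulated clock, so sessions are fully deterministic given a seed.

Difficulty structure: level 1 is slow with only small obstacles; level 2
adds coins and a mix of obstacle sizes; level 3 is fastest with only
large obstacles.  A collision at one remaining life pauses the game for
5 s and resets to level 1 with three lives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DifficultyLevel",
    "GameConfig",
    "GameState",
    "PerformanceWindow",
    "GameSessionLog",
    "LEVELS",
    "decide_difficulty",
    "lose_life",
    "step",
    "run_session",
    "perfect_trigger_times",
]

LIFE_COLORS = {3: "green", 2: "yellow", 1: "red"}


@dataclass(frozen=True)
class DifficultyLevel:
    level: int
    game_speed: float  # world units / s
    p_large_obstacle: float
    coins_enabled: bool


#: The three difficulty levels.  Only the ordering of speeds and the
#: small-only / mixed / large-only obstacle structure is fixed by the
#: game's design; the numeric speeds are engine defaults.
LEVELS = {
    1: DifficultyLevel(1, 1.0, 0.0, False),
    2: DifficultyLevel(2, 1.3, 0.5, True),
    3: DifficultyLevel(3, 1.6, 1.0, True),
}


@dataclass(frozen=True)
class GameConfig:
    """Tunable game parameters (all times in seconds of game clock)."""

    window_s: float = 15.0          # performance evaluation cadence
    up_threshold: float = 0.8       # success rate to raise difficulty
    down_threshold: float = 0.4     # success rate to lower difficulty
    spawn_interval_s: float = 2.0
    spawn_jitter_s: float = 0.3
    spawn_distance: float = 3.0     # world units from spawn to character
    jump_duration_s: float = 0.7
    small_margin_s: float = 0.35    # jump-center timing margin, small obstacle
    large_margin_s: float = 0.20    # tighter margin: large obstacles punish mistiming
    coin_probability: float = 0.3   # per spawn, when coins are enabled
    pause_s: float = 5.0
    dt_s: float = 0.02

    def margin_for(self, size: str) -> float:
        return self.large_margin_s if size == "large" else self.small_margin_s


@dataclass
class PerformanceWindow:
    """Rolling success-rate bookkeeping for one evaluation window.

    ``attempts`` counts obstacles whose outcome (clearance or collision)
    resolved inside the window; coins are excluded.
    """

    window_s: float = 15.0
    attempts: int = 0
    successes: int = 0

    @property
    def success_rate(self) -> float:
        if self.attempts == 0:
            raise ValueError("success rate undefined with zero attempts")
        return self.successes / self.attempts


@dataclass
class _Obstacle:
    arrival_s: float
    size: str  # "small" | "large"


@dataclass
class _Coin:
    arrival_s: float


@dataclass
class GameState:
    """Full mutable game state advanced by :func:`step`."""

    config: GameConfig = field(default_factory=GameConfig)
    clock_s: float = 0.0
    lives: int = 3
    current_level: DifficultyLevel = LEVELS[1]
    paused_until_s: float | None = None
    jump_start_s: float | None = None
    next_spawn_s: float = 1.0
    window: PerformanceWindow = field(default_factory=PerformanceWindow)
    window_end_s: float = 15.0
    obstacles: list = field(default_factory=list)
    coins: list = field(default_factory=list)

    @property
    def character_color(self) -> str:
        return LIFE_COLORS[self.lives]

    @property
    def paused(self) -> bool:
        return self.paused_until_s is not None and self.clock_s < self.paused_until_s

    def airborne_at(self, t: float) -> bool:
        return (
            self.jump_start_s is not None
            and self.jump_start_s <= t <= self.jump_start_s + self.config.jump_duration_s
        )


@dataclass
class GameSessionLog:
    """The three logged metric streams: detected squeeze/click timestamps,
    difficulty-level changes, and obstacle/coin/collision outcomes."""

    click_times_s: list = field(default_factory=list)
    difficulty_changes: list = field(default_factory=list)  # (time, old, new)
    outcomes: list = field(default_factory=list)  # (time, kind)


def decide_difficulty(
    window: PerformanceWindow,
    current_level: DifficultyLevel,
    up_threshold: float = 0.8,
    down_threshold: float = 0.4,
) -> DifficultyLevel:
    """Raise/lower/hold the difficulty from the window's success rate.

    A very good window (rate >= up_threshold) moves one level up, a poor
    one (rate <= down_threshold) one level down; transitions are clamped
    to [1, 3] and never skip a level.  With zero attempts the level holds.
    """
    if window.attempts == 0:
        return current_level
    rate = window.success_rate
    if rate >= up_threshold:
        return LEVELS[min(current_level.level + 1, 3)]
    if rate <= down_threshold:
        return LEVELS[max(current_level.level - 1, 1)]
    return current_level


def lose_life(state: GameState) -> GameState:
    """Apply a collision: decrement lives (3->2->1 with green->yellow->red
    color); a collision at one life pauses for 5 s, resets to level 1 and
    restores three lives (green)."""
    if state.lives > 1:
        state.lives -= 1
        return state
    state.paused_until_s = state.clock_s + state.config.pause_s
    state.current_level = LEVELS[1]
    state.lives = 3
    state.jump_start_s = None
    state.obstacles.clear()
    state.coins.clear()
    state.window = PerformanceWindow(state.config.window_s)
    return state


def step(
    state: GameState,
    dt_s: float,
    trigger_fired: bool,
    rng: np.random.Generator,
    log: GameSessionLog | None = None,
    trigger_time_s: float | None = None,
) -> tuple[GameState, GameSessionLog]:
    """Advance the game by one tick.

    A trigger is always logged as a click (the click stream mirrors the
    detector output) but only starts a jump while unpaused and grounded.
    Obstacles spawn on a jittered interval and arrive after
    ``spawn_distance / game_speed`` seconds; an obstacle is cleared when
    the jump midpoint falls within the size-dependent timing margin of
    the arrival, otherwise it costs a life.  No spawning or outcome
    resolution happens while paused.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    log = log if log is not None else GameSessionLog()
    cfg = state.config
    state.clock_s += dt_s
    now = state.clock_s

    if trigger_fired:
        t_click = trigger_time_s if trigger_time_s is not None else now
        log.click_times_s.append(t_click)
        if not state.paused and not state.airborne_at(now):
            state.jump_start_s = t_click

    if state.paused:
        state.next_spawn_s = max(state.next_spawn_s, state.paused_until_s)
        state.window_end_s = max(state.window_end_s, state.paused_until_s + cfg.window_s)
        return state, log

    # spawning
    while now >= state.next_spawn_s:
        level = state.current_level
        spawn_t = state.next_spawn_s
        travel = cfg.spawn_distance / level.game_speed
        size = "large" if rng.random() < level.p_large_obstacle else "small"
        state.obstacles.append(_Obstacle(spawn_t + travel, size))
        if level.coins_enabled and rng.random() < cfg.coin_probability:
            state.coins.append(_Coin(spawn_t + travel + 0.5 * cfg.spawn_interval_s))
        state.next_spawn_s = spawn_t + cfg.spawn_interval_s + rng.uniform(
            -cfg.spawn_jitter_s, cfg.spawn_jitter_s
        )

    # obstacle outcomes
    for obs in [o for o in state.obstacles if o.arrival_s <= now]:
        state.obstacles.remove(obs)
        cleared = False
        if state.jump_start_s is not None and state.airborne_at(obs.arrival_s):
            mid = state.jump_start_s + cfg.jump_duration_s / 2
            cleared = abs(obs.arrival_s - mid) <= cfg.margin_for(obs.size)
        state.window.attempts += 1
        if cleared:
            state.window.successes += 1
            log.outcomes.append((obs.arrival_s, "obstacle_cleared"))
        else:
            log.outcomes.append((obs.arrival_s, "collision"))
            lose_life(state)
            if state.paused:
                return state, log

    # coin outcomes (never cost lives; misses are not attempts)
    for coin in [c for c in state.coins if c.arrival_s <= now]:
        state.coins.remove(coin)
        if state.airborne_at(coin.arrival_s):
            log.outcomes.append((coin.arrival_s, "coin_collected"))

    # difficulty evaluation on the window cadence
    if now >= state.window_end_s:
        old = state.current_level
        new = decide_difficulty(state.window, old, cfg.up_threshold, cfg.down_threshold)
        if new.level != old.level:
            log.difficulty_changes.append((now, old.level, new.level))
            state.current_level = new
        state.window = PerformanceWindow(cfg.window_s)
        state.window_end_s += cfg.window_s

    return state, log


def run_session(
    trigger_times: Sequence[float],
    duration_s: float = 300.0,
    config: GameConfig | None = None,
    seed: int = 0,
) -> GameSessionLog:
    """Play one game session of ``duration_s`` seconds driven by a sorted
    list of trigger times; deterministic given the seed.

    Clicks are logged at the exact trigger times, so replaying the same
    trigger list reproduces the click stream identically.
    """
    trigger_times = list(trigger_times)
    if any(b < a for a, b in zip(trigger_times, trigger_times[1:])):
        raise ValueError("trigger_times must be sorted")
    cfg = config or GameConfig()
    rng = np.random.default_rng(seed)
    state = GameState(config=cfg, window_end_s=cfg.window_s)
    log = GameSessionLog()
    idx = 0
    n_ticks = int(round(duration_s / cfg.dt_s))
    for k in range(n_ticks):
        t_next = (k + 1) * cfg.dt_s
        fired = idx < len(trigger_times) and trigger_times[idx] <= t_next
        t_trig = trigger_times[idx] if fired else None
        if fired:
            idx += 1
        state, log = step(state, cfg.dt_s, fired, rng, log, trigger_time_s=t_trig)
        # multiple triggers inside one tick: log the extras as clicks
        while idx < len(trigger_times) and trigger_times[idx] <= t_next:
            log.click_times_s.append(trigger_times[idx])
            idx += 1
    return log


def perfect_trigger_times(
    duration_s: float, config: GameConfig | None = None, level: int = 1
) -> list[float]:
    """Trigger schedule that clears every obstacle of a fixed-level,
    jitter-free session (jump midpoint exactly on each arrival).

    Only meaningful with ``spawn_jitter_s = 0`` and a level that does not
    change during the run (it will change: perfect play raises the
    difficulty, which alters later arrival times — use for single-window
    scripted traces)."""
    cfg = config or GameConfig(spawn_jitter_s=0.0, coin_probability=0.0)
    lvl = LEVELS[level]
    travel = cfg.spawn_distance / lvl.game_speed
    times = []
    t = 1.0  # first spawn
    while t + travel <= duration_s:
        times.append(t + travel - cfg.jump_duration_s / 2)
        t += cfg.spawn_interval_s
    return times
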