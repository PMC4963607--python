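"""Headless engine for the food go/nogo + stop-signal training game.

The training game shows a grid of food images; on each trial one image
becomes "active" (a countdown timer appears beside it) and the player must
tap it before the reaction-time deadline (RTD) if it is healthy (Go), or
withhold the tap if it is unhealthy (Nogo).  On *stop* trials the active
image starts healthy and switches to unhealthy partway through the
countdown, requiring cancellation of an already-prepared response.

Each game has 30 trials.  The Go proportion is redrawn uniformly in
[0.70, 0.90] every game so that players cannot pre-prepare responses from
stimulus statistics.  Difficulty is a monotone staircase: promotion after a
good game shortens the RTD and adds one image to the grid (capped at 12
images).

This module also contains the post-hoc log analysis used on a completed
training course: the adherence cutoff (>= 90 games played), the split of a
participant's games into equal consecutive session blocks, and per-block
performance summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GO = "go"
NOGO = "nogo"
STOP = "stop"
TRIAL_KINDS = (GO, NOGO, STOP)

HEALTHY = "healthy"
UNHEALTHY = "unhealthy"

CORRECT_GO = "correct_go"
OMISSION = "omission"
CORRECT_INHIBIT = "correct_inhibit"
COMMISSION = "commission"

#: Latency slack beyond the deadline that is still recorded (a late tap is a
#: miss, not malformed data).  Latencies beyond rtd + grace are rejected as
#: malformed input.
DEFAULT_GRACE_MS = 300.0


class ScheduleError(ValueError):
    """Raised when a game configuration cannot yield a valid trial schedule."""


@dataclass(frozen=True)
class GameConfig:
    """Parameters of one training game and of the difficulty staircase.

    ``rtd_start_ms``, ``rtd_step_ms`` and ``rtd_floor_ms`` define the
    per-level deadline schedule ``rtd(level) = max(floor, start - step*(level-1))``,
    which is non-increasing in level by construction.
    """

    trials_per_game: int = 30
    go_prop_range: tuple[float, float] = (0.70, 0.90)
    stop_trial_prop: float = 0.10
    max_images: int = 12
    rtd_start_ms: float = 1000.0
    rtd_step_ms: float = 50.0
    rtd_floor_ms: float = 250.0
    grace_ms: float = DEFAULT_GRACE_MS
    promote_accuracy: float = 0.85
    promote_min_correct_nogo: int = 1
    promote_max_rt_frac: float = 0.65
    stop_change_range_ms: tuple[float, float] = (100.0, 300.0)

    def __post_init__(self) -> None:
        if self.trials_per_game < 1:
            raise ValueError("trials_per_game must be >= 1")
        lo, hi = self.go_prop_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("go_prop_range must satisfy 0 <= lo <= hi <= 1")
        if self.max_images < 1:
            raise ValueError("max_images must be >= 1")
        if not 0.0 <= self.stop_trial_prop <= 1.0:
            raise ValueError("stop_trial_prop must be a proportion")
        if self.rtd_floor_ms <= 0 or self.rtd_start_ms < self.rtd_floor_ms:
            raise ValueError("deadline schedule must stay positive")
        # a draw at the low end of the Go range must leave at least one
        # non-Go trial, otherwise some games would contain nothing to inhibit
        if self.trials_per_game - round(lo * self.trials_per_game) < 1:
            raise ScheduleError(
                "go_prop_range lower bound leaves no non-Go trial in a game"
            )

    def rtd_for_level(self, level: int) -> float:
        if level < 1:
            raise ValueError("level must be >= 1")
        return max(self.rtd_floor_ms, self.rtd_start_ms - self.rtd_step_ms * (level - 1))

    def n_images_for_level(self, level: int) -> int:
        return min(level, self.max_images)

    @property
    def max_level(self) -> int:
        """Level at which the deadline schedule reaches its floor."""
        if self.rtd_step_ms <= 0:
            return 1
        return 1 + math.ceil((self.rtd_start_ms - self.rtd_floor_ms) / self.rtd_step_ms)


@dataclass(frozen=True)
class DifficultyState:
    level: int
    rtd_ms: float
    n_images: int

    @classmethod
    def initial(cls, config: GameConfig) -> "DifficultyState":
        return cls.at_level(config, 1)

    @classmethod
    def at_level(cls, config: GameConfig, level: int) -> "DifficultyState":
        return cls(
            level=level,
            rtd_ms=config.rtd_for_level(level),
            n_images=config.n_images_for_level(level),
        )


@dataclass(frozen=True)
class Trial:
    """One scheduled stimulus event within a game."""

    index: int
    kind: str
    category: str
    rtd_ms: float
    change_latency_ms: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in TRIAL_KINDS:
            raise ValueError(f"unknown trial kind {self.kind!r}")
        if self.kind == GO and self.category != HEALTHY:
            raise ValueError("go trials are healthy images")
        if self.kind == NOGO and self.category != UNHEALTHY:
            raise ValueError("nogo trials are unhealthy images")
        if self.kind == STOP:
            if self.category != HEALTHY:
                raise ValueError("stop trials start as healthy images")
            if self.change_latency_ms is None or not (
                0.0 < self.change_latency_ms < self.rtd_ms
            ):
                raise ValueError("stop change latency must lie inside (0, rtd)")
        elif self.change_latency_ms is not None:
            raise ValueError("only stop trials carry a change latency")


@dataclass(frozen=True)
class TrialResult:
    trial: Trial
    responded: bool
    rt_ms: float | None
    outcome: str


@dataclass(frozen=True)
class GameRecord:
    """Per-game log row: level played plus response counts and mean correct-Go RT."""

    game_index: int
    level: int
    mean_rt_ms: float
    n_correct_go: int
    n_correct_nogo: int
    n_errors: int
    n_omissions: int


@dataclass
class TrainingLog:
    participant_id: str
    records: list[GameRecord] = field(default_factory=list)
    games_per_day: int = 10
    days: int = 14

    def __len__(self) -> int:
        return len(self.records)

    @property
    def target_games(self) -> int:
        return self.games_per_day * self.days


def schedule_game(
    config: GameConfig, state: DifficultyState, rng: np.random.Generator
) -> list[Trial]:
    """Draw one game's randomized trial list at the current difficulty.

    The Go count is ``round(p * trials_per_game)`` for ``p`` drawn uniformly
    from the configured Go-proportion range; stop trials take the configured
    share of the remaining (non-Go) allotment, the rest are plain Nogo.
    """
    n = config.trials_per_game
    p = rng.uniform(*config.go_prop_range)
    n_go = round(p * n)
    n_non = n - n_go
    if n_non < 1:
        raise ScheduleError("drawn Go proportion leaves no non-Go trial")
    n_stop = round(config.stop_trial_prop * n_non)
    n_nogo = n_non - n_stop

    kinds = [GO] * n_go + [NOGO] * n_nogo + [STOP] * n_stop
    order = rng.permutation(len(kinds))
    lo, hi = config.stop_change_range_ms
    hi = min(hi, 0.95 * state.rtd_ms)
    lo = min(lo, 0.5 * hi)
    trials = []
    for idx, j in enumerate(order):
        kind = kinds[j]
        if kind == STOP:
            trials.append(
                Trial(
                    index=idx,
                    kind=STOP,
                    category=HEALTHY,
                    rtd_ms=state.rtd_ms,
                    change_latency_ms=float(rng.uniform(lo, hi)),
                )
            )
        else:
            trials.append(
                Trial(
                    index=idx,
                    kind=kind,
                    category=HEALTHY if kind == GO else UNHEALTHY,
                    rtd_ms=state.rtd_ms,
                )
            )
    return trials


def adjudicate(
    trial: Trial,
    responded: bool,
    rt_ms: float | None = None,
    *,
    grace_ms: float = DEFAULT_GRACE_MS,
) -> TrialResult:
    """Deterministically classify one response against its trial.

    Outcomes: a Go tap within the deadline is ``correct_go``; late or absent
    Go taps are omissions.  Any tap on an image that is unhealthy at the time
    of the tap (a Nogo image, or a stop image at/after its change) is a
    ``commission``; withholding on those is ``correct_inhibit``.  A stop
    image tapped *before* it changes is a correct Go response.
    """
    if responded != (rt_ms is not None):
        raise ValueError("rt_ms must be present iff responded")
    if responded:
        assert rt_ms is not None
        if rt_ms <= 0 or rt_ms > trial.rtd_ms + grace_ms:
            raise ValueError(f"malformed latency {rt_ms} for deadline {trial.rtd_ms}")

    if trial.kind == GO:
        outcome = CORRECT_GO if responded and rt_ms <= trial.rtd_ms else OMISSION
    elif trial.kind == NOGO:
        outcome = COMMISSION if responded else CORRECT_INHIBIT
    else:  # stop
        if not responded:
            outcome = CORRECT_INHIBIT
        elif rt_ms < trial.change_latency_ms:
            outcome = CORRECT_GO if rt_ms <= trial.rtd_ms else OMISSION
        else:
            outcome = COMMISSION
    return TrialResult(trial=trial, responded=responded, rt_ms=rt_ms, outcome=outcome)


def summarize_game(
    game_index: int, level: int, results: Sequence[TrialResult]
) -> GameRecord:
    """Collapse adjudicated trials of one game into its log row."""
    go_rts = [r.rt_ms for r in results if r.outcome == CORRECT_GO]
    return GameRecord(
        game_index=game_index,
        level=level,
        mean_rt_ms=float(np.mean(go_rts)) if go_rts else float("nan"),
        n_correct_go=sum(r.outcome == CORRECT_GO for r in results),
        n_correct_nogo=sum(r.outcome == CORRECT_INHIBIT for r in results),
        n_errors=sum(r.outcome == COMMISSION for r in results),
        n_omissions=sum(r.outcome == OMISSION for r in results),
    )


def update_difficulty(
    state: DifficultyState, last_game: GameRecord, config: GameConfig
) -> DifficultyState:
    """Staircase step: promote one level after a sufficiently good game.

    Promotion requires game accuracy (correct responses over all trials) of
    at least ``promote_accuracy``, at least ``promote_min_correct_nogo``
    correct inhibitions, and a mean correct-Go latency comfortably inside
    the current deadline (``<= promote_max_rt_frac * rtd``) — the speed
    criterion keeps the staircase from promoting a player onto a deadline
    they cannot beat, since levels never decrease.  The level also stops
    rising once the deadline schedule bottoms out.
    """
    n = config.trials_per_game
    accuracy = (last_game.n_correct_go + last_game.n_correct_nogo) / n
    fast_enough = (
        np.isfinite(last_game.mean_rt_ms)
        and last_game.mean_rt_ms <= config.promote_max_rt_frac * state.rtd_ms
    )
    promote = (
        accuracy >= config.promote_accuracy
        and last_game.n_correct_nogo >= config.promote_min_correct_nogo
        and fast_enough
        and state.level < config.max_level
    )
    if not promote:
        return state
    return DifficultyState.at_level(config, state.level + 1)


def run_course(
    agent,
    config: GameConfig,
    n_games: int,
    rng: np.random.Generator,
    participant_id: str = "sim",
) -> TrainingLog:
    """Play ``n_games`` consecutive games with difficulty carried across games.

    ``agent`` implements the response contract of :mod:`ictrain.agents`
    (``respond(trial, rng) -> (responded, rt_ms)`` and ``learn()`` called once
    per completed game).  Fully reproducible under a fixed ``rng``.
    """
    state = DifficultyState.initial(config)
    log = TrainingLog(participant_id=participant_id)
    for g in range(1, n_games + 1):
        trials = schedule_game(config, state, rng)
        results = [
            adjudicate(t, *agent.respond(t, rng), grace_ms=config.grace_ms)
            for t in trials
        ]
        record = summarize_game(g, state.level, results)
        log.records.append(record)
        agent.learn()
        state = update_difficulty(state, record, config)
    return log


def filter_adherence(
    logs: Iterable[TrainingLog], cutoff: int = 90
) -> list[TrainingLog]:
    """Keep only participants who played at least ``cutoff`` games."""
    return [log for log in logs if len(log) >= cutoff]


def split_sessions(log: TrainingLog | Sequence[GameRecord], k: int = 3) -> list[list[GameRecord]]:
    """Split a participant's games into ``k`` consecutive session blocks.

    Blocks are order-preserving, disjoint and exhaustive; sizes differ by at
    most one, with remainders going to the earliest blocks (120 games split
    exactly into 1-40 / 41-80 / 81-120).
    """
    records = list(log.records if isinstance(log, TrainingLog) else log)
    if len(records) < k:
        raise ValueError(f"need at least {k} games to form {k} sessions")
    splits = np.array_split(np.arange(len(records)), k)
    return [[records[i] for i in idx] for idx in splits]


def summarize_sessions(blocks: Sequence[Sequence[GameRecord]]) -> pd.DataFrame:
    """Per-session means of RT, correct/error counts and game level."""
    if not blocks or any(len(b) == 0 for b in blocks):
        raise ValueError("every session block must contain at least one game")
    rows = []
    for s, block in enumerate(blocks, start=1):
        rows.append(
            {
                "session": s,
                "n_games": len(block),
                "mean_rt_ms": float(np.nanmean([g.mean_rt_ms for g in block])),
                "mean_correct_go": float(np.mean([g.n_correct_go for g in block])),
                "mean_correct_nogo": float(np.mean([g.n_correct_nogo for g in block])),
                "mean_errors": float(np.mean([g.n_errors for g in block])),
                "mean_omissions": float(np.mean([g.n_omissions for g in block])),
                "mean_level": float(np.mean([g.level for g in block])),
            }
        )
    return pd.DataFrame(rows)
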