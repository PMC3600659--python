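"""Two-option probabilistic reversal learning task (PRLT) engine.

The task consists of ``n_phases`` phases of ``trials_per_phase`` trials.
Within each phase one option is "correct": choosing it is rewarded on a
fixed fraction ``p`` of the phase's trials (exact-count scheduling) and
punished on the remainder (false feedback).  The correct option flips at
every phase boundary and nowhere else.  Every feedback event is worth a
fixed number of points, won or lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "OPTIONS",
    "CONTINGENCY_ORDERS",
    "TaskConfig",
    "Schedule",
    "TrialState",
    "ConfigError",
    "ExhaustedScheduleError",
    "build_schedule",
    "play_trial",
]

#: Abstract color tokens for the two response options.
OPTIONS = ("blue", "green")

#: Named per-phase reward-contingency sequences.  The order of
#: contingencies is a balanced between-participant factor.
CONTINGENCY_ORDERS = {
    "easy-late": (0.75, 0.75, 0.875, 0.875),
    "easy-early": (0.875, 0.875, 0.75, 0.75),
}


class ConfigError(ValueError):
    """Invalid task configuration."""


class ExhaustedScheduleError(IndexError):
    """A trial was requested past the end of the schedule."""


@dataclass(frozen=True)
class TaskConfig:
    """Structural parameters of the reversal learning task.

    Parameters
    ----------
    n_phases
        Number of phases; the correct option flips at each boundary.
    trials_per_phase
        Trials per phase; must divide evenly into blocks.
    block_size
        Trials per analysis block.
    contingencies
        Per-phase probability that choosing the correct option is
        rewarded.  Each ``p * trials_per_phase`` must be an integer and
        ``0.5 < p < 1``.
    points_per_feedback
        Points won/lost on every trial.
    """

    n_phases: int = 4
    trials_per_phase: int = 40
    block_size: int = 10
    contingencies: tuple = field(default=CONTINGENCY_ORDERS["easy-late"])
    points_per_feedback: int = 5

    def __post_init__(self) -> None:
        if self.n_phases < 1 or self.trials_per_phase < 1 or self.block_size < 1:
            raise ConfigError("counts must be positive")
        if self.trials_per_phase % self.block_size != 0:
            raise ConfigError(
                f"trials_per_phase={self.trials_per_phase} not divisible by "
                f"block_size={self.block_size}"
            )
        if len(self.contingencies) != self.n_phases:
            raise ConfigError("need one contingency per phase")
        for p in self.contingencies:
            if not (0.5 < p < 1.0):
                raise ConfigError(f"contingency {p} outside (0.5, 1)")
            n_ver = p * self.trials_per_phase
            if abs(n_ver - round(n_ver)) > 1e-9:
                raise ConfigError(
                    f"contingency {p} x {self.trials_per_phase} trials is not "
                    "an integer veridical count"
                )

    @property
    def n_trials(self) -> int:
        return self.n_phases * self.trials_per_phase

    @property
    def n_blocks(self) -> int:
        return self.trials_per_phase // self.block_size


@dataclass
class Schedule:
    """Pre-drawn per-trial task structure.

    Attributes
    ----------
    phase
        1-based phase index per trial.
    correct
        Index into :data:`OPTIONS` of the correct option per trial.
    veridical
        ``True`` where feedback matches choice accuracy; exactly
        ``round(p * trials_per_phase)`` per phase.
    left
        Index of the option displayed on the left (balanced random).
    """

    phase: np.ndarray
    correct: np.ndarray
    veridical: np.ndarray
    left: np.ndarray
    config: TaskConfig

    @property
    def n_trials(self) -> int:
        return len(self.phase)

    def block(self, i: int) -> int:
        """1-based block index of 0-based trial ``i``."""
        within = i % self.config.trials_per_phase
        return within // self.config.block_size + 1


@dataclass(frozen=True)
class TrialState:
    cursor: int = 0
    cumulative_points: int = 0


def build_schedule(config: TaskConfig, seed) -> Schedule:
    """Draw a task schedule: reversal structure, exact-count false
    feedback placement and balanced-random left/right positions.

    Deterministic given ``seed`` (anything accepted by
    :func:`numpy.random.default_rng`).
    """
    rng = np.random.default_rng(seed)
    T = config.trials_per_phase
    phase = np.repeat(np.arange(1, config.n_phases + 1), T)

    first = int(rng.integers(2))
    correct = np.repeat((first + np.arange(config.n_phases)) % 2, T)

    veridical = np.empty(config.n_trials, dtype=bool)
    left = np.empty(config.n_trials, dtype=np.int64)
    for k, p in enumerate(config.contingencies):
        n_ver = round(p * T)
        v = np.zeros(T, dtype=bool)
        v[:n_ver] = True
        rng.shuffle(v)
        veridical[k * T : (k + 1) * T] = v
        # balanced left/right: option 0 on the left on exactly half the
        # trials (rounded down when T is odd)
        pos = np.ones(T, dtype=np.int64)
        pos[: T // 2] = 0
        rng.shuffle(pos)
        left[k * T : (k + 1) * T] = pos

    return Schedule(phase=phase, correct=correct, veridical=veridical,
                    left=left, config=config)


def play_trial(schedule: Schedule, state: TrialState, choice: int):
    """Resolve one trial.

    Returns ``(feedback_points, new_state)`` where feedback is
    ``+points_per_feedback`` iff the choice's accuracy matches the
    trial's veridical flag (accurate & veridical, or inaccurate & false),
    else negative.
    """
    i = state.cursor
    if i >= schedule.n_trials:
        raise ExhaustedScheduleError(f"trial {i} past end of schedule")
    accurate = choice == schedule.correct[i]
    positive = accurate == schedule.veridical[i]
    pts = schedule.config.points_per_feedback
    feedback = pts if positive else -pts
    new_state = replace(state, cursor=i + 1,
                        cumulative_points=state.cumulative_points + feedback)
    return feedback, new_state
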