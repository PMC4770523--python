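"""Stage/score state machine for the Transtheoretical Model (TTM) of behavior change.

Agents occupy one of four ordered stages of readiness to complete an advance
care plan — pre-contemplation, contemplation, preparation, action-maintenance —
and carry an integer propensity score on a 0–100 scale within their current
stage.  Positive experiences (life events, upward social influence) add points;
negative social influence subtracts them.  Crossing the entry threshold of the
next stage advances the agent and resets its score to the destination stage's
baseline; a score pushed below zero marks the agent for a single backslide to
the previous stage.

Advancement chains: after moving up, the new stage is immediately re-evaluated
against the next threshold, so a single large gain (or a favorable baseline)
can carry an agent through several stages in one evaluation.  Backsliding never
chains: at most one stage down per evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import IntEnum
from typing import Literal

import numpy as np

SCORE_MIN = 0
SCORE_MAX = 100


class Stage(IntEnum):
    """Ordered TTM stages; action and maintenance are merged into one stage."""

    PRE_CONTEMPLATION = 0
    CONTEMPLATION = 1
    PREPARATION = 2
    ACTION_MAINTENANCE = 3


N_STAGES = 4

GapScaling = Literal["flat", "linear"]


@dataclass(frozen=True)
class StageState:
    """An agent's stage plus within-stage propensity score.

    ``backslide_pending`` is set by :func:`apply_delta` when accumulated
    negative points would push the score below zero; it is consumed (and
    cleared) by the next call to :func:`evaluate_transitions`.
    """

    stage: Stage
    score: int
    backslide_pending: bool = False

    def __post_init__(self) -> None:
        if not SCORE_MIN <= self.score <= SCORE_MAX:
            raise ValueError(f"score {self.score} outside [0, 100]")


@dataclass(frozen=True)
class ThresholdSchedule:
    """Points required to ENTER each stage from the stage directly below."""

    enter_contemplation: int
    enter_preparation: int
    enter_action: int

    def __post_init__(self) -> None:
        for name in ("enter_contemplation", "enter_preparation", "enter_action"):
            v = getattr(self, name)
            if not SCORE_MIN <= v <= SCORE_MAX:
                raise ValueError(f"{name}={v} outside [0, 100]")

    def entry_threshold(self, stage: Stage | int) -> int:
        """Threshold to enter ``stage`` (undefined for pre-contemplation)."""
        return (
            self.enter_contemplation,
            self.enter_preparation,
            self.enter_action,
        )[int(stage) - 1]

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.enter_contemplation, self.enter_preparation, self.enter_action],
            dtype=np.int64,
        )


@dataclass(frozen=True)
class BaselineSchedule:
    """Score an agent holds on initialization in, or transition into, a stage."""

    pre_contemplation: int
    contemplation: int
    preparation: int
    action_maintenance: int

    def __post_init__(self) -> None:
        for s, v in zip(Stage, self.as_tuple()):
            if not SCORE_MIN <= v <= SCORE_MAX:
                raise ValueError(f"baseline for {s.name} = {v} outside [0, 100]")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (
            self.pre_contemplation,
            self.contemplation,
            self.preparation,
            self.action_maintenance,
        )

    def baseline(self, stage: Stage | int) -> int:
        return self.as_tuple()[int(stage)]

    def as_array(self) -> np.ndarray:
        return np.array(self.as_tuple(), dtype=np.int64)


@dataclass(frozen=True)
class PointSchedule:
    """Point awards for life events and social interactions.

    ``pts_social_down`` is a magnitude: the higher-stage partner in an
    interaction LOSES that many points (times the stage gap under linear
    scaling).  ``gap_scaling`` selects whether social awards are multiplied by
    the stage gap ("linear", the default: larger disparities exert larger
    influence) or applied as-is ("flat").
    """

    pts_icu: int
    pts_loved: int
    pts_pcp: int
    pts_social_up: int
    pts_social_down: int
    gap_scaling: GapScaling = "linear"

    def __post_init__(self) -> None:
        for name in ("pts_icu", "pts_loved", "pts_pcp", "pts_social_up", "pts_social_down"):
            v = getattr(self, name)
            if not 0 <= v <= 10:
                raise ValueError(f"{name}={v} outside [0, 10]")
        if self.gap_scaling not in ("flat", "linear"):
            raise ValueError(f"gap_scaling must be 'flat' or 'linear', got {self.gap_scaling!r}")


def apply_delta(state: StageState, delta: int) -> StageState:
    """Add ``delta`` points to the score, clamped to [0, 100].

    The stage is never changed here.  If the raw sum would fall below zero the
    returned state carries the backslide-pending mark; an already-pending mark
    persists regardless of the sign of ``delta``.
    """
    raw = state.score + int(delta)
    pending = state.backslide_pending or raw < SCORE_MIN
    clamped = min(max(raw, SCORE_MIN), SCORE_MAX)
    return replace(state, score=clamped, backslide_pending=pending)


def evaluate_transitions(
    state: StageState,
    thresholds: ThresholdSchedule,
    baselines: BaselineSchedule,
) -> StageState:
    """Resolve a pending backslide or chained advancement for one agent.

    A pending backslide takes precedence: the agent drops one stage (never
    below pre-contemplation), takes the destination baseline, and the mark is
    cleared with no re-advancement in the same call.  Otherwise the agent
    advances while its score meets the entry threshold of the next stage,
    taking each destination's baseline in turn; action-maintenance is absorbing
    under positive influence.
    """
    if state.backslide_pending:
        if state.stage > Stage.PRE_CONTEMPLATION:
            new_stage = Stage(int(state.stage) - 1)
            return StageState(new_stage, baselines.baseline(new_stage))
        return StageState(state.stage, state.score)

    stage = int(state.stage)
    score = state.score
    while stage < Stage.ACTION_MAINTENANCE and score >= thresholds.entry_threshold(stage + 1):
        stage += 1
        score = baselines.baseline(stage)
    return StageState(Stage(stage), score)


def apply_deltas_array(
    score: np.ndarray, delta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`apply_delta`: returns (clamped scores, pending mask)."""
    raw = score + delta
    pending = raw < SCORE_MIN
    return np.clip(raw, SCORE_MIN, SCORE_MAX), pending


def evaluate_transitions_array(
    stage: np.ndarray,
    score: np.ndarray,
    pending: np.ndarray,
    touched: np.ndarray,
    thresholds: ThresholdSchedule,
    baselines: BaselineSchedule,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`evaluate_transitions` over a population.

    Only agents with ``touched`` set are evaluated (the tick loop marks an
    agent touched when it received any nonzero point delta).  Returns new
    (stage, score) arrays; inputs are not modified.
    """
    stage = stage.copy()
    score = score.copy()
    thr = thresholds.as_array()
    base = baselines.as_array()

    down = touched & pending & (stage > 0)
    stage[down] -= 1
    score[down] = base[stage[down]]

    can_advance = touched & ~pending
    # chained advancement: at most N_STAGES - 1 rounds
    for _ in range(N_STAGES - 1):
        up = can_advance & (stage < Stage.ACTION_MAINTENANCE) & (score >= thr[np.minimum(stage, 2)])
        if not up.any():
            break
        stage[up] += 1
        score[up] = base[stage[up]]
    return stage, score
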