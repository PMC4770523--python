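"""Published experiment presets, replicate execution, and an exact
Markov-chain validation oracle.

Two presets are shipped:

``sim1``
    The idealized experiment: everyone starts in pre-contemplation, everyone
    is susceptible, agents relocate uniformly at random each day ("random
    networks").  All agents are expected to progress to action-maintenance
    and remain there.

``sim2``
    The population experiment: a generic health-behavior starting
    distribution (40/40/20/0), half the population susceptible, local-network
    movement at 0.15 cells/day.  The end state approaches the stage
    distribution reported for advance care planning in the literature, with
    about half the population in action-maintenance.

Parameter values printed in the source tables are fixed; the free geometry
(grid size and footprint rectangles) was calibrated once and frozen here —
see docs/methods.md for the calibration account.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import ttm
from .engine import ModelParams, Trajectory, run
from .ttm import BaselineSchedule, PointSchedule, StageState, ThresholdSchedule, Stage
from .world import PatchKind, World

#: Stage distribution (percent) reported for ACP in the survey literature;
#: a comparison target, not a model output.
EXPECTED_STAGE_DISTRIBUTION = (40.0, 10.0, 3.0, 47.0)

_SIM1_WORLD = {
    "grid": {"width": 33, "height": 33},
    "patches": {
        "loved_one": {"anchor": (2, 2), "width": 16, "height": 16},
        "icu": {"anchor": (24, 23), "width": 8, "height": 8},
        "primary_care": {"anchor": (24, 13), "width": 8, "height": 8},
    },
}

_SIM2_WORLD = {
    "grid": {"width": 50, "height": 50},
    "patches": {
        "loved_one": {"anchor": (0, 0), "width": 49, "height": 49},
        "icu": {"anchor": (49, 45), "width": 1, "height": 3},
        "primary_care": {"anchor": (49, 0), "width": 1, "height": 2},
    },
}


def _sim1_params() -> ModelParams:
    return ModelParams(
        thresholds=ThresholdSchedule(60, 20, 100),
        baselines=BaselineSchedule(0, 0, 0, 0),
        points=PointSchedule(pts_icu=4, pts_loved=3, pts_pcp=1, pts_social_up=3, pts_social_down=1),
        p_icu=33.0,
        p_loved=67.0,
        p_pcp=10.0,
        susceptibility_percent=100.0,
        initial_distribution=(100.0, 0.0, 0.0, 0.0),
        movement_mode="teleport",
        ticks=1825,
        n_agents=200,
        world_config=_SIM1_WORLD,
    )


def _sim2_params() -> ModelParams:
    return ModelParams(
        thresholds=ThresholdSchedule(100, 50, 100),
        baselines=BaselineSchedule(100, 50, 0, 50),
        points=PointSchedule(pts_icu=6, pts_loved=4, pts_pcp=1, pts_social_up=2, pts_social_down=2),
        p_icu=33.0,
        p_loved=67.0,
        p_pcp=10.0,
        susceptibility_percent=50.0,
        initial_distribution=(40.0, 40.0, 20.0, 0.0),
        movement_mode="local",
        movement_rate=0.15,
        ticks=1825,
        n_agents=200,
        world_config=_SIM2_WORLD,
    )


_PRESETS = {"sim1": _sim1_params, "sim2": _sim2_params}


class UnknownPresetError(KeyError):
    pass


def preset(name: str) -> ModelParams:
    """Return a fresh :class:`ModelParams` for a named preset."""
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise UnknownPresetError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
    return factory()


def preset_names() -> list[str]:
    return sorted(_PRESETS)


@dataclass(frozen=True)
class OutcomeSummary:
    """Replicate-aggregated final stage percentages with the reference vector."""

    n_reps: int
    mean: np.ndarray  # per-stage mean final percentage, shape (4,)
    sd: np.ndarray  # per-stage standard deviation (ddof=1; 0 when n_reps == 1)
    per_replicate: np.ndarray  # shape (n_reps, 4)
    expected: tuple[float, float, float, float] = EXPECTED_STAGE_DISTRIBUTION

    def to_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "per_stage": {
                name: {"mean": float(m), "sd": float(s)}
                for name, m, s in zip(
                    ("pre_contemplation", "contemplation", "preparation", "action_maintenance"),
                    self.mean,
                    self.sd,
                )
            },
            "expected": list(self.expected),
            "mean_abs_dev": compare_to_expected(self.mean, self.expected),
        }


def run_replicates(
    params: ModelParams, n_reps: int, base_seed: int
) -> tuple[OutcomeSummary, list[Trajectory]]:
    """Run ``n_reps`` independent replicates (replicate r uses seed base_seed + r)
    and aggregate final stage percentages."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    finals = np.empty((n_reps, ttm.N_STAGES), dtype=float)
    trajectories: list[Trajectory] = []
    for r in range(n_reps):
        traj, _ = run(params, base_seed + r)
        finals[r] = traj.final_percentages()
        trajectories.append(traj)
    sd = finals.std(axis=0, ddof=1) if n_reps > 1 else np.zeros(ttm.N_STAGES)
    return (
        OutcomeSummary(n_reps=n_reps, mean=finals.mean(axis=0), sd=sd, per_replicate=finals),
        trajectories,
    )


def compare_to_expected(
    observed: Sequence[float], expected: Sequence[float] = EXPECTED_STAGE_DISTRIBUTION
) -> float:
    """Mean absolute percentage-point deviation between two stage vectors.

    Stage order matters: element i of ``observed`` is compared with element i
    of ``expected``.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != (ttm.N_STAGES,) or exp.shape != (ttm.N_STAGES,):
        raise ValueError("observed and expected must be 4-vectors")
    return float(np.abs(obs - exp).mean())


class OraclePreconditionError(ValueError):
    """The Markov oracle requires teleport movement, social influence off,
    and annual relapse off."""


def markov_oracle(params: ModelParams, ticks: int | None = None) -> np.ndarray:
    """Exact per-tick stage distribution for the social-free teleport model.

    With teleport movement every agent's cell is uniform and independent each
    tick, so a susceptible agent is a Markov chain on (stage, score): per tick
    it occupies patch k with probability area_k / (W*H) and is awarded that
    patch's points with probability p_k / 100, after which the exact
    stage-machine rules apply.  The chain marginal is mixed with the frozen
    non-susceptible mass.  Returns an array of shape (ticks + 1, 4) whose rows
    are exact stage-occupancy probabilities (row 0 = initial distribution).
    """
    if params.movement_mode != "teleport" or params.social_enabled or params.annual_relapse:
        raise OraclePreconditionError(
            "markov_oracle requires movement_mode='teleport', social_enabled=False, "
            "annual_relapse=False"
        )
    ticks = params.ticks if ticks is None else ticks
    world = params.build_world()
    n_scores = ttm.SCORE_MAX + 1
    n_states = ttm.N_STAGES * n_scores

    def idx(stage: int, score: int) -> int:
        return stage * n_scores + score

    # per-tick outcome weights: award from patch k, or nothing
    p_pct = {PatchKind.ICU: params.p_icu, PatchKind.LOVED_ONE: params.p_loved,
             PatchKind.PRIMARY_CARE: params.p_pcp}
    pts = {PatchKind.ICU: params.points.pts_icu, PatchKind.LOVED_ONE: params.points.pts_loved,
           PatchKind.PRIMARY_CARE: params.points.pts_pcp}
    outcomes: list[tuple[float, int]] = []  # (probability, delta)
    total = 0.0
    for fp in world.footprints:
        w = (fp.area / world.n_cells) * (p_pct[fp.kind] / 100.0)
        if w > 0:
            outcomes.append((w, pts[fp.kind]))
            total += w
    outcomes.append((1.0 - total, 0))

    # next-state index per (outcome, state), via the exact scalar rules
    next_idx = np.empty((len(outcomes), n_states), dtype=np.int64)
    for o, (_, delta) in enumerate(outcomes):
        for s in range(ttm.N_STAGES):
            for sc in range(n_scores):
                st = StageState(Stage(s), sc)
                if delta != 0:
                    st = ttm.apply_delta(st, delta)
                    st = ttm.evaluate_transitions(st, params.thresholds, params.baselines)
                next_idx[o, idx(s, sc)] = idx(int(st.stage), st.score)

    # initial distribution of the susceptible chain
    dist = np.zeros(n_states)
    base = params.baselines.as_tuple()
    for s, frac in enumerate(params.initial_distribution):
        dist[idx(s, base[s])] += frac / 100.0

    init_stage_frac = np.asarray(params.initial_distribution, dtype=float) / 100.0
    s_frac = params.susceptibility_percent / 100.0
    weights = np.array([w for w, _ in outcomes])

    out = np.empty((ticks + 1, ttm.N_STAGES))
    stage_of_state = np.repeat(np.arange(ttm.N_STAGES), n_scores)

    def record(t: int) -> None:
        marg = np.bincount(stage_of_state, weights=dist, minlength=ttm.N_STAGES)
        out[t] = s_frac * marg + (1.0 - s_frac) * init_stage_frac

    record(0)
    for t in range(1, ticks + 1):
        new = np.zeros(n_states)
        for o in range(len(outcomes)):
            np.add.at(new, next_idx[o], weights[o] * dist)
        dist = new
        record(t)
    return out
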