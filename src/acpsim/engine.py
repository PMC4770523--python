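"""Seeded tick loop binding movement, patch events, social influence, and
stage-transition evaluation.

Each tick represents one day.  The within-tick phase order is fixed for
reproducibility: (1) snapshot stages, (2) move every agent, (3) patch events,
(4) social influence computed from the snapshot, (5) transition evaluation for
every agent that received points, (6) record stage counts.  All randomness
flows from a single ``numpy.random.Generator``, with a fixed draw schedule, so
identical (params, seed) yield bit-identical trajectories.

Susceptibility gates every influencing factor: non-susceptible agents receive
neither patch points nor social points, and with the annual-relapse switch off
their (stage, score) is frozen for the whole run.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from . import social, ttm
from .ttm import (
    BaselineSchedule,
    PointSchedule,
    Stage,
    StageState,
    ThresholdSchedule,
)
from .world import PatchKind, Position, World, build_world

STAGE_COLUMNS = ("pre_contemplation", "contemplation", "preparation", "action_maintenance")


@dataclass(frozen=True)
class AgentState:
    """One agent: stage/score state, immutable susceptibility trait, position."""

    agent_id: int
    state: StageState
    susceptible: bool
    position: Position


@dataclass
class ModelParams:
    """All model quantities in one validated record.

    Effect probabilities are percent chances (0–100) that landing on the
    corresponding patch awards its points.  ``initial_distribution`` gives the
    starting stage percentages (must sum to 100).  ``world_config`` carries the
    grid geometry (see :data:`acpsim.world.DEFAULT_LAYOUT`); the effect
    probabilities given here are injected into the footprints when the world
    is built.
    """

    thresholds: ThresholdSchedule
    baselines: BaselineSchedule
    points: PointSchedule
    p_icu: float
    p_loved: float
    p_pcp: float
    susceptibility_percent: float
    initial_distribution: tuple[float, float, float, float]
    movement_mode: Literal["teleport", "local"] = "teleport"
    movement_rate: float = 0.15
    ticks: int = 1825
    n_agents: int = 200
    world_config: dict | None = None
    social_enabled: bool = True
    annual_relapse: bool = False
    p_skip_update: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_icu", "p_loved", "p_pcp", "susceptibility_percent"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")
        dist = tuple(float(p) for p in self.initial_distribution)
        if len(dist) != 4 or any(p < 0 or p > 100 for p in dist):
            raise ValueError("initial_distribution needs four percentages in [0, 100]")
        if abs(sum(dist) - 100.0) > 1e-9:
            raise ValueError(f"initial_distribution sums to {sum(dist)}, expected 100")
        self.initial_distribution = dist
        if self.movement_mode not in ("teleport", "local"):
            raise ValueError(f"movement_mode must be 'teleport' or 'local', got {self.movement_mode!r}")
        if self.movement_mode == "local" and self.movement_rate <= 0:
            raise ValueError("movement_rate must be positive for local movement")
        if self.ticks < 0:
            raise ValueError("ticks must be >= 0")
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if not 0.0 <= self.p_skip_update <= 1.0:
            raise ValueError("p_skip_update must be in [0, 1]")

    def build_world(self) -> World:
        cfg = copy.deepcopy(self.world_config) if self.world_config is not None else None
        if cfg is not None:
            probs = {"icu": self.p_icu, "loved_one": self.p_loved, "primary_care": self.p_pcp}
            for key, patch in cfg.get("patches", {}).items():
                patch.setdefault("effect_probability", probs.get(key, 0.0))
            return build_world(cfg)
        w = build_world(None)  # spec'd default layout
        return w


@dataclass
class Population:
    """Struct-of-arrays population state (one row per agent, identifier order)."""

    stage: np.ndarray  # int64, values in {0..3}
    score: np.ndarray  # int64, values in [0, 100]
    susceptible: np.ndarray  # bool
    x: np.ndarray  # float64 in [0, W)
    y: np.ndarray  # float64 in [0, H)

    @property
    def n(self) -> int:
        return self.stage.shape[0]

    def stage_counts(self) -> np.ndarray:
        return np.bincount(self.stage, minlength=ttm.N_STAGES)

    def as_agent_states(self) -> list[AgentState]:
        return [
            AgentState(
                agent_id=i,
                state=StageState(Stage(int(self.stage[i])), int(self.score[i])),
                susceptible=bool(self.susceptible[i]),
                position=Position(float(self.x[i]), float(self.y[i])),
            )
            for i in range(self.n)
        ]

    def copy(self) -> "Population":
        return Population(
            self.stage.copy(), self.score.copy(), self.susceptible.copy(),
            self.x.copy(), self.y.copy(),
        )


@dataclass
class Trajectory:
    """Per-tick stage counts (row 0 is the initial state) and final summary."""

    counts: np.ndarray  # shape (ticks + 1, 4), int64
    n_agents: int

    @property
    def ticks(self) -> int:
        return self.counts.shape[0] - 1

    def final_percentages(self) -> np.ndarray:
        return 100.0 * self.counts[-1] / self.n_agents

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(STAGE_COLUMNS))
        df.insert(0, "tick", np.arange(self.counts.shape[0]))
        return df

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        counts = df[list(STAGE_COLUMNS)].to_numpy(dtype=np.int64)
        return cls(counts=counts, n_agents=int(counts[0].sum()))


def apportion_largest_remainder(n: int, percentages: tuple[float, ...]) -> np.ndarray:
    """Integer stage counts summing to ``n`` by largest-remainder apportionment.

    Ties in the fractional remainders are broken toward the lower stage index,
    deterministically.
    """
    quotas = np.asarray(percentages, dtype=float) * n / 100.0
    counts = np.floor(quotas).astype(np.int64)
    short = n - int(counts.sum())
    if short > 0:
        remainders = quotas - counts
        order = np.argsort(-remainders, kind="stable")
        counts[order[:short]] += 1
    return counts


def init_population(params: ModelParams, rng: np.random.Generator, world: World | None = None) -> Population:
    """Initial population: apportioned stages, baseline scores, Bernoulli
    susceptibility, uniform positions.  No transition evaluation occurs at
    initialization (no agent has yet received points)."""
    world = world if world is not None else params.build_world()
    n = params.n_agents
    counts = apportion_largest_remainder(n, params.initial_distribution)
    stage = np.repeat(np.arange(ttm.N_STAGES, dtype=np.int64), counts)
    score = params.baselines.as_array()[stage]
    susceptible = rng.random(n) < params.susceptibility_percent / 100.0
    x = rng.uniform(0.0, world.width, n)
    y = rng.uniform(0.0, world.height, n)
    return Population(stage=stage, score=score, susceptible=susceptible, x=x, y=y)


def _cells(pop: Population, world: World) -> tuple[np.ndarray, np.ndarray]:
    cx = np.floor(pop.x).astype(np.int64) % world.width
    cy = np.floor(pop.y).astype(np.int64) % world.height
    return cx, cy


_PATCH_POINTS = {
    PatchKind.ICU: "pts_icu",
    PatchKind.LOVED_ONE: "pts_loved",
    PatchKind.PRIMARY_CARE: "pts_pcp",
}


def step(
    pop: Population,
    world: World,
    params: ModelParams,
    rng: np.random.Generator,
    tick: int = 1,
) -> Population:
    """Advance the population by one tick, in place; returns ``pop``.

    ``tick`` is the 1-based index of the tick being executed (used only by the
    optional annual-relapse check).
    """
    n = pop.n
    snapshot = pop.stage.copy()

    # (2) movement — fixed RNG draw schedule per mode
    if params.movement_mode == "teleport":
        pop.x = rng.uniform(0.0, world.width, n)
        pop.y = rng.uniform(0.0, world.height, n)
    else:
        theta = rng.uniform(0.0, 2.0 * np.pi, n)
        pop.x = (pop.x + params.movement_rate * np.cos(theta)) % world.width
        pop.y = (pop.y + params.movement_rate * np.sin(theta)) % world.height
    cx, cy = _cells(pop, world)

    # (3) patch events: probabilistic award, susceptible agents only
    kind = world.kinds_at_cells(cx, cy)
    p_by_kind = np.array([params.p_icu, params.p_loved, params.p_pcp]) / 100.0
    pts_by_kind = np.array(
        [getattr(params.points, _PATCH_POINTS[k]) for k in PatchKind], dtype=np.int64
    )
    u = rng.random(n)
    on_patch = kind >= 0
    k_safe = np.maximum(kind, 0)
    award = on_patch & pop.susceptible & (u < p_by_kind[k_safe])
    delta = np.where(award, pts_by_kind[k_safe], 0).astype(np.int64)

    # (4) social influence from the start-of-tick stage snapshot
    if params.social_enabled:
        cell_ids = cx * world.height + cy
        delta += social.accumulate_influence(
            snapshot, pop.susceptible, cell_ids, params.points, world.n_cells
        )

    # optional annual ACP-update relapse (off by default): susceptible
    # action-maintenance agents who skip their yearly update drop to preparation
    forced_relapse = np.zeros(n, dtype=bool)
    if params.annual_relapse and tick > 0 and tick % 365 == 0:
        r = rng.random(n)
        forced_relapse = (
            pop.susceptible
            & (pop.stage == Stage.ACTION_MAINTENANCE)
            & (r < params.p_skip_update)
        )

    # (5) apply net delta once (single clamp; order-independent) and evaluate
    new_score, pending = ttm.apply_deltas_array(pop.score, delta)
    pending |= forced_relapse
    touched = (delta != 0) | forced_relapse
    pop.stage, pop.score = ttm.evaluate_transitions_array(
        pop.stage, new_score, pending, touched, params.thresholds, params.baselines
    )
    return pop


def run(params: ModelParams, seed: int | np.random.Generator) -> tuple[Trajectory, Population]:
    """Run ``params.ticks`` ticks from a fresh population; returns the
    trajectory (initial state included) and the final population."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    world = params.build_world()
    pop = init_population(params, rng, world)
    counts = np.empty((params.ticks + 1, ttm.N_STAGES), dtype=np.int64)
    counts[0] = pop.stage_counts()
    for t in range(1, params.ticks + 1):
        step(pop, world, params, rng, tick=t)
        counts[t] = pop.stage_counts()
    return Trajectory(counts=counts, n_agents=params.n_agents), pop
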