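"""Same-cell social influence between agents.

Agents sharing a grid cell "talk" about advance care planning.  The partner in
the higher TTM stage pulls the lower-stage partner upward (positive points);
the lower-stage partner drags the higher one downward (negative points, the
sole backsliding channel).  Two gates apply per receiving agent: only
susceptible agents receive outcomes, and pre-contemplation agents are immune
to upward influence (they have never considered the behavior, so others'
stages do not move them).  Under linear gap scaling the award is multiplied by
the stage disparity, so larger gaps exert larger influence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .ttm import N_STAGES, PointSchedule, Stage


@dataclass(frozen=True)
class InteractionOutcome:
    """A signed point delta attributed to one agent by one interaction."""

    agent: int
    delta: int
    cause: Literal["social_up", "social_down"]

    def __post_init__(self) -> None:
        if self.cause == "social_up" and self.delta < 0:
            raise ValueError("social_up outcomes must be non-negative")
        if self.cause == "social_down" and self.delta > 0:
            raise ValueError("social_down outcomes must be non-positive")


def find_pairs(cells: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """All unordered pairs of agents occupying the same cell.

    ``cells`` maps agent index -> occupied cell.  Each co-located unordered
    pair appears exactly once, ordered (i, j) with i < j; no self-pairs.
    """
    by_cell: dict[tuple[int, int], list[int]] = {}
    for idx, cell in enumerate(cells):
        by_cell.setdefault(cell, []).append(idx)
    pairs: list[tuple[int, int]] = []
    for members in by_cell.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                pairs.append((members[a], members[b]))
    return pairs


def influence(
    pair: tuple[int, int],
    stages: Sequence[int],
    points: PointSchedule,
    susceptible: Sequence[bool],
) -> list[InteractionOutcome]:
    """Outcomes of one interaction, from a start-of-tick stage snapshot.

    Equal stages produce nothing.  Otherwise the lower-stage agent gains
    ``pts_social_up`` and the higher-stage agent loses ``pts_social_down``
    (each times the stage gap under linear scaling); an outcome is emitted
    only for susceptible receivers, and the lower-stage agent's gain is
    suppressed when it is in pre-contemplation.
    """
    i, j = pair
    si, sj = int(stages[i]), int(stages[j])
    if si == sj:
        return []
    lo, hi = (i, j) if si < sj else (j, i)
    gap = abs(si - sj)
    m = gap if points.gap_scaling == "linear" else 1
    outcomes: list[InteractionOutcome] = []
    if susceptible[lo] and int(stages[lo]) != Stage.PRE_CONTEMPLATION:
        outcomes.append(InteractionOutcome(lo, points.pts_social_up * m, "social_up"))
    if susceptible[hi]:
        outcomes.append(InteractionOutcome(hi, -points.pts_social_down * m, "social_down"))
    return outcomes


def influence_matrix(points: PointSchedule) -> np.ndarray:
    """Per-interaction delta G[own_stage, partner_stage] for a susceptible receiver.

    Row 0 (pre-contemplation) has its upward entries zeroed (immunity).  The
    net social delta of agent i on a cell is then sum over co-located partners
    j of G[stage_i, stage_j], which the engine computes from per-cell stage
    counts in O(N).
    """
    g = np.zeros((N_STAGES, N_STAGES), dtype=np.int64)
    for own in range(N_STAGES):
        for other in range(N_STAGES):
            gap = abs(other - own)
            if gap == 0:
                continue
            m = gap if points.gap_scaling == "linear" else 1
            if other > own:
                g[own, other] = points.pts_social_up * m
            else:
                g[own, other] = -points.pts_social_down * m
    g[Stage.PRE_CONTEMPLATION, :] = np.minimum(g[Stage.PRE_CONTEMPLATION, :], 0)
    return g


def accumulate_influence(
    stages: np.ndarray,
    susceptible: np.ndarray,
    cell_ids: np.ndarray,
    points: PointSchedule,
    n_cells: int,
) -> np.ndarray:
    """Net social point delta per agent for one tick (vectorized).

    ``cell_ids`` are flattened cell indices in [0, n_cells).  Equivalent to
    summing :func:`influence` over :func:`find_pairs` (property-tested), but
    linear in the number of agents.
    """
    n = stages.shape[0]
    counts = np.zeros((n_cells, N_STAGES), dtype=np.int64)
    np.add.at(counts, (cell_ids, stages), 1)
    g = influence_matrix(points)
    # partner counts on own cell; G[s, s] == 0 so subtracting self is unneeded
    delta = np.einsum("ns,ns->n", g[stages], counts[cell_ids].astype(np.int64))
    delta = np.where(susceptible, delta, 0)
    return delta
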