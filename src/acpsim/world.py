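"""Toroidal grid world with rectangular event-patch footprints and movement.

Three kinds of experience patch can exist: a personal ICU stay (small but high
impact), a loved one's critical illness or death (larger, lower impact), and a
primary-care visit (placed near the ICU patch, reflecting post-ICU follow-up
care).  An agent occupying a footprint cell may probabilistically gain that
patch's points.

Two movement regimes are supported: global random relocation ("random
networks": a fresh uniform position every tick) and a local random walk
("local networks": a fixed-length step in a uniformly random direction, which
keeps an agent's social surroundings comparatively stable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np


class PatchKind(IntEnum):
    ICU = 0
    LOVED_ONE = 1
    PRIMARY_CARE = 2


class WorldError(ValueError):
    """Raised for invalid world geometry (overlap, placement, bounds)."""


@dataclass(frozen=True)
class PatchFootprint:
    """A rectangle of cells anchored at (column, row), with an effect probability.

    ``effect_probability`` is the percent chance (0–100) that an occupying
    agent gains the patch's points on a given tick.
    """

    kind: PatchKind
    anchor: tuple[int, int]
    width: int
    height: int
    effect_probability: float

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise WorldError(f"{self.kind.name}: footprint must be at least 1x1")
        if not 0.0 <= self.effect_probability <= 100.0:
            raise WorldError(
                f"{self.kind.name}: effect_probability {self.effect_probability} outside [0, 100]"
            )

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (self.anchor[0] + self.width / 2.0, self.anchor[1] + self.height / 2.0)

    def cells(self) -> set[tuple[int, int]]:
        c0, r0 = self.anchor
        return {(c, r) for c in range(c0, c0 + self.width) for r in range(r0, r0 + self.height)}


@dataclass(frozen=True)
class Position:
    """Continuous coordinates on the torus; the occupied cell is the floor."""

    x: float
    y: float

    @property
    def cell(self) -> tuple[int, int]:
        return (int(math.floor(self.x)), int(math.floor(self.y)))


def _torus_distance(a: tuple[float, float], b: tuple[float, float], w: int, h: int) -> float:
    dx = abs(a[0] - b[0])
    dy = abs(a[1] - b[1])
    dx = min(dx, w - dx)
    dy = min(dy, h - dy)
    return math.hypot(dx, dy)


@dataclass(frozen=True)
class World:
    """Toroidal grid of ``width`` x ``height`` cells with disjoint patch footprints."""

    width: int
    height: int
    footprints: tuple[PatchFootprint, ...]
    # cell -> patch kind lookup, -1 for empty; built in __post_init__
    kind_grid: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise WorldError("grid must be at least 1x1")
        kinds = [f.kind for f in self.footprints]
        if len(set(kinds)) != len(kinds):
            raise WorldError("at most one footprint per patch kind")

        grid = np.full((self.width, self.height), -1, dtype=np.int8)
        for f in self.footprints:
            c0, r0 = f.anchor
            if c0 < 0 or r0 < 0 or c0 + f.width > self.width or r0 + f.height > self.height:
                raise WorldError(f"{f.kind.name}: footprint extends outside the grid")
            block = grid[c0 : c0 + f.width, r0 : r0 + f.height]
            if (block != -1).any():
                raise WorldError(f"{f.kind.name}: footprint overlaps another patch")
            block[:] = int(f.kind)

        by_kind = {f.kind: f for f in self.footprints}
        icu = by_kind.get(PatchKind.ICU)
        loved = by_kind.get(PatchKind.LOVED_ONE)
        pcp = by_kind.get(PatchKind.PRIMARY_CARE)
        if icu is not None and loved is not None and not icu.area < loved.area:
            raise WorldError(
                f"ICU footprint ({icu.area} cells) must be smaller than "
                f"LOVED_ONE footprint ({loved.area} cells)"
            )
        if icu is not None and loved is not None and pcp is not None:
            d_icu = _torus_distance(pcp.center, icu.center, self.width, self.height)
            d_loved = _torus_distance(pcp.center, loved.center, self.width, self.height)
            if not d_icu < d_loved:
                raise WorldError(
                    "PRIMARY_CARE patch must be placed nearer to ICU "
                    f"({d_icu:.2f}) than to LOVED_ONE ({d_loved:.2f})"
                )
        object.__setattr__(self, "kind_grid", grid)

    @property
    def n_cells(self) -> int:
        return self.width * self.height

    def footprint(self, kind: PatchKind) -> PatchFootprint | None:
        for f in self.footprints:
            if f.kind == kind:
                return f
        return None

    def effect_probabilities(self) -> np.ndarray:
        """Per-kind effect probability (percent), indexed by PatchKind; 0 if absent."""
        p = np.zeros(len(PatchKind), dtype=float)
        for f in self.footprints:
            p[int(f.kind)] = f.effect_probability
        return p

    def kinds_at_cells(self, cx: np.ndarray, cy: np.ndarray) -> np.ndarray:
        """Vectorized cell -> patch-kind lookup (-1 for empty cells)."""
        return self.kind_grid[cx, cy]


# Spec'd small default layout of the customary 33x33 world; presets use their
# own calibrated geometry (see acpsim.experiments).
DEFAULT_LAYOUT: dict = {
    "grid": {"width": 33, "height": 33},
    "patches": {
        "icu": {"anchor": (24, 16), "width": 1, "height": 1, "effect_probability": 33.0},
        "primary_care": {"anchor": (18, 16), "width": 2, "height": 2, "effect_probability": 10.0},
        "loved_one": {"anchor": (6, 16), "width": 3, "height": 3, "effect_probability": 67.0},
    },
}

_KIND_KEYS = {"icu": PatchKind.ICU, "loved_one": PatchKind.LOVED_ONE, "primary_care": PatchKind.PRIMARY_CARE}


def build_world(config: dict | None = None) -> World:
    """Construct a :class:`World` from a config mapping (or the default layout).

    ``config`` has the shape of :data:`DEFAULT_LAYOUT`; any subset of the three
    patch kinds may be present.  Raises :class:`WorldError` for overlapping
    footprints, out-of-bounds footprints, an ICU patch at least as large as the
    loved-one patch, or a primary-care patch placed nearer the loved-one patch
    than the ICU patch.
    """
    cfg = DEFAULT_LAYOUT if config is None or config == "default-layout" else config
    grid = cfg["grid"]
    fps = []
    for key, patch in cfg.get("patches", {}).items():
        if key not in _KIND_KEYS:
            raise WorldError(f"unknown patch kind {key!r}")
        fps.append(
            PatchFootprint(
                kind=_KIND_KEYS[key],
                anchor=tuple(patch["anchor"]),
                width=int(patch["width"]),
                height=int(patch["height"]),
                effect_probability=float(patch["effect_probability"]),
            )
        )
    return World(int(grid["width"]), int(grid["height"]), tuple(fps))


def move_teleport(pos: Position, world: World, rng: np.random.Generator) -> Position:
    """Relocate uniformly at random over the grid area (random networks)."""
    return Position(rng.uniform(0.0, world.width), rng.uniform(0.0, world.height))


def move_local(pos: Position, rate: float, world: World, rng: np.random.Generator) -> Position:
    """Step ``rate`` cell-lengths in a uniformly random direction, wrapping toroidally."""
    if rate <= 0:
        raise ValueError("movement rate must be positive")
    theta = rng.uniform(0.0, 2.0 * math.pi)
    return Position(
        (pos.x + rate * math.cos(theta)) % world.width,
        (pos.y + rate * math.sin(theta)) % world.height,
    )


def events_at(pos: Position, world: World) -> set[PatchKind]:
    """Patch kinds whose footprint contains the occupied cell (0 or 1 kinds)."""
    cx, cy = pos.cell
    k = int(world.kind_grid[cx, cy])
    return set() if k < 0 else {PatchKind(k)}


def move_teleport_array(
    n: int, world: World, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized teleport for ``n`` agents: fresh uniform positions."""
    return rng.uniform(0.0, world.width, n), rng.uniform(0.0, world.height, n)


def move_local_array(
    x: np.ndarray, y: np.ndarray, rate: float, world: World, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized local random walk: one fixed-length step per agent."""
    if rate <= 0:
        raise ValueError("movement rate must be positive")
    theta = rng.uniform(0.0, 2.0 * math.pi, x.shape[0])
    return (x + rate * np.cos(theta)) % world.width, (y + rate * np.sin(theta)) % world.height
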