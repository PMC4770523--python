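"""World geometry, movement regimes, and patch-event lookup."""

import math

import numpy as np
import pytest
from scipy import stats

from acpsim.world import (
    DEFAULT_LAYOUT,
    PatchFootprint,
    PatchKind,
    Position,
    World,
    WorldError,
    build_world,
    events_at,
    move_local,
    move_local_array,
    move_teleport,
)


class TestBuildWorld:
    def test_default_layout_satisfies_invariants(self):
        w = build_world(None)
        assert (w.width, w.height) == (33, 33)
        icu = w.footprint(PatchKind.ICU)
        loved = w.footprint(PatchKind.LOVED_ONE)
        pcp = w.footprint(PatchKind.PRIMARY_CARE)
        assert icu.area < loved.area
        # primary care sits between the ICU and the loved-one patch
        d_icu = math.dist(pcp.center, icu.center)
        d_loved = math.dist(pcp.center, loved.center)
        assert d_icu == pytest.approx(5.5, abs=0.1)
        assert d_loved == pytest.approx(11.5, abs=0.1)
        assert d_icu < d_loved

    def test_icu_larger_than_loved_rejected(self):
        cfg = {
            "grid": {"width": 20, "height": 20},
            "patches": {
                "icu": {"anchor": (0, 0), "width": 3, "height": 3, "effect_probability": 33},
                "loved_one": {"anchor": (10, 10), "width": 1, "height": 1, "effect_probability": 67},
            },
        }
        with pytest.raises(WorldError, match="smaller"):
            build_world(cfg)

    def test_overlapping_footprints_rejected(self):
        cfg = {
            "grid": {"width": 20, "height": 20},
            "patches": {
                "icu": {"anchor": (5, 5), "width": 2, "height": 2, "effect_probability": 33},
                "loved_one": {"anchor": (6, 6), "width": 3, "height": 3, "effect_probability": 67},
            },
        }
        with pytest.raises(WorldError, match="overlap"):
            build_world(cfg)

    def test_primary_care_must_be_nearer_icu(self):
        cfg = {
            "grid": {"width": 30, "height": 30},
            "patches": {
                "icu": {"anchor": (0, 0), "width": 1, "height": 1, "effect_probability": 33},
                "loved_one": {"anchor": (12, 12), "width": 3, "height": 3, "effect_probability": 67},
                "primary_care": {"anchor": (14, 10), "width": 2, "height": 2, "effect_probability": 10},
            },
        }
        with pytest.raises(WorldError, match="nearer"):
            build_world(cfg)

    def test_out_of_bounds_footprint_rejected(self):
        cfg = {
            "grid": {"width": 10, "height": 10},
            "patches": {"icu": {"anchor": (9, 9), "width": 2, "height": 2, "effect_probability": 33}},
        }
        with pytest.raises(WorldError, match="outside"):
            build_world(cfg)

    def test_placement_distance_uses_torus_wrap(self):
        # primary care adjoins the ICU across the seam; flat distance would reject it
        cfg = {
            "grid": {"width": 20, "height": 20},
            "patches": {
                "loved_one": {"anchor": (5, 8), "width": 4, "height": 4, "effect_probability": 67},
                "icu": {"anchor": (19, 18), "width": 1, "height": 2, "effect_probability": 33},
                "primary_care": {"anchor": (19, 0), "width": 1, "height": 2, "effect_probability": 10},
            },
        }
        w = build_world(cfg)
        assert w.footprint(PatchKind.PRIMARY_CARE) is not None

    def test_random_valid_layouts_keep_invariants(self, rng):
        accepted = 0
        for _ in range(200):
            W = int(rng.integers(8, 30))
            cfg = {
                "grid": {"width": W, "height": W},
                "patches": {
                    "icu": {
                        "anchor": (int(rng.integers(0, W)), int(rng.integers(0, W))),
                        "width": int(rng.integers(1, 4)),
                        "height": int(rng.integers(1, 4)),
                        "effect_probability": 33,
                    },
                    "loved_one": {
                        "anchor": (int(rng.integers(0, W)), int(rng.integers(0, W))),
                        "width": int(rng.integers(1, 6)),
                        "height": int(rng.integers(1, 6)),
                        "effect_probability": 67,
                    },
                },
            }
            try:
                w = build_world(cfg)
            except WorldError:
                continue
            accepted += 1
            cells_icu = w.footprint(PatchKind.ICU).cells()
            cells_loved = w.footprint(PatchKind.LOVED_ONE).cells()
            assert not cells_icu & cells_loved
            assert len(cells_icu) < len(cells_loved)
        assert accepted > 10  # the sampler does accept layouts


class TestMovement:
    def test_teleport_uniform_over_cells(self):
        rng = np.random.default_rng(8)
        w = build_world(None)
        n = 100_000
        pos = Position(1.0, 1.0)
        xs = np.empty(n)
        ys = np.empty(n)
        for i in range(n):
            p = move_teleport(pos, w, rng)
            xs[i], ys[i] = p.x, p.y
        assert ((xs >= 0) & (xs < w.width)).all()
        assert ((ys >= 0) & (ys < w.height)).all()
        cells = np.floor(xs).astype(int) * w.height + np.floor(ys).astype(int)
        observed = np.bincount(cells, minlength=w.n_cells)
        res = stats.chisquare(observed)
        assert res.pvalue > 0.01

    def test_teleport_degenerate_world(self, rng):
        w = World(1, 1, ())
        for _ in range(10):
            assert move_teleport(Position(0.5, 0.5), w, rng).cell == (0, 0)

    def test_local_step_length_exact(self):
        w = build_world(None)

        class FixedHeading:
            def __init__(self, theta):
                self.theta = theta

            def uniform(self, lo, hi):
                return self.theta

        start = Position(10.0, 10.0)
        for theta_deg in (0, 45, 90, 225, 300):
            p = move_local(start, 0.15, w, FixedHeading(math.radians(theta_deg)))
            assert math.dist((start.x, start.y), (p.x, p.y)) == pytest.approx(0.15)

    def test_local_wraps_toroidally(self):
        w = build_world(None)

        class FixedHeading:
            def uniform(self, lo, hi):
                return math.radians(225)

        p = move_local(Position(0.05, 0.05), 0.15, w, FixedHeading())
        assert w.width - 1 <= p.x < w.width
        assert w.height - 1 <= p.y < w.height

    def test_local_rejects_nonpositive_rate(self):
        w = build_world(None)
        with pytest.raises(ValueError):
            move_local(Position(1, 1), 0.0, w, np.random.default_rng(0))

    def test_mean_squared_displacement_follows_random_walk_law(self, rng):
        # 2-D fixed-step random walk: E[r^2] after t steps = rate^2 * t
        rate, t, walkers = 0.15, 1000, 4000
        w = World(1000, 1000, ())  # large world: no wrap over this horizon
        x = np.full(walkers, 500.0)
        y = np.full(walkers, 500.0)
        for _ in range(t):
            x, y = move_local_array(x, y, rate, w, rng)
        msd = ((x - 500.0) ** 2 + (y - 500.0) ** 2).mean()
        assert msd == pytest.approx(rate**2 * t, rel=0.10)


class TestEventsAt:
    def test_inside_icu_footprint(self):
        w = build_world(None)
        assert events_at(Position(24.5, 16.5), w) == {PatchKind.ICU}

    def test_empty_cell(self):
        w = build_world(None)
        assert events_at(Position(0.5, 0.5), w) == set()

    def test_at_most_one_kind(self, rng):
        w = build_world(None)
        for _ in range(500):
            pos = Position(rng.uniform(0, w.width), rng.uniform(0, w.height))
            assert len(events_at(pos, w)) <= 1

    def test_loved_one_occupancy_matches_area_ratio(self, rng):
        w = build_world(None)
        n = 100_000
        x = rng.uniform(0, w.width, n)
        y = rng.uniform(0, w.height, n)
        kinds = w.kinds_at_cells(np.floor(x).astype(int), np.floor(y).astype(int))
        hits = int((kinds == int(PatchKind.LOVED_ONE)).sum())
        res = stats.binomtest(hits, n, p=9 / 1089)
        assert res.pvalue > 0.01


def test_footprint_validation():
    with pytest.raises(WorldError):
        PatchFootprint(PatchKind.ICU, (0, 0), 0, 1, 33.0)
    with pytest.raises(WorldError):
        PatchFootprint(PatchKind.ICU, (0, 0), 1, 1, 101.0)
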