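"""Spatial engine: collision detection, motion, membrane, stepping."""

import math

import numpy as np
import pytest

from enzsim.engine import (
    Arena,
    World,
    collisions_all_pairs,
    collisions_indexed,
    specular_reflect,
    step_length,
)
from enzsim.rules import MembraneRule, ReactionRule, Rulebook
from enzsim.units import SpeciesSpec, UnitSystem


def make_world(species, rulebook=None, arena=1.0, seed=0, jitter=0.2):
    units = UnitSystem(
        arena_area=arena,
        distance_unit=min(s.particle_radius for s in species if s.mobile),
    )
    return World(
        species, Arena.square(arena), rulebook or Rulebook(), units, seed, jitter
    )


def place(world, species_name, x, y, heading):
    """Spawn one agent at an exact position (test helper)."""
    sp = world._sp_index[species_name]
    return world._spawn(sp, x, y, heading)


FAST = SpeciesSpec("fast", 100.0, 0.01, 4e-14)
SLOW = SpeciesSpec("slow", 400.0, 0.02, 2e-14)
WALLS = SpeciesSpec("hurdle", 1e4, 0.01, 0.0, role="obstacle")


class TestCollisionDetection:
    def test_overlapping_pair_detected(self):
        pos = np.array([[0.0, 0.0], [1.9, 0.0]])
        radii = np.array([1.0, 1.0])
        assert len(collisions_all_pairs(pos, radii)) == 1
        assert len(collisions_indexed(pos, radii)) == 1

    def test_separated_pair_not_detected(self):
        pos = np.array([[0.0, 0.0], [2.1, 0.0]])
        radii = np.array([1.0, 1.0])
        assert len(collisions_all_pairs(pos, radii)) == 0
        assert len(collisions_indexed(pos, radii)) == 0

    def test_touching_pair_not_detected(self):
        # strict inequality: distance exactly equal to combined radius
        pos = np.array([[0.0, 0.0], [2.0, 0.0]])
        radii = np.array([1.0, 1.0])
        assert len(collisions_all_pairs(pos, radii)) == 0

    @pytest.mark.parametrize("trial", range(25))
    def test_index_equals_all_pairs_oracle(self, trial):
        rng = np.random.default_rng(trial)
        n = rng.integers(2, 200)
        pos = rng.random((n, 2))
        radii = rng.uniform(1e-3, 0.08, size=n)
        a = collisions_all_pairs(pos, radii)
        b = collisions_indexed(pos, radii)
        assert np.array_equal(np.sort(a, axis=0), np.sort(b, axis=0))


class TestMotion:
    def test_step_length_proportional_to_diffusion(self):
        assert step_length(4e-14, 4e-14, 0.01) == 0.01  # fastest: one unit
        assert step_length(2e-14, 4e-14, 0.01) == 0.005  # half speed

    def test_fastest_species_moves_one_distance_unit(self):
        w = make_world([FAST, SLOW])
        i = place(w, "fast", 0.5, 0.5, 0.0)
        w.step()
        assert w._x[i] == pytest.approx(0.5 + w.units.distance_unit)
        assert w._y[i] == pytest.approx(0.5)
        assert w._heading[i] == 0.0  # no collision, heading persists

    def test_slower_species_scales_displacement(self):
        w = make_world([FAST, SLOW])
        i = place(w, "slow", 0.5, 0.5, math.pi / 2)
        w.step()
        assert w._y[i] == pytest.approx(0.5 + w.units.distance_unit / 2)

    def test_obstacles_never_move(self):
        w = make_world([FAST, WALLS])
        i = place(w, "hurdle", 0.3, 0.7, 0.0)
        place(w, "fast", 0.3, 0.7, 0.0)  # overlapping on purpose
        for _ in range(50):
            w.step()
        assert (w._x[i], w._y[i]) == (0.3, 0.7)

    def test_containment_over_many_ticks(self):
        w = make_world([FAST, SLOW, WALLS], seed=3)
        w.add_agents("fast", 150)
        w.add_agents("slow", 100)
        w.add_agents("hurdle", 30, avoid_overlap=True)
        for _ in range(500):
            w.step()
        live = np.flatnonzero(w._alive[: w.n_agents])
        r = w._radius[w._sp[live]]
        assert np.all(w._x[live] >= r - 1e-12)
        assert np.all(w._x[live] <= w.arena.width - r + 1e-12)
        assert np.all(w._y[live] >= r - 1e-12)
        assert np.all(w._y[live] <= w.arena.height_2d - r + 1e-12)


class TestReorientation:
    def test_head_on_wall_reflection(self):
        assert specular_reflect(0.0, (-1.0, 0.0)) == pytest.approx(math.pi)

    def test_mirror_law_on_floor_normal(self):
        out = specular_reflect(math.pi / 4, (0.0, 1.0))
        assert out == pytest.approx(-math.pi / 4 % (2 * math.pi))

    def test_reflection_preserves_speed_direction_only(self):
        # reflecting twice about the same normal restores the heading
        h = 1.234
        n = (0.6, 0.8)
        assert specular_reflect(specular_reflect(h, n), n) == pytest.approx(h)

    def test_collision_jitter_bounded(self):
        # colliding pairs reorient to specular heading +/- jitter
        jit = 0.1
        devs = []
        for seed in range(300):
            w = make_world([FAST, SLOW], seed=seed, jitter=jit)
            i = place(w, "fast", 0.5, 0.5, 0.0)
            place(w, "slow", 0.5 + 0.028, 0.5, math.pi)  # will overlap after move
            w.step()
            # contact normal is along x; specular reflection of heading 0 is pi
            dev = (w._heading[i] - math.pi + math.pi) % (2 * math.pi) - math.pi
            devs.append(dev)
        devs = np.abs(devs)
        assert np.all(devs <= jit + 1e-9)
        assert devs.max() > jit / 2  # jitter actually applied

    def test_overlap_separated_after_reorientation(self):
        w = make_world([FAST, SLOW], seed=1)
        i = place(w, "fast", 0.5, 0.5, 0.0)
        j = place(w, "slow", 0.505, 0.5, math.pi)
        w.step()
        d = math.hypot(w._x[i] - w._x[j], w._y[i] - w._y[j])
        assert d >= (FAST.particle_radius + SLOW.particle_radius) - 1e-12


class TestMembrane:
    def test_default_reflection_keeps_agent_inside(self):
        w = make_world([FAST], jitter=0.0)
        i = place(w, "fast", FAST.particle_radius + 1e-4, 0.5, math.pi)
        w.step()
        assert w._x[i] >= FAST.particle_radius
        assert abs(w._heading[i]) < 1e-9  # pi reflected to 0

    def test_membrane_jitter_bounded(self):
        w = make_world([FAST], jitter=0.15)
        i = place(w, "fast", FAST.particle_radius + 1e-4, 0.5, math.pi)
        w.step()
        dev = (w._heading[i] + math.pi) % (2 * math.pi) - math.pi
        assert abs(dev) <= 0.15 + 1e-12

    def test_reconversion_replaces_species_in_place(self):
        nadh = SpeciesSpec("NADH", 663.43, 0.658e-3, 1.973e-14, role="cofactor")
        nad = SpeciesSpec("NAD+", 661.41, 0.657e-3, 1.975e-14, role="cofactor")
        rb = Rulebook(membrane=(MembraneRule("NADH", "reconvert", "NAD+"),))
        w = make_world([nadh, nad], rb, arena=0.01)
        place(w, "NADH", nadh.particle_radius + 1e-6, 0.05, math.pi)
        w.step()
        assert w.count_of("NADH") == 0
        assert w.count_of("NAD+") == 1

    def test_excretion_removes_and_counts(self):
        benzoate = SpeciesSpec("benzoate", 121.12, 0.338e-3, 3.843e-14)
        rb = Rulebook(membrane=(MembraneRule("benzoate", "excrete"),))
        w = make_world([benzoate], rb, arena=0.01)
        place(w, "benzoate", benzoate.particle_radius + 1e-6, 0.05, math.pi)
        w.step()
        assert w.count_of("benzoate") == 0
        assert w.excreted[w._sp_index["benzoate"]] == 1


class TestStepWorld:
    def test_lone_agent_only_translates(self):
        w = make_world([FAST, SLOW])
        place(w, "fast", 0.5, 0.5, 1.0)
        before = w.species_counts().copy()
        w.step()
        assert np.array_equal(w.species_counts(), before)

    def test_forced_reaction_products_same_tick(self):
        enz = SpeciesSpec("enz", 4e4, 3e-3, 4e-15, role="enzyme")
        sub = SpeciesSpec("sub", 108.0, 0.3e-3, 4e-14)
        prod = SpeciesSpec("prod", 106.0, 0.3e-3, 4e-14)
        rb = Rulebook(
            reactions=(
                ReactionRule("enz", "sub", (("enz", 1), ("prod", 1)), 1.0, 0),
            )
        )
        w = make_world([enz, sub, prod], rb)
        place(w, "enz", 0.5, 0.5, 0.0)
        place(w, "sub", 0.5, 0.5, 0.0)
        w.step()
        assert w.count_of("prod") == 1
        assert w.count_of("enz") == 1
        assert w.count_of("sub") == 0

    def test_determinism_same_seed_identical_trajectories(self):
        def run(seed):
            w = make_world([FAST, SLOW, WALLS], seed=seed)
            w.add_agents("fast", 80)
            w.add_agents("slow", 40)
            w.add_agents("hurdle", 20, avoid_overlap=True)
            w.run(120)
            return w.snapshot_frame()

        a, b, c = run(7), run(7), run(8)
        assert a.equals(b)
        assert not a.equals(c)

    def test_snapshot_frame_columns(self):
        w = make_world([FAST])
        w.add_agents("fast", 5)
        snap = w.snapshot_frame()
        assert list(snap.columns) == ["tick", "agent_id", "species", "x", "y", "heading"]
        assert len(snap) == 5


class TestCrowding:
    def test_obstacles_reduce_reaction_rate(self):
        """Molecular crowding: hurdles block movement, shortening the mean
        free path, so the number of catalytic events over a fixed horizon is
        non-increasing in obstacle count.  Densities are chosen in the
        transport-limited regime (obstacle encounters every few steps) where
        the effect is well above seed noise."""
        enz = SpeciesSpec("enz", 4e4, 3.3e-3, 4e-15, role="enzyme")
        sub = SpeciesSpec("sub", 108.14, 0.323e-3, 4.018e-14)
        prod = SpeciesSpec("prod", 106.1, 0.321e-3, 4.047e-14)
        hurdle = SpeciesSpec("obstacle", 1e4, 0.323e-3, 0.0, role="obstacle")
        rb = Rulebook(
            reactions=(
                ReactionRule("enz", "sub", (("enz", 1), ("prod", 1)), 1.0, 0),
            )
        )
        means = []
        for n_obs in (0, 2500, 5000):
            totals = []
            for seed in range(5):
                w = make_world([enz, sub, prod, hurdle], rb, arena=0.01, seed=seed + 11)
                w.add_agents("enz", 30)
                w.add_agents("sub", 300)
                if n_obs:
                    w.add_agents("obstacle", n_obs, avoid_overlap=True)
                for _ in range(100):
                    w.step()
                totals.append(int(w.reaction_counts.sum()))
            means.append(np.mean(totals))
        assert means[0] >= means[1] >= means[2]
        assert means[0] > 1.2 * means[2]  # strong effect, not a tie
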