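"""Behavioural rulebook: binding, probabilistic catalysis, influx, conservation."""

import math

import numpy as np
import pytest

from enzsim.engine import Arena, World
from enzsim.rules import (
    BindingRule,
    InfluxSchedule,
    MembraneRule,
    ReactionRule,
    RuleError,
    Rulebook,
)
from enzsim.scenario import generate_fixture
from enzsim.units import SpeciesSpec, UnitSystem

ENZ = SpeciesSpec("enz", 4e4, 3.3e-3, 4e-15, role="enzyme")
COF = SpeciesSpec("cof", 661.41, 0.657e-3, 1.975e-14, role="cofactor")
HOLO = SpeciesSpec("holo", 4.07e4, 3.3e-3, 4e-15, role="holoenzyme")
SUB = SpeciesSpec("sub", 108.14, 0.323e-3, 4.018e-14)
PROD = SpeciesSpec("prod", 106.1, 0.321e-3, 4.047e-14)


def make_world(species, rulebook, arena=1.0, seed=0):
    units = UnitSystem(
        arena_area=arena,
        distance_unit=min(s.particle_radius for s in species if s.mobile),
    )
    return World(species, Arena.square(arena), rulebook, units, seed)


def place(world, name, x, y, heading=0.0):
    return world._spawn(world._sp_index[name], x, y, heading)


class TestRuleValidation:
    def test_probability_bounds(self):
        with pytest.raises(RuleError):
            ReactionRule("e", "s", (("p", 1),), p_react=1.5)

    def test_products_required(self):
        with pytest.raises(RuleError):
            ReactionRule("e", "s", ())

    def test_undeclared_species_caught(self):
        rb = Rulebook(reactions=(ReactionRule("enz", "ghost", (("prod", 1),)),))
        with pytest.raises(RuleError, match="ghost"):
            rb.validate({"enz", "prod"})

    def test_duplicate_membrane_rule_rejected(self):
        rb = Rulebook(
            membrane=(MembraneRule("sub"), MembraneRule("sub", "excrete"))
        )
        with pytest.raises(RuleError, match="duplicate"):
            rb.validate({"sub"})


class TestCofactorBinding:
    def test_collision_creates_holoenzyme(self):
        rb = Rulebook(binding=(BindingRule("enz", "cof", "holo"),))
        w = make_world([ENZ, COF, HOLO], rb)
        e = place(w, "enz", 0.5, 0.5, 1.0)
        place(w, "cof", 0.5005, 0.5)
        w.step()
        assert w.count_of("holo") == 1
        assert w.count_of("enz") == 0
        assert w.count_of("cof") == 0
        # holoenzyme appears at the enzyme's position with its heading
        h = int(np.flatnonzero(w._alive[: w.n_agents])[0])
        assert w._heading[h] == pytest.approx(1.0)

    def test_no_rule_pair_just_reorients(self):
        rb = Rulebook(binding=(BindingRule("enz", "cof", "holo"),))
        w = make_world([ENZ, COF, HOLO, SUB], rb)
        place(w, "enz", 0.5, 0.5)
        place(w, "sub", 0.5005, 0.5)  # enzyme+metabolite: no rule without cofactor
        w.step()
        assert w.count_of("holo") == 0
        assert w.count_of("enz") == 1
        assert w.count_of("sub") == 1

    def test_enzyme_pool_conserved_through_binding(self):
        rb = Rulebook(binding=(BindingRule("enz", "cof", "holo"),))
        w = make_world([ENZ, COF, HOLO], rb, arena=0.01, seed=2)
        w.add_agents("enz", 40)
        w.add_agents("cof", 200)
        for _ in range(100):
            w.step()
            assert w.count_of("enz") + w.count_of("holo") == 40
            assert w.count_of("cof") + w.count_of("holo") == 200


class TestCatalysis:
    @staticmethod
    def _world_with_pairs(n_pairs, p, tau, seed=0):
        """n_pairs disjoint catalyst-substrate contacts in one large arena."""
        rb = Rulebook(
            reactions=(
                ReactionRule("enz", "sub", (("enz", 1), ("prod", 1)), p, tau),
            )
        )
        w = make_world([ENZ, SUB, PROD], rb, arena=100.0, seed=seed)
        side = int(math.ceil(math.sqrt(n_pairs)))
        pitch = 10.0 / (side + 1)
        k = 0
        for i in range(side):
            for j in range(side):
                if k >= n_pairs:
                    break
                x, y = (i + 1) * pitch, (j + 1) * pitch
                place(w, "enz", x, y)
                place(w, "sub", x, y)
                k += 1
        return w

    def test_reaction_fraction_follows_binomial_law(self):
        p = 0.25
        n = 10_000
        w = self._world_with_pairs(n, p, tau=0, seed=42)
        w.step()
        frac = w.count_of("prod") / n
        se = math.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * se

    def test_zero_probability_never_reacts(self):
        w = self._world_with_pairs(100, p=0.0, tau=0, seed=1)
        for _ in range(30):
            w.step()
        assert w.count_of("prod") == 0
        assert w.count_of("sub") == 100

    def test_reaction_duration_delays_products(self):
        tau = 3
        w = self._world_with_pairs(1, p=1.0, tau=tau, seed=0)
        w.step()  # reactive collision at tick 0: substrate consumed, enzyme busy
        assert w.count_of("sub") == 0
        assert w.count_of("prod") == 0
        w.step()
        w.step()
        assert w.count_of("prod") == 0
        w.step()  # busy_until = 3 reached
        assert w.count_of("prod") == 1
        assert w.count_of("enz") == 1

    def test_null_stoichiometry_keeps_counts(self):
        rb = Rulebook(
            reactions=(ReactionRule("enz", "enz2", (("enz", 1), ("enz2", 1)), 1.0, 0),)
        )
        enz2 = SpeciesSpec("enz2", 4e4, 3.3e-3, 4e-15, role="enzyme")
        w = make_world([ENZ, enz2], rb)
        place(w, "enz", 0.5, 0.5)
        place(w, "enz2", 0.5, 0.5)
        total = int(w._alive[: w.n_agents].sum())
        w.step()
        assert int(w._alive[: w.n_agents].sum()) == total

    def test_more_reactive_collisions_make_more_product(self):
        """Cumulative product at a fixed horizon is non-decreasing in p_react."""
        totals = []
        for p in (0.1, 0.5, 1.0):
            runs = []
            for seed in range(3):
                rb = Rulebook(
                    reactions=(
                        ReactionRule("enz", "sub", (("enz", 1), ("prod", 1)), p, 0),
                    )
                )
                w = make_world([ENZ, SUB, PROD], rb, seed=seed + 5)
                w.add_agents("enz", 150)
                w.add_agents("sub", 1500)
                for _ in range(200):
                    w.step()
                runs.append(w.count_of("prod"))
            totals.append(np.mean(runs))
        assert totals[0] <= totals[1] <= totals[2]
        assert totals[0] < totals[2]

    def test_longer_reactions_slow_substrate_consumption(self):
        """Time to consume half the substrate is non-decreasing in tau."""
        half_times = []
        for tau in (0, 60):
            runs = []
            for seed in range(3):
                rb = Rulebook(
                    reactions=(
                        ReactionRule("enz", "sub", (("enz", 1), ("prod", 1)), 1.0, tau),
                    )
                )
                w = make_world([ENZ, SUB, PROD], rb, arena=0.05, seed=seed + 3)
                w.add_agents("enz", 100)
                w.add_agents("sub", 400)
                t = 0
                while w.count_of("sub") > 200 and t < 3000:
                    w.step()
                    t += 1
                runs.append(t)
            half_times.append(np.mean(runs))
        assert half_times[0] <= half_times[1]


class TestInflux:
    def test_batches_of_ten_percent(self):
        sched = InfluxSchedule("sub", 1500, 0.1, 10)
        sizes = sched.batch_sizes()
        assert sizes == [150] * 10
        assert sched.batch_at(0) == 150
        assert sched.batch_at(5) == 0
        assert sched.batch_at(90) == 150
        assert sched.batch_at(100) == 0

    def test_remainder_absorbed_by_last_batch(self):
        sizes = InfluxSchedule("sub", 1005, 0.1, 10).batch_sizes()
        assert sum(sizes) == 1005
        assert set(sizes) <= {100, 101, 105, 96}  # base 100 or 101 per rounding

    def test_single_batch(self):
        assert InfluxSchedule("sub", 42, 1.0, 1).batch_sizes() == [42]

    def test_world_receives_scheduled_agents(self):
        rb = Rulebook(influx=(InfluxSchedule("sub", 30, 0.5, 5, start_step=2),))
        w = make_world([SUB], rb)
        counts = []
        for _ in range(10):
            w.step()
            counts.append(w.count_of("sub"))
        # batches of 15 at ticks 2 and 7
        assert counts == [0, 0, 15, 15, 15, 15, 15, 30, 30, 30]

    def test_invalid_fraction_rejected(self):
        with pytest.raises(RuleError):
            InfluxSchedule("sub", 10, 0.0, 1)


class TestPathwayConservation:
    def test_enzyme_and_cofactor_identities_hold(self):
        cfg = generate_fixture("two_step_pathway", scale=0.005)
        counts0 = cfg.initial_counts()
        w = cfg.build_world(seed=9)
        for _ in range(300):
            w.step()
            c = {s.name: w.count_of(s.name) for s in cfg.species}
            assert (
                c["aryl_alcohol_DH"] + c["holo_aryl_alcohol_DH"]
                == counts0["aryl_alcohol_DH"]
            )
            assert (
                c["benzaldehyde_DH"] + c["holo_benzaldehyde_DH"]
                == counts0["benzaldehyde_DH"]
            )
            assert (
                c["NAD+"] + c["NADH"] + c["holo_aryl_alcohol_DH"]
                + c["holo_benzaldehyde_DH"]
                == counts0["NAD+"] + counts0["NADH"]
            )
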