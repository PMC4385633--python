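"""Continuous 2D arena: agent motion, collision detection, membrane, stepping.

Agents are circles in a rectangular arena whose boundary is the cell
membrane.  Motion is ballistic with heading persistence: each mobile agent
advances along its heading by ``distance_unit * D / D_max`` per tick, so the
fastest species moves exactly one distance unit (the radius of the smallest
mobile molecule) per tick.  Two agents collide when the distance between
their centres is below the sum of their radii; a collision either fires a
behavioural rule (binding, catalysis) or reorients both agents by specular
reflection about the contact normal plus a small uniform angular jitter.

The per-tick schedule is:

1. apply influx schedules;
2. move all mobile, non-reacting agents (busy catalysts move too but ignore
   collisions), applying membrane actions at the boundary;
3. detect collisions (KD-tree candidates, exact distance filter);
4. resolve collision pairs in seeded-shuffled order, at most one
   rule-triggering event per agent per tick;
5. complete reactions whose busy interval has elapsed;
6. append species counts, cumulative reaction and excretion counters to the
   time series.

State lives in flat numpy arrays (one slot per agent ever created); the
only Python-level loop is over actually-overlapping pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .rules import Rulebook
from .timeseries import TimeSeries
from .units import SpeciesSpec, UnitSystem

log = logging.getLogger(__name__)

_REFLECT, _RECONVERT, _EXCRETE = 0, 1, 2


@dataclass
class Arena:
    """Rectangular membrane-bounded arena, lengths in um."""

    width: float
    height_2d: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height_2d <= 0:
            raise ValueError("arena dimensions must be > 0")

    @property
    def area(self) -> float:
        return self.width * self.height_2d

    @classmethod
    def square(cls, area_um2: float) -> "Arena":
        side = math.sqrt(area_um2)
        return cls(side, side)


@dataclass
class AgentState:
    """Snapshot of one agent (copy of the engine's array slot)."""

    agent_id: int
    species: str
    position: tuple[float, float]
    heading: float
    busy_until: int = 0
    alive: bool = True


@dataclass
class CollisionEvent:
    """One overlapping unordered pair."""

    pair: tuple[int, int]
    centre_distance: float
    contact_normal: tuple[float, float]  # unit vector from pair[1] to pair[0]


def collisions_all_pairs(positions: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """All-pairs O(n^2) collision oracle.

    Returns an (m, 2) integer array of index pairs (i < j) with Euclidean
    centre distance strictly below the combined radius.
    """
    n = len(positions)
    if n < 2:
        return np.empty((0, 2), dtype=np.int64)
    diff = positions[:, None, :] - positions[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    thresh = (radii[:, None] + radii[None, :]) ** 2
    hit = d2 < thresh
    iu = np.triu_indices(n, k=1)
    mask = hit[iu]
    return np.stack([iu[0][mask], iu[1][mask]], axis=1)


def collisions_indexed(positions: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Spatial-index accelerated collision detection.

    Candidate pairs within twice the maximum radius come from a KD-tree;
    the exact combined-radius test then filters them.  Returns the identical
    pair set as :func:`collisions_all_pairs`, sorted lexicographically.
    """
    n = len(positions)
    if n < 2:
        return np.empty((0, 2), dtype=np.int64)
    tree = cKDTree(positions)
    cand = tree.query_pairs(r=2.0 * float(radii.max()), output_type="ndarray")
    if len(cand) == 0:
        return np.empty((0, 2), dtype=np.int64)
    d = np.linalg.norm(positions[cand[:, 0]] - positions[cand[:, 1]], axis=1)
    keep = d < radii[cand[:, 0]] + radii[cand[:, 1]]
    pairs = cand[keep]
    pairs = np.sort(pairs, axis=1)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order]


def step_length(diffusion_rate: float, d_max: float, distance_unit: float) -> float:
    """Per-tick displacement: proportional to D, capped at one distance unit."""
    if d_max <= 0:
        return 0.0
    return distance_unit * diffusion_rate / d_max


def specular_reflect(heading: float, normal: tuple[float, float]) -> float:
    """Reflect a heading about a contact normal (mirror law)."""
    nx, ny = normal
    vx, vy = math.cos(heading), math.sin(heading)
    dot = vx * nx + vy * ny
    return math.atan2(vy - 2.0 * dot * ny, vx - 2.0 * dot * nx) % (2.0 * math.pi)


class World:
    """The simulation state: species registry, agents, rulebook, counters.

    Parameters
    ----------
    species : list of SpeciesSpec
        All species of the scenario (including obstacle species).
    arena : Arena
    rulebook : Rulebook
    units : UnitSystem
    seed : int
        Seeds the single generator driving every stochastic choice.
    jitter : float
        Half-width (rad) of the uniform angular jitter added on reorientation.
    """

    def __init__(
        self,
        species: list[SpeciesSpec],
        arena: Arena,
        rulebook: Rulebook,
        units: UnitSystem,
        seed: int = 0,
        jitter: float = 0.2,
    ) -> None:
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")
        rulebook.validate(set(names))
        self.species = list(species)
        self.arena = arena
        self.rulebook = rulebook
        self.units = units
        self.jitter = float(jitter)
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        self.t = 0

        self._sp_index = {s.name: i for i, s in enumerate(species)}
        self._radius = np.array([s.particle_radius for s in species])
        d = np.array([s.diffusion_rate for s in species])
        mobile = np.array([s.mobile for s in species])
        d_max = d[mobile].max() if mobile.any() else 0.0
        self._speed = np.array(
            [step_length(di, d_max, units.distance_unit) for di in d]
        )
        self._mobile = mobile
        self._max_radius = float(self._radius.max())

        # membrane actions, default reflect
        self._mem_action = np.full(len(species), _REFLECT, dtype=np.int64)
        self._mem_target = np.full(len(species), -1, dtype=np.int64)
        for m in rulebook.membrane:
            i = self._sp_index[m.species]
            if m.action == "reconvert":
                self._mem_action[i] = _RECONVERT
                self._mem_target[i] = self._sp_index[m.reconvert_to]
            elif m.action == "excrete":
                self._mem_action[i] = _EXCRETE

        # pair dispatch: (lo_sp, hi_sp) -> ("bind"|"react", payload)
        self._pair_rules: dict[tuple[int, int], tuple[str, tuple]] = {}
        for b in rulebook.binding:
            e, c = self._sp_index[b.enzyme_species], self._sp_index[b.cofactor_species]
            h = self._sp_index[b.holoenzyme_species]
            key = (min(e, c), max(e, c))
            if key in self._pair_rules:
                raise ValueError(f"conflicting rules for species pair {key}")
            self._pair_rules[key] = ("bind", (e, h))
        self._reactions = list(rulebook.reactions)
        self._rx_products: list[list[tuple[int, int]]] = []
        for ri, r in enumerate(self._reactions):
            cat = self._sp_index[r.catalyst_species]
            sub = self._sp_index[r.substrate_species]
            key = (min(cat, sub), max(cat, sub))
            if key in self._pair_rules:
                raise ValueError(f"conflicting rules for species pair {key}")
            self._pair_rules[key] = ("react", (cat, ri))
            self._rx_products.append(
                [(self._sp_index[sp], cnt) for sp, cnt in r.products]
            )

        # agent arrays (append-only; dead slots stay dead)
        cap = 1024
        self._x = np.empty(cap)
        self._y = np.empty(cap)
        self._heading = np.empty(cap)
        self._sp = np.empty(cap, dtype=np.int64)
        self._busy_until = np.zeros(cap, dtype=np.int64)
        self._pending = np.full(cap, -1, dtype=np.int64)  # reaction index or -1
        self._alive = np.zeros(cap, dtype=bool)
        self.n_agents = 0

        self._prev_x = np.empty(0)
        self._prev_y = np.empty(0)
        self.reaction_counts = np.zeros(len(self._reactions), dtype=np.int64)
        self.excreted = np.zeros(len(species), dtype=np.int64)
        self._influx_created = np.zeros(len(rulebook.influx), dtype=np.int64)

    # ------------------------------------------------------------------ agents

    def _grow(self, need: int) -> None:
        cap = len(self._x)
        if self.n_agents + need <= cap:
            return
        new = max(cap * 2, self.n_agents + need)
        for attr in ("_x", "_y", "_heading"):
            arr = getattr(self, attr)
            out = np.empty(new)
            out[: self.n_agents] = arr[: self.n_agents]
            setattr(self, attr, out)
        for attr, fill in (("_sp", 0), ("_busy_until", 0), ("_pending", -1)):
            arr = getattr(self, attr)
            out = np.full(new, fill, dtype=np.int64)
            out[: self.n_agents] = arr[: self.n_agents]
            setattr(self, attr, out)
        out = np.zeros(new, dtype=bool)
        out[: self.n_agents] = self._alive[: self.n_agents]
        self._alive = out

    def _spawn(self, sp: int, x: float, y: float, heading: float) -> int:
        self._grow(1)
        i = self.n_agents
        self._x[i], self._y[i], self._heading[i] = x, y, heading
        self._sp[i] = sp
        self._busy_until[i] = 0
        self._pending[i] = -1
        self._alive[i] = True
        self.n_agents += 1
        return i

    def _sample_positions(
        self, sp: int, n: int, avoid_overlap: bool, max_rounds: int = 20
    ) -> np.ndarray:
        """Uniform positions inside the membrane; optionally rejection-sampled
        against existing agents.  Falls back to allowing overlap (with a
        logged warning) if the arena is too crowded."""
        r = self._radius[sp]
        w, h = self.arena.width, self.arena.height_2d
        lo = np.array([r, r])
        hi = np.array([w - r, h - r])
        if np.any(hi <= lo):
            raise ValueError("arena smaller than agent diameter")

        def draw(k: int) -> np.ndarray:
            return lo + self.rng.random((k, 2)) * (hi - lo)

        if not avoid_overlap or self.n_agents == 0:
            return draw(n)
        live = np.flatnonzero(self._alive[: self.n_agents])
        pts = np.stack([self._x[live], self._y[live]], axis=1)
        tree = cKDTree(pts)
        max_r = self._radius[self._sp[live]].max()
        accepted: list[np.ndarray] = []
        need = n
        for _ in range(max_rounds):
            cand = draw(need)
            dist, idx = tree.query(cand, k=1)
            ok = dist > r + self._radius[self._sp[live[idx]]]
            accepted.append(cand[ok])
            need -= int(ok.sum())
            if need == 0:
                break
        if need:
            log.warning(
                "could not place %d agents of %s without overlap; allowing overlap",
                need,
                self.species[sp].name,
            )
            accepted.append(draw(need))
        return np.concatenate(accepted, axis=0)[:n]

    def add_agents(
        self,
        species_name: str,
        n: int,
        avoid_overlap: bool = False,
    ) -> None:
        """Create ``n`` agents at random positions with random headings."""
        if n < 0:
            raise ValueError("agent count must be >= 0")
        if n == 0:
            return
        sp = self._sp_index[species_name]
        pos = self._sample_positions(sp, n, avoid_overlap)
        headings = self.rng.random(n) * 2.0 * math.pi
        self._grow(n)
        i0 = self.n_agents
        self._x[i0 : i0 + n] = pos[:, 0]
        self._y[i0 : i0 + n] = pos[:, 1]
        self._heading[i0 : i0 + n] = headings
        self._sp[i0 : i0 + n] = sp
        self._busy_until[i0 : i0 + n] = 0
        self._pending[i0 : i0 + n] = -1
        self._alive[i0 : i0 + n] = True
        self.n_agents += n

    # ---------------------------------------------------------------- queries

    def species_counts(self) -> np.ndarray:
        """Alive agents per species index."""
        live = self._alive[: self.n_agents]
        return np.bincount(self._sp[: self.n_agents][live], minlength=len(self.species))

    def count_of(self, species_name: str) -> int:
        return int(self.species_counts()[self._sp_index[species_name]])

    def agents(self) -> list[AgentState]:
        """Snapshot of all alive agents."""
        out = []
        for i in np.flatnonzero(self._alive[: self.n_agents]):
            out.append(
                AgentState(
                    agent_id=int(i),
                    species=self.species[self._sp[i]].name,
                    position=(float(self._x[i]), float(self._y[i])),
                    heading=float(self._heading[i]),
                    busy_until=int(self._busy_until[i]) if self._pending[i] >= 0 else 0,
                )
            )
        return out

    def detect_collisions(self) -> list[CollisionEvent]:
        """Current overlapping pairs as :class:`CollisionEvent` objects."""
        live = np.flatnonzero(self._alive[: self.n_agents])
        pts = np.stack([self._x[live], self._y[live]], axis=1)
        pairs = collisions_indexed(pts, self._radius[self._sp[live]])
        events = []
        for a, b in pairs:
            i, j = int(live[a]), int(live[b])
            dx, dy = self._x[i] - self._x[j], self._y[i] - self._y[j]
            d = math.hypot(dx, dy)
            n = (dx / d, dy / d) if d > 0 else (1.0, 0.0)
            events.append(CollisionEvent((i, j), d, n))
        return events

    def snapshot_frame(self):
        """Per-agent snapshot as a DataFrame (tick, agent_id, species, x, y, heading)."""
        import pandas as pd

        live = np.flatnonzero(self._alive[: self.n_agents])
        return pd.DataFrame(
            {
                "tick": self.t,
                "agent_id": live,
                "species": [self.species[s].name for s in self._sp[live]],
                "x": self._x[live],
                "y": self._y[live],
                "heading": self._heading[live],
            }
        )

    # --------------------------------------------------------------- dynamics

    def _apply_influx(self) -> None:
        for fi, sched in enumerate(self.rulebook.influx):
            n = sched.batch_at(self.t)
            if n:
                self.add_agents(sched.species, n, avoid_overlap=True)
                self._influx_created[fi] += n

    def _move_and_membrane(self) -> None:
        n = self.n_agents
        live = self._alive[:n]
        sp = self._sp[:n]
        moving = live & (self._speed[sp] > 0)
        idx = np.flatnonzero(moving)
        # pre-move positions: obstacles cancel the move of agents they block
        self._prev_x = self._x[:n].copy()
        self._prev_y = self._y[:n].copy()
        if len(idx) == 0:
            return
        s = self._speed[sp[idx]]
        h = self._heading[idx]
        nx = self._x[idx] + s * np.cos(h)
        ny = self._y[idx] + s * np.sin(h)
        r = self._radius[sp[idx]]
        w, hh = self.arena.width, self.arena.height_2d

        out = (nx < r) | (nx > w - r) | (ny < r) | (ny > hh - r)
        act = self._mem_action[sp[idx]]

        # excretion: remove and count
        exc = out & (act == _EXCRETE)
        for i, spi in zip(idx[exc], sp[idx][exc]):
            self._alive[i] = False
            self.excreted[spi] += 1

        # reconversion: species replacement in place, then reflect back inside
        rec = out & (act == _RECONVERT)
        self._sp[idx[rec]] = self._mem_target[sp[idx[rec]]]

        keep = ~exc
        ki = idx[keep]
        kx, ky = nx[keep], ny[keep]
        kh = h[keep].copy()
        kr = self._radius[self._sp[ki]]
        # mirror off each wall (reflect heading; reconverted agents bounce too)
        hit = np.zeros(len(ki), dtype=bool)
        m = kx < kr
        kx[m] = 2.0 * kr[m] - kx[m]
        kh[m] = np.pi - kh[m]
        hit |= m
        m = kx > w - kr
        kx[m] = 2.0 * (w - kr[m]) - kx[m]
        kh[m] = np.pi - kh[m]
        hit |= m
        m = ky < kr
        ky[m] = 2.0 * kr[m] - ky[m]
        kh[m] = -kh[m]
        hit |= m
        m = ky > hh - kr
        ky[m] = 2.0 * (hh - kr[m]) - ky[m]
        kh[m] = -kh[m]
        hit |= m
        # membrane contact reorients like any collision: jitter breaks the
        # closed billiard orbits a pure specular box would produce
        if self.jitter and hit.any():
            kh[hit] += self.rng.uniform(-self.jitter, self.jitter, int(hit.sum()))
        self._x[ki] = np.clip(kx, kr, w - kr)
        self._y[ki] = np.clip(ky, kr, hh - kr)
        self._heading[ki] = kh % (2.0 * np.pi)

    def _clamp(self, i: int) -> None:
        r = self._radius[self._sp[i]]
        self._x[i] = min(max(self._x[i], r), self.arena.width - r)
        self._y[i] = min(max(self._y[i], r), self.arena.height_2d - r)

    def _block_by_obstacle(self, mob: int, obs: int) -> None:
        """Obstacles prevent movement: the blocked agent loses its step and
        is reoriented off the contact normal."""
        if mob < len(self._prev_x):
            self._x[mob], self._y[mob] = self._prev_x[mob], self._prev_y[mob]
        dx, dy = self._x[mob] - self._x[obs], self._y[mob] - self._y[obs]
        d = math.hypot(dx, dy)
        if d > 0:
            nx, ny = dx / d, dy / d
        else:
            ang = self.rng.random() * 2.0 * math.pi
            nx, ny = math.cos(ang), math.sin(ang)
        h = specular_reflect(self._heading[mob], (nx, ny))
        if self.jitter:
            h = (h + self.rng.uniform(-self.jitter, self.jitter)) % (2.0 * math.pi)
        self._heading[mob] = h
        # reverting can still leave an overlap (initial placement, pile-ups)
        overlap = self._radius[self._sp[mob]] + self._radius[self._sp[obs]] - d
        if overlap > 0:
            self._x[mob] += nx * overlap
            self._y[mob] += ny * overlap
            self._clamp(mob)

    def _reorient_pair(self, i: int, j: int) -> None:
        dx, dy = self._x[i] - self._x[j], self._y[i] - self._y[j]
        d = math.hypot(dx, dy)
        if d > 0:
            nx, ny = dx / d, dy / d
        else:
            ang = self.rng.random() * 2.0 * math.pi
            nx, ny = math.cos(ang), math.sin(ang)
        ri, rj = self._radius[self._sp[i]], self._radius[self._sp[j]]
        overlap = ri + rj - d
        mi, mj = self._mobile[self._sp[i]], self._mobile[self._sp[j]]
        jit = self.jitter
        if mi:
            h = specular_reflect(self._heading[i], (nx, ny))
            if jit:
                h = (h + self.rng.uniform(-jit, jit)) % (2.0 * math.pi)
            self._heading[i] = h
        if mj:
            h = specular_reflect(self._heading[j], (nx, ny))
            if jit:
                h = (h + self.rng.uniform(-jit, jit)) % (2.0 * math.pi)
            self._heading[j] = h
        if overlap > 0:
            if mi and mj:
                self._x[i] += nx * overlap / 2.0
                self._y[i] += ny * overlap / 2.0
                self._x[j] -= nx * overlap / 2.0
                self._y[j] -= ny * overlap / 2.0
            elif mi:
                self._x[i] += nx * overlap
                self._y[i] += ny * overlap
            elif mj:
                self._x[j] -= nx * overlap
                self._y[j] -= ny * overlap
            if mi:
                self._clamp(i)
            if mj:
                self._clamp(j)

    def _resolve_collisions(self) -> None:
        n = self.n_agents
        live = np.flatnonzero(self._alive[:n])
        if len(live) < 2:
            return
        pts = np.stack([self._x[live], self._y[live]], axis=1)
        tree = cKDTree(pts)
        cand = tree.query_pairs(r=2.0 * self._max_radius, output_type="ndarray")
        if len(cand) == 0:
            return
        a, b = live[cand[:, 0]], live[cand[:, 1]]
        d = np.hypot(self._x[a] - self._x[b], self._y[a] - self._y[b])
        spa, spb = self._sp[a], self._sp[b]
        hit = d < self._radius[spa] + self._radius[spb]
        # obstacles never interact with each other; busy catalysts ignore collisions
        busy = self._pending[:n] >= 0
        hit &= self._mobile[spa] | self._mobile[spb]
        hit &= ~(busy[a] | busy[b])
        a, b = a[hit], b[hit]
        if len(a) == 0:
            return
        order = self.rng.permutation(len(a))
        locked = np.zeros(n, dtype=bool)
        pair_rules = self._pair_rules
        for k in order:
            i, j = int(a[k]), int(b[k])
            if not (self._alive[i] and self._alive[j]) or locked[i] or locked[j]:
                continue
            si, sj = int(self._sp[i]), int(self._sp[j])
            entry = pair_rules.get((si, sj) if si <= sj else (sj, si))
            if entry is None:
                if not self._mobile[si]:
                    self._block_by_obstacle(j, i)
                elif not self._mobile[sj]:
                    self._block_by_obstacle(i, j)
                else:
                    self._reorient_pair(i, j)
                continue
            kind, payload = entry
            if kind == "bind":
                enz_sp, holo_sp = payload
                enz = i if si == enz_sp else j
                self._alive[i] = False
                self._alive[j] = False
                self._spawn(holo_sp, self._x[enz], self._y[enz], self._heading[enz])
            else:  # react
                cat_sp, ri = payload
                cat, sub = (i, j) if si == cat_sp else (j, i)
                rule = self._reactions[ri]
                if self.rng.random() < rule.p_react:
                    self._alive[sub] = False
                    self._pending[cat] = ri
                    self._busy_until[cat] = self.t + rule.duration_steps
                    locked[cat] = True
                else:
                    self._reorient_pair(i, j)

    def _complete_reactions(self) -> None:
        n = self.n_agents
        due = np.flatnonzero(
            self._alive[:n] & (self._pending[:n] >= 0) & (self._busy_until[:n] <= self.t)
        )
        for i in due:
            ri = int(self._pending[i])
            x, y = self._x[i], self._y[i]
            self._alive[i] = False
            for sp, cnt in self._rx_products[ri]:
                for _ in range(cnt):
                    h = self.rng.random() * 2.0 * math.pi
                    k = self._spawn(sp, x, y, h)
                    self._clamp(k)
            self.reaction_counts[ri] += 1

    def step(self) -> None:
        """Advance the world by one tick."""
        self._apply_influx()
        self._move_and_membrane()
        self._resolve_collisions()
        self._complete_reactions()
        self.t += 1

    def run(self, n_steps: int, record: bool = True) -> TimeSeries:
        """Run ``n_steps`` ticks, recording one time-series row per tick plus
        the initial conditions."""
        ts = TimeSeries.empty(
            [s.name for s in self.species],
            [r.name for r in self._reactions],
            seed=self.seed,
        )
        if record:
            ts.append(self.t, self.species_counts(), self.reaction_counts, self.excreted)
        for k in range(n_steps):
            self.step()
            if record:
                ts.append(
                    self.t, self.species_counts(), self.reaction_counts, self.excreted
                )
            if record and self.t % 1000 == 0:
                log.info(
                    "tick %d: %d agents, %d reactions",
                    self.t,
                    int(self._alive[: self.n_agents].sum()),
                    int(self.reaction_counts.sum()),
                )
        ts.finalize()
        return ts
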