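"""Scenario configuration: load/save, validation, fixtures, world building.

A scenario is a self-contained description of one simulation: arena
geometry, the species table (with geometry either given or derived from
molecular mass), initial composition (counts or mM concentrations, never
both for one species), the behavioural rulebook, and run settings.  The
on-disk format is YAML with units spelled out in key names.

Two fixtures are bundled:

* ``single_reaction_assay`` — one enzyme, one substrate, one product; the
  setting of the virtual kinetics assay (150 enzymes at 4.98e-2 mM in a
  1 um^2 slab, 10 s per tick).
* ``two_step_pathway`` — benzyl alcohol -> benzaldehyde -> benzoate via two
  NAD+-dependent dehydrogenases, with NADH recycling at the membrane,
  benzoate excretion, 1e5 crowding obstacles and gradual substrate influx
  (10% of 1500 molecules every 10 ticks).

``generate_fixture(name, scale)`` multiplies all counts and the arena area
by ``scale``, preserving every concentration.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from . import refdata
from .engine import Arena, World
from .rules import (
    BindingRule,
    InfluxSchedule,
    MembraneRule,
    ReactionRule,
    Rulebook,
)
from .units import (
    SpeciesSpec,
    UnitSystem,
    concentration_to_count,
    derive_species,
    distance_unit_of,
    fit_mass_scaling_exponent,
)

SCHEMA = "enzsim/1"

#: nominal molar masses for the two dehydrogenases (subunit scale, g/mol);
#: the holoenzymes inherit the bare enzyme's geometry
ENZYME_MASSES = {"aryl_alcohol_DH": 40000.0, "benzaldehyde_DH": 50000.0}


class ScenarioError(ValueError):
    """Invalid scenario configuration; message carries the offending key."""


@dataclass
class ScenarioConfig:
    name: str
    species: list[SpeciesSpec]
    initial: dict[str, dict]  # species -> {"count": n} | {"concentration_mM": c}
    rulebook: Rulebook
    arena_area_um2: float = 1.0
    assumed_height_um: float = 0.005
    seconds_per_step: float = 10.0
    obstacle_count: int = 0
    obstacle_radius_um: float | None = None
    max_steps: int = 1000
    seed: int = 0
    jitter_rad: float = 0.2

    # -------------------------------------------------------------- units

    def unit_system(self) -> UnitSystem:
        return UnitSystem(
            arena_area=self.arena_area_um2,
            assumed_height=self.assumed_height_um,
            distance_unit=distance_unit_of(self.species),
            seconds_per_step=self.seconds_per_step,
        )

    def initial_counts(self) -> dict[str, int]:
        """Initial composition resolved to agent counts."""
        units = self.unit_system()
        out: dict[str, int] = {}
        for name, spec in self.initial.items():
            if "count" in spec and "concentration_mM" in spec:
                raise ScenarioError(
                    f"initial.{name}: give count or concentration_mM, not both"
                )
            if "count" in spec:
                n = int(spec["count"])
                if n < 0:
                    raise ScenarioError(f"initial.{name}.count: must be >= 0")
                out[name] = n
            elif "concentration_mM" in spec:
                out[name] = concentration_to_count(spec["concentration_mM"], units)
            else:
                raise ScenarioError(
                    f"initial.{name}: needs count or concentration_mM"
                )
        return out

    # ---------------------------------------------------------- validation

    def validate(self) -> None:
        names = {s.name for s in self.species}
        for name in self.initial:
            if name not in names:
                raise ScenarioError(f"initial.{name}: undeclared species")
        if self.obstacle_count < 0:
            raise ScenarioError("obstacles.count: must be >= 0")
        if self.max_steps < 0:
            raise ScenarioError("max_steps: must be >= 0")
        all_names = names | ({"obstacle"} if self.obstacle_count else set())
        self.rulebook.validate(all_names)
        self.initial_counts()  # raises on malformed entries

    # ------------------------------------------------------------- digest

    def to_dict(self) -> dict:
        rb = self.rulebook
        return {
            "schema": SCHEMA,
            "name": self.name,
            "arena_area_um2": self.arena_area_um2,
            "assumed_height_um": self.assumed_height_um,
            "seconds_per_step": self.seconds_per_step,
            "max_steps": self.max_steps,
            "seed": self.seed,
            "jitter_rad": self.jitter_rad,
            "species": [
                {
                    "name": s.name,
                    "molecular_weight_g_mol": s.molecular_weight,
                    "particle_radius_um": s.particle_radius,
                    "diffusion_rate_um2_s": s.diffusion_rate,
                    "role": s.role,
                }
                for s in self.species
            ],
            "initial": {k: dict(v) for k, v in self.initial.items()},
            "obstacles": {
                "count": self.obstacle_count,
                **(
                    {"radius_um": self.obstacle_radius_um}
                    if self.obstacle_radius_um is not None
                    else {}
                ),
            },
            "rules": {
                "binding": [
                    {
                        "enzyme": b.enzyme_species,
                        "cofactor": b.cofactor_species,
                        "holoenzyme": b.holoenzyme_species,
                    }
                    for b in rb.binding
                ],
                "reactions": [
                    {
                        "name": r.name,
                        "catalyst": r.catalyst_species,
                        "substrate": r.substrate_species,
                        "products": [[sp, cnt] for sp, cnt in r.products],
                        "p_react_percent": r.p_react * 100.0,
                        "duration_steps": r.duration_steps,
                    }
                    for r in rb.reactions
                ],
                "membrane": [
                    {
                        "species": m.species,
                        "action": m.action,
                        **({"to": m.reconvert_to} if m.reconvert_to else {}),
                    }
                    for m in rb.membrane
                ],
                "influx": [
                    {
                        "species": f.species,
                        "total_count": f.total_count,
                        "fraction_per_batch": f.fraction_per_batch,
                        "interval_steps": f.interval_steps,
                        "start_step": f.start_step,
                    }
                    for f in rb.influx
                ],
            },
        }

    @property
    def digest(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    # ----------------------------------------------------------------- I/O

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, raw: dict) -> "ScenarioConfig":
        try:
            species_raw = raw["species"]
        except KeyError as e:
            raise ScenarioError(f"missing required key {e.args[0]!r}") from None
        # geometry derivation for rows lacking radius/diffusion: power law
        # fitted to the rows that do carry an explicit radius (fallback to
        # the bundled small-molecule anchors)
        anchors = [
            (s["molecular_weight_g_mol"], s["particle_radius_um"])
            for s in species_raw
            if "particle_radius_um" in s
        ]
        if len({m for m, _ in anchors}) >= 2:
            alpha = fit_mass_scaling_exponent(anchors)
            m0, r0 = anchors[0]
            d0 = next(
                (
                    s["diffusion_rate_um2_s"]
                    for s in species_raw
                    if "diffusion_rate_um2_s" in s and "particle_radius_um" in s
                ),
                None,
            )
            if d0 is None:
                ref, alpha = refdata.default_scaling()
            else:
                ref = SpeciesSpec("__ref__", m0, r0, d0)
        else:
            ref, alpha = refdata.default_scaling()
        species = []
        for i, s in enumerate(species_raw):
            where = f"species[{i}]"
            try:
                species.append(
                    derive_species(
                        s["name"],
                        s["molecular_weight_g_mol"],
                        ref,
                        alpha,
                        role=s.get("role", "metabolite"),
                        particle_radius=s.get("particle_radius_um"),
                        diffusion_rate=s.get("diffusion_rate_um2_s"),
                        display_tag=s.get("display_tag", ""),
                    )
                )
            except KeyError as e:
                raise ScenarioError(f"{where}: missing key {e.args[0]!r}") from None
            except ValueError as e:
                raise ScenarioError(f"{where}: {e}") from None
        rules_raw = raw.get("rules", {})
        try:
            rulebook = Rulebook(
                binding=tuple(
                    BindingRule(b["enzyme"], b["cofactor"], b["holoenzyme"])
                    for b in rules_raw.get("binding", [])
                ),
                reactions=tuple(
                    ReactionRule(
                        r["catalyst"],
                        r["substrate"],
                        tuple((sp, int(cnt)) for sp, cnt in r["products"]),
                        p_react=float(r.get("p_react_percent", 100.0)) / 100.0,
                        duration_steps=int(r.get("duration_steps", 0)),
                        name=r.get("name", ""),
                    )
                    for r in rules_raw.get("reactions", [])
                ),
                membrane=tuple(
                    MembraneRule(m["species"], m.get("action", "reflect"), m.get("to", ""))
                    for m in rules_raw.get("membrane", [])
                ),
                influx=tuple(
                    InfluxSchedule(
                        f["species"],
                        int(f["total_count"]),
                        float(f.get("fraction_per_batch", 1.0)),
                        int(f.get("interval_steps", 1)),
                        int(f.get("start_step", 0)),
                    )
                    for f in rules_raw.get("influx", [])
                ),
            )
        except KeyError as e:
            raise ScenarioError(f"rules: missing key {e.args[0]!r}") from None
        obstacles = raw.get("obstacles", {}) or {}
        cfg = cls(
            name=raw.get("name", "scenario"),
            species=species,
            initial={k: dict(v) for k, v in (raw.get("initial") or {}).items()},
            rulebook=rulebook,
            arena_area_um2=float(raw.get("arena_area_um2", 1.0)),
            assumed_height_um=float(raw.get("assumed_height_um", 0.005)),
            seconds_per_step=float(raw.get("seconds_per_step", 10.0)),
            obstacle_count=int(obstacles.get("count", 0)),
            obstacle_radius_um=obstacles.get("radius_um"),
            max_steps=int(raw.get("max_steps", 1000)),
            seed=int(raw.get("seed", 0)),
            jitter_rad=float(raw.get("jitter_rad", 0.2)),
        )
        cfg.validate()
        return cfg

    @classmethod
    def load(cls, path: str | Path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ScenarioError(f"{path}: not a mapping")
        return cls.from_dict(raw)

    # --------------------------------------------------------------- world

    def build_world(self, seed: int | None = None) -> World:
        """Instantiate the world: mobile species first (uniform random),
        then obstacles rejection-sampled against everything already placed."""
        self.validate()
        units = self.unit_system()
        species = list(self.species)
        if self.obstacle_count:
            r_obs = (
                self.obstacle_radius_um
                if self.obstacle_radius_um is not None
                else units.distance_unit
            )
            species.append(
                SpeciesSpec("obstacle", 1e4, r_obs, 0.0, role="obstacle")
            )
        world = World(
            species,
            Arena.square(self.arena_area_um2),
            self.rulebook,
            units,
            seed=self.seed if seed is None else seed,
            jitter=self.jitter_rad,
        )
        for name, n in self.initial_counts().items():
            world.add_agents(name, n)
        if self.obstacle_count:
            world.add_agents("obstacle", self.obstacle_count, avoid_overlap=True)
        return world


# ------------------------------------------------------------------ fixtures


def _pathway_species() -> list[SpeciesSpec]:
    ref, alpha = refdata.default_scaling()
    small = [
        refdata.reference_species("benzyl_alcohol", "metabolite"),
        refdata.reference_species("NAD+", "cofactor"),
        refdata.reference_species("NADH", "cofactor"),
        refdata.reference_species("benzaldehyde", "metabolite"),
        refdata.reference_species("benzoate", "metabolite"),
    ]
    enzymes, holos = [], []
    for ename, mw in ENZYME_MASSES.items():
        e = derive_species(ename, mw, ref, alpha, role="enzyme")
        enzymes.append(e)
        holos.append(
            SpeciesSpec(
                f"holo_{ename}",
                mw + refdata.SMALL_MOLECULES["NAD+"][0],
                e.particle_radius,
                e.diffusion_rate,
                role="holoenzyme",
            )
        )
    return small + enzymes + holos


def generate_fixture(name: str, scale: float = 1.0) -> ScenarioConfig:
    """One of the two bundled scenarios, linearly scaled.

    ``scale`` multiplies every agent count (and the obstacle count) and the
    arena area, leaving all concentrations unchanged.
    """
    if not (0.0 < scale <= 1.0):
        raise ScenarioError(f"scale must be in (0, 1], got {scale}")
    if name == "two_step_pathway":
        rulebook = Rulebook(
            binding=(
                BindingRule("aryl_alcohol_DH", "NAD+", "holo_aryl_alcohol_DH"),
                BindingRule("benzaldehyde_DH", "NAD+", "holo_benzaldehyde_DH"),
            ),
            reactions=(
                ReactionRule(
                    "holo_aryl_alcohol_DH",
                    "benzyl_alcohol",
                    (("aryl_alcohol_DH", 1), ("NADH", 1), ("benzaldehyde", 1)),
                    p_react=0.1,
                    duration_steps=10,
                    name="benzyl_alcohol_oxidation",
                ),
                ReactionRule(
                    "holo_benzaldehyde_DH",
                    "benzaldehyde",
                    (("benzaldehyde_DH", 1), ("NADH", 1), ("benzoate", 1)),
                    p_react=0.04,
                    duration_steps=10,
                    name="benzaldehyde_oxidation",
                ),
            ),
            membrane=(
                MembraneRule("NADH", "reconvert", "NAD+"),
                MembraneRule("benzoate", "excrete"),
            ),
            influx=(
                InfluxSchedule(
                    "benzyl_alcohol",
                    total_count=round(1500 * scale),
                    fraction_per_batch=0.1,
                    interval_steps=10,
                    start_step=0,
                ),
            ),
        )
        return ScenarioConfig(
            name="two_step_pathway",
            species=_pathway_species(),
            initial={
                "aryl_alcohol_DH": {"concentration_mM": 1.66},
                "benzaldehyde_DH": {"concentration_mM": 1.66},
                "NAD+": {"concentration_mM": 33.2},
                "NADH": {"concentration_mM": 3.32},
            },
            rulebook=rulebook,
            arena_area_um2=1.0 * scale,
            obstacle_count=round(1e5 * scale),
            max_steps=15000,
            seconds_per_step=10.0,
        )
    if name == "single_reaction_assay":
        ref, alpha = refdata.default_scaling()
        substrate = SpeciesSpec(
            "substrate", 108.14, 0.323e-3, 4.018e-14, role="metabolite"
        )
        product = SpeciesSpec(
            "product", 106.121, 0.321e-3, 4.047e-14, role="metabolite"
        )
        enzyme = derive_species("enzyme", 40000.0, ref, alpha, role="enzyme")
        rulebook = Rulebook(
            reactions=(
                ReactionRule(
                    "enzyme",
                    "substrate",
                    (("enzyme", 1), ("product", 1)),
                    p_react=1.0,
                    duration_steps=0,
                    name="catalysis",
                ),
            ),
        )
        return ScenarioConfig(
            name="single_reaction_assay",
            species=[substrate, product, enzyme],
            initial={
                "enzyme": {"concentration_mM": 4.98e-2},
                "substrate": {"concentration_mM": 6.64e-2},
            },
            rulebook=rulebook,
            arena_area_um2=1.0 * scale,
            obstacle_count=0,
            max_steps=400,
            seconds_per_step=10.0,
        )
    raise ScenarioError(f"unknown fixture {name!r}")
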