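"""Unit conversions and molecular-mass scaling laws.

The simulator lives in "agent units": integer particle counts in a thin
rectangular slab of intracellular space, advanced in discrete ticks.  The
laboratory reports concentrations (mM) and real time (s).  This module is
the bridge between the two, plus the scaling laws that assign a particle
radius and a diffusion rate to a molecular species from its molecular mass
when neither has been measured directly:

* radius:     r(M) = r_ref * (M / M_ref) ** alpha   (power law, alpha fitted)
* diffusion:  D(r) = D_ref * (r_ref / r)            (Stokes-like, inverse radius)

Concentration <-> count conversion treats the 2D arena as a slab of fixed
height (default 0.005 um, roughly one enzyme tall):

    n = C[mM] * 1e-3 mol/L * N_A * area[um^2] * height[um] * 1e-15 L/um^3
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

AVOGADRO = 6.02214076e23
"""Avogadro constant, 1/mol (2019 SI exact value)."""

#: valid species roles
ROLES = ("enzyme", "metabolite", "cofactor", "holoenzyme", "complex", "obstacle")


class UnitError(ValueError):
    """Invalid argument to a unit conversion."""


@dataclass(frozen=True)
class SpeciesSpec:
    """Physical identity of one molecular species.

    Parameters
    ----------
    name : str
        Unique identifier within a scenario.
    molecular_weight : float
        Molar mass in g/mol.
    particle_radius : float
        Agent radius in um.
    diffusion_rate : float
        Diffusion rate in um^2/s; zero only for obstacles.
    role : str
        One of :data:`ROLES`.
    display_tag : str, optional
        Label used in outputs; defaults to ``name``.
    """

    name: str
    molecular_weight: float
    particle_radius: float
    diffusion_rate: float
    role: str = "metabolite"
    display_tag: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise UnitError(f"unknown role {self.role!r} for species {self.name!r}")
        if self.particle_radius <= 0:
            raise UnitError(f"species {self.name!r}: particle_radius must be > 0")
        if self.diffusion_rate < 0:
            raise UnitError(f"species {self.name!r}: diffusion_rate must be >= 0")
        if (self.diffusion_rate == 0) != (self.role == "obstacle"):
            raise UnitError(
                f"species {self.name!r}: diffusion_rate == 0 exactly for obstacles"
            )
        if not self.display_tag:
            object.__setattr__(self, "display_tag", self.name)

    @property
    def mobile(self) -> bool:
        return self.role != "obstacle"


@dataclass(frozen=True)
class UnitSystem:
    """Geometry and time base tying agent units to laboratory units.

    ``distance_unit`` is the radius of the smallest mobile species in the
    scenario; it is also the per-tick displacement of the fastest species.
    """

    arena_area: float  # um^2
    assumed_height: float = 0.005  # um, slab height (~ one enzyme)
    distance_unit: float = 0.323e-3  # um
    seconds_per_step: float = 10.0  # s per tick
    avogadro: float = field(default=AVOGADRO, repr=False)

    def __post_init__(self) -> None:
        if self.arena_area <= 0:
            raise UnitError("arena_area must be > 0")
        if self.assumed_height <= 0:
            raise UnitError("assumed_height must be > 0")
        if self.seconds_per_step <= 0:
            raise UnitError("seconds_per_step must be > 0")
        if self.distance_unit <= 0:
            raise UnitError("distance_unit must be > 0")

    @property
    def slab_volume_liters(self) -> float:
        """Arena slab volume in litres (1 um^3 = 1e-15 L)."""
        return self.arena_area * self.assumed_height * 1e-15


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (1499.5 -> 1500)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def concentration_to_count(conc_mM: float, units: UnitSystem) -> int:
    """Convert a molar concentration to an integer agent count.

    Multiplies the concentration by the Avogadro number and the slab volume
    of the arena, then rounds half away from zero.
    """
    if conc_mM < 0:
        raise UnitError(f"concentration must be >= 0, got {conc_mM}")
    molecules = conc_mM * 1e-3 * units.avogadro * units.slab_volume_liters
    return _round_half_away(molecules)


def count_to_concentration(n: float, units: UnitSystem) -> float:
    """Exact algebraic inverse of :func:`concentration_to_count` (pre-rounding).

    Returns the concentration in mM represented by ``n`` agents.
    """
    if n < 0:
        raise UnitError(f"count must be >= 0, got {n}")
    return n / (units.avogadro * units.slab_volume_liters) * 1e3


def steps_to_seconds(n_steps: float, units: UnitSystem) -> float:
    """Real time spanned by ``n_steps`` simulation ticks."""
    if n_steps < 0:
        raise UnitError("n_steps must be >= 0")
    return n_steps * units.seconds_per_step


def fit_mass_scaling_exponent(
    reference_rows: Sequence[tuple[float, float]],
) -> float:
    """Fit the exponent alpha of the radius-mass power law r = r0 * M**alpha.

    Least-squares slope of log(radius) against log(mass).  With exactly two
    rows this reduces to ln(r2/r1) / ln(M2/M1).

    Parameters
    ----------
    reference_rows : sequence of (molecular_weight, particle_radius)
        At least two rows with distinct masses.
    """
    rows = list(reference_rows)
    masses = np.array([m for m, _ in rows], dtype=float)
    radii = np.array([r for _, r in rows], dtype=float)
    if len(np.unique(masses)) < 2:
        raise UnitError("need >= 2 rows with distinct molecular weights")
    slope, _ = np.polyfit(np.log(masses), np.log(radii), 1)
    return float(slope)


def radius_from_mass(mw: float, ref: SpeciesSpec, alpha: float) -> float:
    """Predict a particle radius from molecular mass via the fitted power law."""
    if mw <= 0:
        raise UnitError("molecular weight must be > 0")
    return ref.particle_radius * (mw / ref.molecular_weight) ** alpha


def diffusion_from_radius(r: float, ref: SpeciesSpec) -> float:
    """Predict a diffusion rate by inverse-radius (Stokes-like) scaling."""
    if r <= 0:
        raise UnitError("radius must be > 0")
    return ref.diffusion_rate * (ref.particle_radius / r)


def derive_species(
    name: str,
    molecular_weight: float,
    ref: SpeciesSpec,
    alpha: float,
    role: str = "metabolite",
    particle_radius: float | None = None,
    diffusion_rate: float | None = None,
    display_tag: str = "",
) -> SpeciesSpec:
    """Build a :class:`SpeciesSpec`, deriving unspecified geometry from mass."""
    r = particle_radius if particle_radius is not None else radius_from_mass(
        molecular_weight, ref, alpha
    )
    d = diffusion_rate if diffusion_rate is not None else diffusion_from_radius(r, ref)
    return SpeciesSpec(name, molecular_weight, r, d, role, display_tag)


def distance_unit_of(species: Iterable[SpeciesSpec]) -> float:
    """The scenario's distance unit: minimum radius over mobile species."""
    radii = [s.particle_radius for s in species if s.mobile]
    if not radii:
        raise UnitError("no mobile species in scenario")
    return min(radii)
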