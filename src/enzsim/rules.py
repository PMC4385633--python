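"""The behavioural rulebook: cofactor binding, timed probabilistic catalysis,
membrane actions, and gradual influx.

Four rule kinds drive everything that is not plain diffusion:

* :class:`BindingRule` — apoenzyme + cofactor collide -> one holoenzyme agent.
* :class:`ReactionRule` — catalyst + substrate collide -> with probability
  ``p_react`` the substrate is consumed and the catalyst turns busy for
  ``duration_steps`` ticks, after which it is replaced by the product side
  (regenerated enzyme, converted cofactor, products).
* :class:`MembraneRule` — what a species does on hitting the cell membrane:
  reflect (default), reconvert into another species, or be excreted.
* :class:`InfluxSchedule` — staged introduction of a species (e.g. 10% of the
  total every 10 ticks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence


class RuleError(ValueError):
    """Invalid rulebook entry."""


@dataclass(frozen=True)
class BindingRule:
    """Enzyme + cofactor -> holoenzyme (immediate, deterministic)."""

    enzyme_species: str
    cofactor_species: str
    holoenzyme_species: str


@dataclass(frozen=True)
class ReactionRule:
    """Probabilistic timed catalysis on a catalyst-substrate collision.

    ``products`` lists (species, count) pairs created when the reaction
    completes, including any regenerated enzyme and converted cofactor.
    Sub-resolution participants (H+, H2O) are not instantiated as agents.
    """

    catalyst_species: str
    substrate_species: str
    products: tuple[tuple[str, int], ...]
    p_react: float = 1.0
    duration_steps: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_react <= 1.0):
            raise RuleError(f"p_react must be in [0, 1], got {self.p_react}")
        if self.duration_steps < 0:
            raise RuleError("duration_steps must be >= 0")
        if not self.products:
            raise RuleError("products must be non-empty")
        object.__setattr__(self, "products", tuple(tuple(p) for p in self.products))
        if not self.name:
            object.__setattr__(
                self, "name", f"{self.catalyst_species}+{self.substrate_species}"
            )


#: membrane actions
MEMBRANE_ACTIONS = ("reflect", "reconvert", "excrete")


@dataclass(frozen=True)
class MembraneRule:
    """Behaviour of one species at the cell membrane (arena boundary)."""

    species: str
    action: str = "reflect"
    reconvert_to: str = ""

    def __post_init__(self) -> None:
        if self.action not in MEMBRANE_ACTIONS:
            raise RuleError(f"unknown membrane action {self.action!r}")
        if self.action == "reconvert" and not self.reconvert_to:
            raise RuleError(f"membrane rule for {self.species!r}: reconvert target missing")


@dataclass(frozen=True)
class InfluxSchedule:
    """Staged influx: ``fraction_per_batch`` of ``total_count`` every
    ``interval_steps`` ticks, starting at ``start_step``.

    Batch sizes are ``round(fraction * total)`` with the last batch absorbing
    the rounding remainder, so the cumulative influx equals ``total_count``
    exactly.
    """

    species: str
    total_count: int
    fraction_per_batch: float = 1.0
    interval_steps: int = 1
    start_step: int = 0

    def __post_init__(self) -> None:
        if self.total_count < 0:
            raise RuleError("total_count must be >= 0")
        if not (0.0 < self.fraction_per_batch <= 1.0):
            raise RuleError("fraction_per_batch must be in (0, 1]")
        if self.interval_steps < 1:
            raise RuleError("interval_steps must be >= 1")
        if self.start_step < 0:
            raise RuleError("start_step must be >= 0")

    @property
    def n_batches(self) -> int:
        # ceil(1/f) with guard against float fuzz (0.1 -> 10 batches)
        n = int(round(1.0 / self.fraction_per_batch))
        return max(n, 1)

    def batch_sizes(self) -> list[int]:
        base = int(round(self.fraction_per_batch * self.total_count))
        sizes = [base] * (self.n_batches - 1)
        sizes.append(self.total_count - base * (self.n_batches - 1))
        if sizes[-1] < 0:  # extreme rounding: fold back into earlier batches
            deficit = -sizes[-1]
            sizes[-1] = 0
            for i in range(len(sizes) - 2, -1, -1):
                take = min(deficit, sizes[i])
                sizes[i] -= take
                deficit -= take
                if deficit == 0:
                    break
        return sizes

    def batch_at(self, step: int) -> int:
        """Number of agents to introduce at tick ``step`` (0 if none)."""
        if step < self.start_step:
            return 0
        offset = step - self.start_step
        if offset % self.interval_steps:
            return 0
        k = offset // self.interval_steps
        sizes = self.batch_sizes()
        return sizes[k] if k < len(sizes) else 0


@dataclass
class Rulebook:
    """Validated collection of all behavioural rules of a scenario."""

    binding: Sequence[BindingRule] = field(default_factory=tuple)
    reactions: Sequence[ReactionRule] = field(default_factory=tuple)
    membrane: Sequence[MembraneRule] = field(default_factory=tuple)
    influx: Sequence[InfluxSchedule] = field(default_factory=tuple)

    def validate(self, species_names: set[str]) -> None:
        """Check every rule references only declared species."""
        def check(name: str, where: str) -> None:
            if name not in species_names:
                raise RuleError(f"{where} references undeclared species {name!r}")

        for b in self.binding:
            check(b.enzyme_species, "binding rule")
            check(b.cofactor_species, "binding rule")
            check(b.holoenzyme_species, "binding rule")
        for r in self.reactions:
            check(r.catalyst_species, f"reaction {r.name!r}")
            check(r.substrate_species, f"reaction {r.name!r}")
            for sp, cnt in r.products:
                check(sp, f"reaction {r.name!r} products")
                if cnt < 1:
                    raise RuleError(f"reaction {r.name!r}: product count must be >= 1")
        seen = set()
        for m in self.membrane:
            check(m.species, "membrane rule")
            if m.action == "reconvert":
                check(m.reconvert_to, "membrane rule")
            if m.species in seen:
                raise RuleError(f"duplicate membrane rule for {m.species!r}")
            seen.add(m.species)
        for f in self.influx:
            check(f.species, "influx schedule")
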