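"""Per-tick record of a simulation run.

One row per tick: count of every species, cumulative completed reactions
per reaction rule, cumulative excreted agents per species.  Round-trips
losslessly through tab-separated text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class TimeSeries:
    species_names: list[str]
    reaction_names: list[str]
    seed: int = 0
    config_digest: str = ""
    _rows: list[np.ndarray] = field(default_factory=list, repr=False)
    frame: pd.DataFrame | None = None

    @classmethod
    def empty(
        cls,
        species_names: list[str],
        reaction_names: list[str],
        seed: int = 0,
        config_digest: str = "",
    ) -> "TimeSeries":
        return cls(list(species_names), list(reaction_names), seed, config_digest)

    def append(
        self,
        tick: int,
        counts: np.ndarray,
        reaction_counts: np.ndarray,
        excreted: np.ndarray,
    ) -> None:
        row = np.concatenate([[tick], counts, reaction_counts, excreted])
        self._rows.append(row.astype(np.int64))

    def finalize(self) -> pd.DataFrame:
        cols = (
            ["tick"]
            + [f"count_{s}" for s in self.species_names]
            + [f"reactions_{r}" for r in self.reaction_names]
            + [f"excreted_{s}" for s in self._excreted_species()]
        )
        data = np.stack(self._rows) if self._rows else np.empty((0, len(cols)), int)
        self.frame = pd.DataFrame(data, columns=cols)
        return self.frame

    def _excreted_species(self) -> list[str]:
        return self.species_names

    def counts(self, species: str) -> np.ndarray:
        return self.frame[f"count_{species}"].to_numpy()

    def excreted_of(self, species: str) -> np.ndarray:
        return self.frame[f"excreted_{species}"].to_numpy()

    def total_reactions(self) -> np.ndarray:
        cols = [c for c in self.frame.columns if c.startswith("reactions_")]
        return self.frame[cols].sum(axis=1).to_numpy()

    @property
    def n_ticks(self) -> int:
        return len(self.frame)

    # ------------------------------------------------------------------- I/O

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# seed={self.seed} digest={self.config_digest}\n")
            self.frame.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TimeSeries":
        path = Path(path)
        with path.open() as fh:
            header = fh.readline().strip()
            frame = pd.read_csv(fh, sep="\t")
        meta = dict(
            kv.split("=", 1) for kv in header.lstrip("# ").split() if "=" in kv
        )
        species = [c[len("count_"):] for c in frame.columns if c.startswith("count_")]
        reactions = [
            c[len("reactions_"):] for c in frame.columns if c.startswith("reactions_")
        ]
        ts = cls(
            species,
            reactions,
            seed=int(meta.get("seed", 0)),
            config_digest=meta.get("digest", ""),
        )
        ts.frame = frame
        return ts
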