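"""Virtual enzyme assay: initial velocities, Lineweaver-Burk regression,
parameter scans, and matching against experimentally measured enzymes.

The assay mirrors the laboratory protocol.  A fixed amount of enzyme is
simulated against a series of substrate concentrations; the initial
velocity V at each concentration is the least-squares slope of product
concentration (mM) against real time (s).  The Michaelis-Menten law

    V = Vmax * S / (Km + S)

is then fitted through its Lineweaver-Burk double-reciprocal form

    1/V = (Km/Vmax) * (1/S) + 1/Vmax

by ordinary least squares of 1/V on 1/S, giving Km = slope/intercept,
Vmax = 1/intercept and the turnover number kcat = Vmax/[E].  Negative
estimates are genuine stochastic outcomes at weak catalysis (the fitted
intercept can cross zero) and are reported unmodified.

Two simulation knobs stand in for the microscopic rate constants: the
probability that a collision reacts (p_react) tunes affinity (Km), and the
reaction duration in ticks (tau) tunes turnover (kcat).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scenario import ScenarioConfig, generate_fixture
from .timeseries import TimeSeries
from .units import UnitSystem, concentration_to_count, count_to_concentration


class AssayError(ValueError):
    """Degenerate assay input (zero velocity, too few points, ...)."""


#: default substrate series, mM (200 to 2000 molecules in the 1 um^2 slab)
DEFAULT_SUBSTRATE_CONCENTRATIONS = (6.64e-2, 1.66e-1, 3.32e-1, 4.98e-1, 6.64e-1)


def michaelis_menten_velocity(S: float, km: float, vmax: float) -> float:
    """Michaelis-Menten velocity at substrate concentration ``S``."""
    if km <= 0:
        raise AssayError("km must be > 0")
    if S < 0:
        raise AssayError("S must be >= 0")
    return vmax * S / (km + S)


@dataclass(frozen=True)
class KineticsResult:
    """Output of one Lineweaver-Burk fit.

    ``km`` [mM], ``vmax`` [mM/s], ``kcat`` [1/s], regression ``slope`` [s],
    ``intercept`` [s/mM], ``r_squared``, and the (S, V) points fitted.
    Negative or non-finite values are reported as-is.
    """

    km: float
    vmax: float
    kcat: float
    slope: float
    intercept: float
    r_squared: float
    enzyme_concentration: float
    per_concentration_velocities: tuple[tuple[float, float], ...] = ()


def lineweaver_burk_fit(
    points: Sequence[tuple[float, float]], enzyme_concentration: float
) -> KineticsResult:
    """Fit the double-reciprocal regression to (S [mM], V [mM/s]) points."""
    pts = [(float(s), float(v)) for s, v in points]
    if len(pts) < 3:
        raise AssayError(f"need >= 3 (S, V) points, got {len(pts)}")
    for s, v in pts:
        if s <= 0:
            raise AssayError(f"substrate concentration must be > 0, got {s}")
        if v == 0:
            raise AssayError(
                f"zero velocity at S = {s} mM: cannot take reciprocal "
                "(lengthen the measurement window or raise p_react)"
            )
    inv_s = np.array([1.0 / s for s, _ in pts])
    inv_v = np.array([1.0 / v for _, v in pts])
    fit = stats.linregress(inv_s, inv_v)
    slope, intercept = float(fit.slope), float(fit.intercept)
    if intercept == 0.0:
        vmax = km = math.inf
    else:
        vmax = 1.0 / intercept
        km = slope / intercept
    kcat = vmax / enzyme_concentration
    return KineticsResult(
        km=km,
        vmax=vmax,
        kcat=kcat,
        slope=slope,
        intercept=intercept,
        r_squared=float(fit.rvalue) ** 2,
        enzyme_concentration=enzyme_concentration,
        per_concentration_velocities=tuple(pts),
    )


def measure_velocity(
    series: TimeSeries,
    product_species: str,
    window: int,
    units: UnitSystem,
) -> float:
    """Initial velocity (mM/s): OLS slope of product concentration against
    real time over the first ``window`` ticks of the run."""
    if window < 1:
        raise AssayError("window must be >= 1 tick")
    counts = series.counts(product_species)
    if len(counts) < window + 1:
        raise AssayError(
            f"window ({window} ticks) longer than series ({len(counts) - 1} ticks)"
        )
    conc = np.array(
        [count_to_concentration(c, units) for c in counts[: window + 1]]
    )
    t = np.arange(window + 1) * units.seconds_per_step
    slope = np.polyfit(t, conc, 1)[0]
    return float(slope)


def default_window(
    series: TimeSeries, substrate_species: str, run_steps: int
) -> int:
    """Default initial-velocity window: first 10% of the run, or the
    interval before 10% of the substrate is consumed, whichever is shorter."""
    w = max(1, run_steps // 10)
    counts = series.counts(substrate_species)
    start = counts[0]
    if start > 0:
        below = np.flatnonzero(counts < 0.9 * start)
        if len(below):
            w = min(w, max(1, int(below[0])))
    return w


@dataclass(frozen=True)
class AssayDesign:
    """Design of one virtual assay (one (p_react, tau) condition)."""

    substrate_concentrations: tuple[float, ...] = DEFAULT_SUBSTRATE_CONCENTRATIONS
    enzyme_concentration: float = 4.98e-2  # mM (150 enzymes in the 1 um^2 slab)
    p_react: float = 1.0
    duration_steps: int = 0
    replicates: int = 3
    seconds_per_step: float = 10.0
    run_steps: int = 400
    measurement_window: int | None = None  # None -> default_window rule
    base_seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.substrate_concentrations)) < 3:
            raise AssayError("need >= 3 distinct substrate concentrations")
        if any(s <= 0 for s in self.substrate_concentrations):
            raise AssayError("substrate concentrations must be > 0")
        if self.replicates < 1:
            raise AssayError("replicates must be >= 1")


def _condition_seed(
    base_seed: int, p_react: float, tau: int, conc_index: int, replicate: int
) -> int:
    """Deterministic per-run seed, independent of scan iteration order."""
    ss = np.random.SeedSequence(
        [base_seed, int(round(p_react * 1e6)), tau, conc_index, replicate]
    )
    return int(ss.generate_state(1)[0])


def _assay_scenario(
    template: ScenarioConfig, design: AssayDesign, substrate_conc: float
) -> ScenarioConfig:
    rules = template.rulebook
    if len(rules.reactions) != 1:
        raise AssayError("assay template must declare exactly one reaction")
    rule = replace(
        rules.reactions[0],
        p_react=design.p_react,
        duration_steps=design.duration_steps,
    )
    cfg = replace(
        template,
        rulebook=replace(rules, reactions=(rule,)),
        seconds_per_step=design.seconds_per_step,
        max_steps=design.run_steps,
    )
    cfg.initial = dict(template.initial)
    cfg.initial[rule.substrate_species] = {"concentration_mM": float(substrate_conc)}
    cfg.initial[rule.catalyst_species] = {
        "concentration_mM": float(design.enzyme_concentration)
    }
    return cfg


def run_assay(
    design: AssayDesign, template: ScenarioConfig | None = None
) -> KineticsResult:
    """Run the substrate series, average replicate velocities per
    concentration, and fit the Lineweaver-Burk regression."""
    if template is None:
        template = generate_fixture("single_reaction_assay")
    rule = template.rulebook.reactions[0]
    substrate, product = rule.substrate_species, "product"
    # the first non-catalyst product is the tracked product species
    for sp, _ in rule.products:
        if sp != rule.catalyst_species:
            product = sp
            break
    points = []
    for ci, conc in enumerate(design.substrate_concentrations):
        cfg = _assay_scenario(template, design, conc)
        units = cfg.unit_system()
        velocities = []
        for rep in range(design.replicates):
            seed = _condition_seed(
                design.base_seed, design.p_react, design.duration_steps, ci, rep
            )
            world = cfg.build_world(seed=seed)
            series = world.run(design.run_steps)
            w = (
                design.measurement_window
                if design.measurement_window is not None
                else default_window(series, substrate, design.run_steps)
            )
            velocities.append(measure_velocity(series, product, w, units))
        points.append((conc, float(np.mean(velocities))))
    return lineweaver_burk_fit(points, design.enzyme_concentration)


def parameter_scan(
    p_react_values: Iterable[float],
    duration_values: Iterable[int],
    design: AssayDesign | None = None,
    template: ScenarioConfig | None = None,
) -> pd.DataFrame:
    """One assay per (p_react, tau) combination, as a tidy table.

    Per-run seeds derive from (base_seed, p_react, tau, concentration,
    replicate), so rows do not depend on grid iteration order.
    """
    design = design or AssayDesign()
    p_vals, taus = list(p_react_values), list(duration_values)
    if not p_vals or not taus:
        raise AssayError("scan grids must be non-empty")
    rows = []
    for p in p_vals:
        for tau in taus:
            res = run_assay(
                replace(design, p_react=p, duration_steps=int(tau)), template
            )
            rows.append(
                {
                    "p_react_percent": p * 100.0,
                    "duration_steps": int(tau),
                    "km": res.km,
                    "kcat": res.kcat,
                    "vmax": res.vmax,
                    "r_squared": res.r_squared,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ReferenceEnzyme:
    """Experimentally measured Michaelis-Menten constants for one enzyme."""

    ec_number: str
    name: str
    km: float  # mM
    kcat: float  # 1/s

    def __post_init__(self) -> None:
        if self.km <= 0 or self.kcat <= 0:
            raise AssayError(
                f"reference {self.ec_number}: km and kcat must be > 0"
            )


def read_reference_table(path: str | Path) -> list[ReferenceEnzyme]:
    """Load references from delimited text (ec_number, name, km_mM, kcat_per_s)."""
    frame = pd.read_csv(path, sep=None, engine="python")
    frame.columns = [c.strip().lower() for c in frame.columns]
    out = []
    for _, row in frame.iterrows():
        out.append(
            ReferenceEnzyme(
                str(row["ec_number"]),
                str(row["name"]),
                float(row.get("km_mm", row.get("km"))),
                float(row.get("kcat_per_s", row.get("kcat"))),
            )
        )
    return out


def match_to_reference(
    scan_table: pd.DataFrame, references: Sequence[ReferenceEnzyme]
) -> pd.DataFrame:
    """For each reference enzyme, the scan row minimising the
    reference-scaled Euclidean distance

        sqrt((dKm/Km_ref)^2 + (dkcat/kcat_ref)^2).

    Rows with non-positive Km or kcat are excluded from matching (they are
    artefacts of near-zero turnover, not usable kinetics).
    """
    if scan_table.empty or not len(references):
        raise AssayError("scan table and references must be non-empty")
    usable = scan_table[(scan_table["km"] > 0) & (scan_table["kcat"] > 0)]
    if usable.empty:
        raise AssayError("no scan rows with positive km and kcat to match against")
    rows = []
    for ref in references:
        d = np.hypot(
            (usable["km"] - ref.km) / ref.km,
            (usable["kcat"] - ref.kcat) / ref.kcat,
        )
        best = usable.loc[d.idxmin()]
        rows.append(
            {
                "ec_number": ref.ec_number,
                "name": ref.name,
                "km_ref": ref.km,
                "kcat_ref": ref.kcat,
                "p_react_percent": best["p_react_percent"],
                "duration_steps": int(best["duration_steps"]),
                "km": best["km"],
                "kcat": best["kcat"],
                "distance": float(d.min()),
            }
        )
    return pd.DataFrame(rows)
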