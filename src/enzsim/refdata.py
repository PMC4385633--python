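"""Bundled reference data for the benzyl-alcohol oxidation pathway examples.

Three small data sets ship with the package:

* measured geometry of the five small molecules of the two-step
  benzyl alcohol -> benzaldehyde -> benzoate pathway (molar mass,
  particle radius, diffusion rate);
* a published grid of virtual-assay kinetic estimates over combinations of
  reactive-collision percentage and reaction duration, used by the
  enzyme-matching examples and tests;
* experimentally measured Michaelis-Menten constants for six enzymes
  (BRENDA records) that the grid is matched against.
"""

from __future__ import annotations

import pandas as pd

from .units import SpeciesSpec, fit_mass_scaling_exponent

# name -> (molecular weight g/mol, particle radius um, diffusion rate um^2/s)
SMALL_MOLECULES: dict[str, tuple[float, float, float]] = {
    "benzyl_alcohol": (108.14, 0.323e-3, 4.018e-14),
    "NAD+": (661.41, 0.657e-3, 1.975e-14),
    "NADH": (663.43, 0.658e-3, 1.973e-14),
    "benzaldehyde": (106.121, 0.321e-3, 4.047e-14),
    "benzoate": (121.12, 0.338e-3, 3.843e-14),
}

#: anchor species for the mass scaling laws (smallest-vs-largest measured pair)
SCALING_ANCHORS = ("benzyl_alcohol", "NAD+")


def reference_species(name: str = "benzyl_alcohol", role: str = "metabolite") -> SpeciesSpec:
    """A :class:`SpeciesSpec` for one of the measured small molecules."""
    mw, r, d = SMALL_MOLECULES[name]
    return SpeciesSpec(name, mw, r, d, role)


def default_scaling() -> tuple[SpeciesSpec, float]:
    """Reference species and power-law exponent fitted to the two anchors."""
    rows = [
        (SMALL_MOLECULES[n][0], SMALL_MOLECULES[n][1]) for n in SCALING_ANCHORS
    ]
    return reference_species(), fit_mass_scaling_exponent(rows)


# Published virtual-assay estimates: (% reactive collision, duration steps,
# K_m in mM, k_cat in 1/s).  Negative rows are genuine outputs at very low
# reactive-collision percentages, where near-zero k_cat plus stochastic noise
# flips the sign of the fitted Lineweaver-Burk intercept.
KINETIC_SCAN_GRID: list[tuple[float, int, float, float]] = [
    (1, 0, -0.850576595, -0.028514453),
    (5, 0, -2.996153951, -6.87e-01),
    (5, 25, -4.656418568, -9.77e-01),
    (5, 50, 3.439111157, 8.08e-01),
    (5, 75, 2.918555171, 6.25e-01),
    (5, 100, -21.79373575, -3.92e00),
    (10, 0, -14.6001318, -6.631944616),
    (15, 0, 11.51508927, 7.623330464),
    (25, 0, 0.87739, 1.08e00),
    (25, 5, 1.36829, 1.44e00),
    (25, 25, 2.45375, 2.23e00),
    (25, 50, 1.20869, 1.06e00),
    (25, 75, 0.70036, 6.22e-01),
    (25, 100, 0.531257304, 4.52e-01),
    (34, 1, 3.18977, 3.93e00),
    (50, 0, 0.71725, 1.27e00),
    (75, 0, 3.65866, 6.49e00),
    (75, 5, 3.06473, 5.33e00),
    (75, 25, 1.13387, 2.01e00),
    (75, 50, 0.60205, 1.07e00),
    (75, 75, 0.37565, 6.69e-01),
    (75, 100, 0.29693544, 5.06e-01),
    (90, 0, 4.43222, 8.17e00),
    (95, 0, 4.49601, 8.44e00),
    (95, 25, 1.277963717, 2.396621333),
    (95, 50, 0.56747, 1.11e00),
    (95, 75, 0.34196, 6.88e-01),
    (95, 100, 0.237537579, 4.88e-01),
    (100, 0, 0.75547, 1.60e00),
]


def kinetic_scan_table() -> pd.DataFrame:
    """The published scan grid as a tidy DataFrame."""
    return pd.DataFrame(
        KINETIC_SCAN_GRID, columns=["p_react_percent", "duration_steps", "km", "kcat"]
    )


# (EC number, name, K_m mM, k_cat 1/s) — experimentally measured constants.
REFERENCE_ENZYMES: list[tuple[str, str, float, float]] = [
    ("1.8.1.9", "glutathione reductase", 0.404, 0.39),
    ("4.1.1.11", "aspartate 1-decarboxylase", 0.219, 0.65),
    ("1.1.1.1", "alcohol dehydrogenase", 0.41, 1.0),
    ("1.1.1.205", "IMP dehydrogenase", 1.7, 1.9),
    ("3.4.13.22", "D-Ala-D-Ala dipeptidase", 1.0, 4.7),
    ("4.1.1.1", "pyruvate decarboxylase", 1.8, 1.2),
]


def reference_enzyme_table() -> pd.DataFrame:
    """The bundled experimental kinetics as a tidy DataFrame."""
    return pd.DataFrame(
        REFERENCE_ENZYMES, columns=["ec_number", "name", "km", "kcat"]
    )
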