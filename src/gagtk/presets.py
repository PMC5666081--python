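"""Published CXCL13/heparan-sulfate study conditions used as generator defaults.

Concentration series, rate constants and equilibrium constants for the
wild-type and HS-binding-site mutants of murine CXCL13, used as the default
parameters of the synthetic-data generators so that simulated experiments
mirror the real ones.  Concentrations are molar; rates in SI units.

Variant naming: ``met`` is the Met-initiated wild-type construct, ``dn`` the
N-terminally truncated form, ``c1``/``c5``/``c15`` carry alanine mutations
of the alpha-helix basic cluster, the C-terminal basic cluster, or both.
"""

from __future__ import annotations

import numpy as np

_NM = 1e-9

#: SPR analyte concentration series per protein variant (M).
SPR_CONCENTRATIONS: dict[str, tuple[float, ...]] = {
    "met": tuple(c * _NM for c in (12, 18, 28, 41, 62, 93, 140)),
    "dn": tuple(c * _NM for c in (12, 18, 28, 41, 62, 93, 140)),
    "c5": tuple(c * _NM for c in (15, 22, 33, 50, 74, 112, 167)),
    "c1": tuple(c * _NM for c in (50, 74, 112, 167, 251, 377, 565)),
    "c15": tuple(c * _NM for c in (86, 129, 193, 289, 434, 651, 977)),
}

#: Kinetic rate constants per variant: (kon / M^-1 s^-1, koff / s^-1).
SPR_RATES: dict[str, tuple[float, float]] = {
    "met": (3.08e5, 5.8e-3),
    "dn": (2.7e5, 5.3e-3),
    "c5": (9.14e4, 7.5e-3),
}

#: Steady-state affinities per variant (M).
STEADY_STATE_KD: dict[str, float] = {
    "wt": 50e-9,
    "c5": 95e-9,
    "c1": 504e-9,
    "c15": 1.62e-6,
}

#: Monomer-dimer dissociation constant (M) and an NMR-scale concentration series.
DIMER_KD: float = 0.3e-3
DIMER_CONCENTRATIONS: tuple[float, ...] = tuple(
    c * 1e-6 for c in (50, 100, 300, 580, 950)
)

#: Protein and ligand concentrations of the HS-dp4 titration (M).
TITRATION_PROTEIN_CONC: float = 100e-6
TITRATION_LIGAND_CONCS: tuple[float, ...] = (37e-6, 74e-6, 144e-6)

#: Key basic residues of the two HS binding sites.
CLUSTER1_RESIDUES: tuple[str, ...] = ("R58", "K60", "R64", "R67", "K72")
CLUSTER5_RESIDUES: tuple[str, ...] = ("K84", "R85", "R86")

#: Binding-site sphere radius (Angstrom).
SITE_RADIUS: float = 16.0

#: 15N resonance frequency (Hz) used for relaxation defaults.
NU_N_DEFAULT: float = 60.8e6
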