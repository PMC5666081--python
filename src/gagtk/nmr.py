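"""Chemical-shift perturbation, dimerization and relaxation analysis.

Three standard solution-NMR analyses of protein-ligand and protein-protein
equilibria:

* **Combined CSP.**  On ligand binding in fast exchange, each amide's
  observed 1H and 15N shifts move toward the bound-state values.  The two
  dimensions are combined as a weighted Euclidean norm,
  ``sqrt(ddH**2 + (w*ddN)**2)``, with the conventional 15N scaling
  w = 0.159 reflecting the nitrogen shift-range/gyromagnetic ratio.
  Residues whose combined CSP exceeds a threshold rule (default
  mean + 1 SD) are called perturbed - the usual first pass at mapping a
  binding surface.

* **Monomer-dimer K_D from slow-exchange intensities.**  When dimerization
  is slow on the chemical-shift timescale, monomer and dimer give separate
  peaks whose integrals report the state populations.  With dimer signal
  proportional to protomer concentration 2[D] and monomer signal to [M],
  the intensity ratio r = I_dim/I_mono = 2[D]/[M] at total monomer-equivalent
  concentration C_tot = [M] + 2[D] inverts the mass-action law
  K_D = [M]**2/[D] in closed form: K_D = 2*C_tot/(r*(1+r)).

* **Rotational correlation time and apparent MW from 15N relaxation.**
  For isotropic tumbling the T1/T2 ratio gives the correlation time via
  tau_c = sqrt(6*T1/T2 - 7)/(4*pi*nu_N), with nu_N the 15N resonance
  frequency.  tau_c scales roughly linearly with molecular weight for
  compact globular proteins; a configurable linear calibration converts it
  into an apparent MW, good enough to distinguish monomer from dimer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeakRecord",
    "CSPRecord",
    "RelaxationRecord",
    "DEFAULT_CSP_WEIGHT",
    "DEFAULT_MW_SLOPE_KDA_PER_NS",
    "combined_csp",
    "csp_table",
    "call_perturbed_residues",
    "dimer_kd_from_intensities",
    "dimer_kd_from_table",
    "monomer_fraction",
    "tau_c_from_t1t2",
    "tau_c_and_mw",
    "peaks_from_csv",
    "relaxation_from_csv",
]

#: Conventional 15N scaling factor for combined 1H/15N CSPs.
DEFAULT_CSP_WEIGHT = 0.159

#: Default linear tau_c -> MW calibration for compact globular proteins.
DEFAULT_MW_SLOPE_KDA_PER_NS = 1 / 0.55  # kDa per ns, i.e. 0.55 ns/kDa inverted


@dataclass(frozen=True)
class PeakRecord:
    """One assigned amide resonance: position, intensity, oligomeric-state tag."""

    residue: str
    delta_h: float  # ppm
    delta_n: float  # ppm
    intensity: float = 1.0
    state: str = "n/a"  # monomer | dimer | n/a

    def __post_init__(self) -> None:
        if not (math.isfinite(self.delta_h) and math.isfinite(self.delta_n)):
            raise ValueError(f"non-finite shift for {self.residue}")
        if self.intensity < 0:
            raise ValueError(f"negative intensity for {self.residue}")


@dataclass(frozen=True)
class CSPRecord:
    residue: str
    dd_h: float
    dd_n: float
    dd_combined: float
    weight: float


@dataclass(frozen=True)
class RelaxationRecord:
    """Per-residue 15N relaxation data at a given spectrometer frequency."""

    residue: str
    t1: float  # s
    t2: float  # s
    het_noe: float = float("nan")
    nu_n: float = 60.8e6  # Hz, 15N frequency (600 MHz 1H spectrometer)

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError(f"T1 and T2 must be positive for {self.residue}")


def combined_csp(dd_h: float, dd_n: float, weight: float = DEFAULT_CSP_WEIGHT) -> float:
    """Weighted Euclidean combination of 1H and 15N shift differences (ppm)."""
    if weight <= 0:
        raise ValueError("weight must be positive")
    return math.sqrt(dd_h ** 2 + (weight * dd_n) ** 2)


def csp_table(
    free: Iterable[PeakRecord],
    bound: Iterable[PeakRecord],
    weight: float = DEFAULT_CSP_WEIGHT,
) -> list[CSPRecord]:
    """Per-residue combined CSPs between a free and a bound peak table.

    Residues present in only one table are skipped (unassigned or broadened
    out on binding).
    """
    free_by_res = {p.residue: p for p in free}
    out = []
    for p in bound:
        f = free_by_res.get(p.residue)
        if f is None:
            continue
        dd_h = p.delta_h - f.delta_h
        dd_n = p.delta_n - f.delta_n
        out.append(
            CSPRecord(
                residue=p.residue,
                dd_h=dd_h,
                dd_n=dd_n,
                dd_combined=combined_csp(dd_h, dd_n, weight),
                weight=weight,
            )
        )
    return out


def call_perturbed_residues(
    csps: Sequence[CSPRecord],
    rule: Callable[[np.ndarray], float] | None = None,
    exclude_prolines: bool = True,
) -> list[str]:
    """Residues whose combined CSP exceeds the threshold rule.

    The default rule is mean + 1 SD over the supplied records, the common
    convention for calling a binding surface from a CSP map.  ``rule`` may be
    any callable mapping the CSP array to a threshold.  An all-zero map
    yields an empty call set.
    """
    if len(csps) < 5:
        raise ValueError("need at least 5 CSP records for a meaningful threshold")
    records = [
        c for c in csps if not (exclude_prolines and c.residue.upper().startswith("P"))
    ]
    values = np.array([c.dd_combined for c in records], dtype=float)
    threshold = rule(values) if rule is not None else float(values.mean() + values.std(ddof=0))
    called = [c.residue for c in records if c.dd_combined > threshold]
    return sorted(called, key=_residue_sort_key)


def _residue_sort_key(residue: str):
    digits = "".join(ch for ch in residue if ch.isdigit())
    return (int(digits) if digits else 0, residue)


# ---------------------------------------------------------------------------
# monomer-dimer equilibrium from slow-exchange intensities
# ---------------------------------------------------------------------------

def dimer_kd_from_intensities(r: float, c_tot: float) -> float:
    """Dimerization K_D (same units as ``c_tot``) from an intensity ratio.

    ``r`` is the dimer/monomer peak intensity ratio with dimer intensity
    proportional to protomer concentration 2[D]; ``c_tot`` the total
    monomer-equivalent concentration.  Closed form of the mass-action
    inversion: K_D = 2*c_tot/(r*(1+r)).
    """
    if c_tot <= 0:
        raise ValueError("total concentration must be positive")
    if r < 0:
        raise ValueError("intensity ratio cannot be negative")
    if r == 0:
        raise ValueError("pure monomer (r = 0): dimer K_D undefined")
    return 2.0 * c_tot / (r * (1.0 + r))


def monomer_fraction(kd_dim: float, c_tot: float) -> float:
    """Free-monomer concentration fraction [M]/C_tot for 2M <-> D mass action."""
    if kd_dim <= 0 or c_tot <= 0:
        raise ValueError("K_D and C_tot must be positive")
    # 2[M]^2/K_D + [M] - C_tot = 0
    m = (math.sqrt(1.0 + 8.0 * c_tot / kd_dim) - 1.0) * kd_dim / 4.0
    return m / c_tot


def dimer_kd_from_table(
    table: pd.DataFrame,
    residues: Sequence[str] | None = None,
) -> dict:
    """Pooled dimer K_D over a (c_tot, residue, i_mono, i_dim) intensity table.

    Intensity ratios are pooled by mean over the selected residues at each
    concentration, converted to per-concentration K_D estimates, and averaged.
    Returns the mean estimate with the per-concentration values and SD.
    """
    df = table
    if residues is not None:
        df = df[df["residue"].isin(list(residues))]
    if df.empty:
        raise ValueError("no intensity rows after residue selection")
    per_conc = []
    for c_tot, grp in df.groupby("c_tot", sort=True):
        r = float((grp["i_dim"] / grp["i_mono"]).mean())
        per_conc.append((float(c_tot), dimer_kd_from_intensities(r, float(c_tot))))
    kds = np.array([kd for _, kd in per_conc], dtype=float)
    return {
        "kd": float(kds.mean()),
        "sd": float(kds.std(ddof=1)) if kds.size > 1 else float("nan"),
        "per_concentration": per_conc,
        "n_concentrations": int(kds.size),
    }


# ---------------------------------------------------------------------------
# rotational correlation time and apparent molecular weight
# ---------------------------------------------------------------------------

def tau_c_from_t1t2(t1: float, t2: float, nu_n: float) -> float:
    """Rotational correlation time (seconds) from the 15N T1/T2 ratio.

    tau_c = sqrt(6*T1/T2 - 7) / (4*pi*nu_N); valid for T1/T2 >= 7/6 (the
    radicand is negative below that, where the estimator does not apply).
    """
    ratio = t1 / t2
    radicand = 6.0 * ratio - 7.0
    if radicand < 0:
        raise ValueError(
            f"T1/T2 = {ratio:.3f} < 7/6: correlation-time estimator undefined"
        )
    return math.sqrt(radicand) / (4.0 * math.pi * nu_n)


def tau_c_and_mw(
    rec: RelaxationRecord,
    mw_slope_kda_per_ns: float = DEFAULT_MW_SLOPE_KDA_PER_NS,
) -> dict:
    """Correlation time (ns) and apparent MW (kDa) for one relaxation record.

    The MW is a linear rescaling of tau_c and is labelled apparent: the
    calibration assumes a compact globular shape and breaks down for
    elongated or disordered proteins.
    """
    tau_c_s = tau_c_from_t1t2(rec.t1, rec.t2, rec.nu_n)
    tau_c_ns = tau_c_s * 1e9
    return {
        "residue": rec.residue,
        "tau_c_ns": tau_c_ns,
        "mw_kda_apparent": mw_slope_kda_per_ns * tau_c_ns,
    }


# ---------------------------------------------------------------------------
# CSV ingestion
# ---------------------------------------------------------------------------

def peaks_from_csv(path) -> list[PeakRecord]:
    """Read a peak table CSV (residue, delta_h, delta_n[, intensity][, state])."""
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples():
        out.append(
            PeakRecord(
                residue=str(row.residue),
                delta_h=float(row.delta_h),
                delta_n=float(row.delta_n),
                intensity=float(getattr(row, "intensity", 1.0)),
                state=str(getattr(row, "state", "n/a")),
            )
        )
    return out


def relaxation_from_csv(path, nu_n: float = 60.8e6) -> list[RelaxationRecord]:
    """Read a relaxation table CSV (residue, t1, t2[, noe][, nu_n])."""
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples():
        out.append(
            RelaxationRecord(
                residue=str(row.residue),
                t1=float(row.t1),
                t2=float(row.t2),
                het_noe=float(getattr(row, "noe", float("nan"))),
                nu_n=float(getattr(row, "nu_n", nu_n)),
            )
        )
    return out
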