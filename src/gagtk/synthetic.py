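"""Synthetic-data generators for every input the analysis modules consume.

Each generator is the exact forward model of the corresponding estimator, so
noise-free output round-trips through the analysis to the generating
parameters; noise models are the simplest ones consistent with each
estimator's assumptions (additive Gaussian in RU for SPR, multiplicative
Gaussian for intensities and relaxation times, Bernoulli for H-bond events,
Gaussian for per-frame energies).  All generators are deterministic given a
seed.

Defaults follow the published CXCL13 study conditions collected in
:mod:`gagtk.presets` (concentration series, rate constants, equilibrium
constants), so a default simulation reproduces the published experimental
design.
"""

from __future__ import annotations

import math
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import presets
from .md_occupancy import EventSeries
from .nmr import PeakRecord, RelaxationRecord, monomer_fraction
from .screening import Pose, PoseAtom, PoseSet, SiteDefinition, surrogate_score
from .spr import KineticParams, Sensorgram, simulate_sensorgram

__all__ = [
    "gen_sensorgrams",
    "gen_titration_peaks",
    "bound_fraction",
    "gen_dimer_intensities",
    "gen_pose_cloud",
    "gen_hbond_events",
    "gen_residue_energies",
    "gen_relaxation",
    "SurrogateDockingBackend",
]


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# SPR
# ---------------------------------------------------------------------------

def gen_sensorgrams(
    kon: float = presets.SPR_RATES["met"][0],
    koff: float = presets.SPR_RATES["met"][1],
    rmax: float = 100.0,
    concentrations: Sequence[float] = presets.SPR_CONCENTRATIONS["met"],
    t_assoc: float = 300.0,
    t_dissoc: float = 300.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> list[Sensorgram]:
    """1:1 Langmuir curves over a concentration series, optional Gaussian noise."""
    rng = _rng(seed)
    params = KineticParams(kon=kon, koff=koff, rmax=rmax)
    return [
        simulate_sensorgram(
            params, c, t_assoc=t_assoc, t_dissoc=t_dissoc, dt=dt,
            noise_sd=noise_sd, rng=rng,
        )
        for c in concentrations
    ]


# ---------------------------------------------------------------------------
# NMR titration (fast exchange)
# ---------------------------------------------------------------------------

def bound_fraction(p_tot: float, l_tot: float, kd: float) -> float:
    """Fraction of protein bound for P + L <-> PL, exact quadratic solution."""
    if p_tot <= 0 or kd <= 0 or l_tot < 0:
        raise ValueError("concentrations and K_D must be positive")
    b = p_tot + l_tot + kd
    pl = (b - math.sqrt(b * b - 4.0 * p_tot * l_tot)) / 2.0
    return pl / p_tot


def gen_titration_peaks(
    p_tot: float = presets.TITRATION_PROTEIN_CONC,
    ligand_concs: Sequence[float] = presets.TITRATION_LIGAND_CONCS,
    kd_bind: float = 10e-6,
    dd_max: Mapping[str, tuple[float, float]] | None = None,
    residues: Sequence[str] | None = None,
    free_shifts: Mapping[str, tuple[float, float]] | None = None,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> dict[float, list[PeakRecord]]:
    """Fast-exchange titration peak tables at each ligand concentration.

    ``dd_max`` maps perturbed residues to their saturated (ddH, ddN) shift
    changes in ppm; unlisted residues keep their free-state shifts (zero
    CSP).  Observed shifts interpolate linearly in the bound fraction, the
    fast-exchange limit.  Returns {ligand concentration: peak table},
    including the free state at concentration 0.0.
    """
    rng = _rng(seed)
    dd_max = dict(dd_max or {})
    if residues is None:
        residues = sorted(dd_max) or [f"G{i}" for i in range(1, 11)]
    if free_shifts is None:
        free_shifts = {
            res: (8.0 + 0.5 * float(rng.standard_normal()),
                  115.0 + 5.0 * float(rng.standard_normal()))
            for res in residues
        }
    tables: dict[float, list[PeakRecord]] = {}
    for l_tot in [0.0, *ligand_concs]:
        f = bound_fraction(p_tot, l_tot, kd_bind) if l_tot > 0 else 0.0
        peaks = []
        for res in residues:
            h0, n0 = free_shifts[res]
            dh, dn = dd_max.get(res, (0.0, 0.0))
            noise_h = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
            noise_n = float(rng.normal(0.0, noise_sd * 5)) if noise_sd > 0 else 0.0
            peaks.append(
                PeakRecord(
                    residue=res,
                    delta_h=h0 + f * dh + noise_h,
                    delta_n=n0 + f * dn + noise_n,
                )
            )
        tables[l_tot] = peaks
    return tables


# ---------------------------------------------------------------------------
# slow-exchange monomer/dimer intensities
# ---------------------------------------------------------------------------

def gen_dimer_intensities(
    kd_dim: float = presets.DIMER_KD,
    c_tots: Sequence[float] = presets.DIMER_CONCENTRATIONS,
    residues: Sequence[str] = ("R28", "I29", "T32"),
    noise_frac: float = 0.0,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Monomer/dimer peak intensities under 2M <-> D mass action.

    Monomer intensity is proportional to [M], dimer intensity to the
    protomer concentration 2[D]; multiplicative Gaussian noise of relative
    SD ``noise_frac`` is applied per peak.  Returns a long DataFrame with
    columns (c_tot, residue, i_mono, i_dim).
    """
    rng = _rng(seed)
    rows = []
    for c_tot in c_tots:
        fm = monomer_fraction(kd_dim, c_tot)
        m = fm * c_tot
        d2 = c_tot - m  # 2[D]
        for res in residues:
            nm = 1.0 + (rng.normal(0.0, noise_frac) if noise_frac > 0 else 0.0)
            nd = 1.0 + (rng.normal(0.0, noise_frac) if noise_frac > 0 else 0.0)
            rows.append(
                {
                    "c_tot": c_tot,
                    "residue": res,
                    "i_mono": m * nm,
                    "i_dim": d2 * nd,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# docking pose clouds and surrogate backend
# ---------------------------------------------------------------------------

def gen_pose_cloud(
    template: np.ndarray,
    spread_sigma: float,
    n_runs: int = 3,
    poses_per_run: int = 6,
    ligand_label: str = "ligand",
    charge_classes: Sequence[str] | None = None,
    score_model: Callable[[Pose], float] | None = None,
    run_offsets: Sequence[Sequence[float]] | None = None,
    seed: int | None = 0,
) -> PoseSet:
    """Poses scattered around a template with isotropic Gaussian displacements.

    Each atom of each pose is the template coordinate plus N(0, sigma^2)
    noise per Cartesian component; optional rigid per-run offsets model
    docking runs that settle in different sub-sites.  Scores default to the
    negative mean displacement from the template (tighter pose = higher
    score) unless a score model is supplied.
    """
    if spread_sigma < 0:
        raise ValueError("spread sigma cannot be negative")
    rng = _rng(seed)
    template = np.asarray(template, dtype=float)
    n_atoms = template.shape[0]
    if charge_classes is None:
        charge_classes = ["sulfate_O"] * n_atoms
    poses = []
    for run in range(n_runs):
        offset = np.zeros(3)
        if run_offsets is not None:
            offset = np.asarray(run_offsets[run % len(run_offsets)], dtype=float)
        for _ in range(poses_per_run):
            coords = template + offset + rng.normal(0.0, spread_sigma, size=template.shape)
            atoms = tuple(
                PoseAtom(
                    name=f"A{i}", element="O", charge_class=charge_classes[i],
                    xyz=tuple(coords[i]),
                )
                for i in range(n_atoms)
            )
            pose = Pose(ligand_label=ligand_label, atoms=atoms, score=0.0, run_id=run)
            if score_model is not None:
                score = float(score_model(pose))
            else:
                score = -float(np.mean(np.linalg.norm(coords - template, axis=1)))
            poses.append(
                Pose(ligand_label=ligand_label, atoms=atoms, score=score, run_id=run)
            )
    return PoseSet(ligand_label, poses)


class SurrogateDockingBackend:
    """Deterministic pose supplier that stands in for an external docking engine.

    For each ligand it derives a pseudo-structure from the sequence (one
    anionic oxygen per sulfate, one carboxylate oxygen per uronic acid, one
    ring centroid per unit) laid out near the site centre, perturbs poses
    with a configurable per-ligand spatial spread, and scores them with the
    distance-weighted surrogate scorer against the site's basic atoms.
    Identical (ligand, site, run, seed) inputs give identical poses.
    """

    def __init__(
        self,
        protein_basic_atoms: Sequence[tuple[str, Sequence[float]]],
        spread_sigma: float = 0.5,
        per_ligand_sigma: Mapping[str, float] | None = None,
        fail_labels: Sequence[str] = (),
    ) -> None:
        self.protein_basic_atoms = list(protein_basic_atoms)
        self.spread_sigma = spread_sigma
        self.per_ligand_sigma = dict(per_ligand_sigma or {})
        self.fail_labels = set(fail_labels)

    def _template(self, sequence, site: SiteDefinition) -> tuple[np.ndarray, list[str]]:
        from .glycan import Base, format_sequence, sequence_properties

        center = np.asarray(site.center, dtype=float)
        coords: list[np.ndarray] = []
        classes: list[str] = []
        # deterministic per-ligand layout seeded by the notation string
        label_seed = abs(hash_stable(format_sequence(sequence))) % (2**31)
        lrng = np.random.default_rng(label_seed)
        for i, unit in enumerate(sequence.units):
            base_pos = center + np.array([1.5 * i, 0.0, 0.0]) + lrng.normal(0, 0.3, 3)
            coords.append(base_pos)
            classes.append("ring")
            for _ in range(unit.n_sulfates):
                coords.append(base_pos + lrng.normal(0, 0.8, 3))
                classes.append("sulfate_O")
            if unit.base is Base.IDOA:
                coords.append(base_pos + lrng.normal(0, 0.8, 3))
                classes.append("carboxylate_O")
        return np.array(coords), classes

    def dock(
        self,
        sequence,
        site: SiteDefinition,
        run_id: int,
        n_poses: int,
        seed: int,
    ) -> list[Pose]:
        from .glycan import format_sequence

        label = sequence.label or format_sequence(sequence)
        if label in self.fail_labels:
            raise RuntimeError(f"surrogate backend configured to fail for {label}")
        sigma = self.per_ligand_sigma.get(label, self.spread_sigma)
        template, classes = self._template(sequence, site)
        pose_seed = (
            abs(hash_stable(f"{label}|{site.name}|{run_id}|{seed}")) % (2**31)
        )
        rng = np.random.default_rng(pose_seed)
        poses = []
        for _ in range(n_poses):
            coords = template + rng.normal(0.0, sigma, size=template.shape)
            atoms = tuple(
                PoseAtom(name=f"A{i}", element="O", charge_class=classes[i],
                         xyz=tuple(coords[i]))
                for i in range(len(classes))
            )
            pose = Pose(ligand_label=label, atoms=atoms, score=0.0, run_id=run_id)
            score = surrogate_score(pose, site, self.protein_basic_atoms)
            poses.append(
                Pose(ligand_label=label, atoms=atoms, score=score, run_id=run_id)
            )
        return poses


def hash_stable(text: str) -> int:
    """Process-independent 64-bit string hash (FNV-1a)."""
    h = 0xCBF29CE484222325
    for byte in text.encode():
        h ^= byte
        h = (h * 0x100000001B3) % (1 << 64)
    return h


# ---------------------------------------------------------------------------
# MD event/energy tables
# ---------------------------------------------------------------------------

def gen_hbond_events(
    occupancy: float | Mapping[str, float],
    n_frames: int = 1000,
    n_runs: int = 1,
    residue: str = "R64",
    seed: int | None = 0,
) -> list[EventSeries]:
    """Independent Bernoulli(p) H-bond event series per residue and run."""
    rng = _rng(seed)
    probs = occupancy if isinstance(occupancy, Mapping) else {residue: occupancy}
    out = []
    for res, p in probs.items():
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"occupancy for {res} must lie in [0, 1]")
        for run in range(n_runs):
            frames = tuple(int(x) for x in (rng.random(n_frames) < p))
            out.append(EventSeries(residue=res, frames=frames, run_id=run))
    return out


def gen_residue_energies(
    means: Mapping[str, float],
    sd: float = 0.0,
    n_frames: int = 500,
    n_runs: int = 1,
    seed: int | None = 0,
) -> dict[str, list[list[float]]]:
    """Gaussian per-frame interaction energies around per-residue means (kcal/mol)."""
    if sd < 0:
        raise ValueError("sd cannot be negative")
    rng = _rng(seed)
    out: dict[str, list[list[float]]] = {}
    for res, mu in means.items():
        runs = []
        for _ in range(n_runs):
            series = mu + (rng.normal(0.0, sd, n_frames) if sd > 0 else np.zeros(n_frames))
            runs.append([float(v) for v in series])
        out[res] = runs
    return out


# ---------------------------------------------------------------------------
# 15N relaxation
# ---------------------------------------------------------------------------

def gen_relaxation(
    tau_c_ns: float,
    nu_n: float = presets.NU_N_DEFAULT,
    n_residues: int = 20,
    t1_base: float = 0.65,
    noise_frac: float = 0.0,
    seed: int | None = 0,
) -> list[RelaxationRecord]:
    """Relaxation records whose T1/T2 ratio encodes the requested tau_c.

    The exact inverse of the T1/T2 correlation-time estimator:
    T1/T2 = (7 + (4*pi*nu_N*tau_c)^2)/6, split into a plausible T1 and the
    implied T2, with multiplicative Gaussian noise applied to both.
    """
    if tau_c_ns < 0:
        raise ValueError("tau_c cannot be negative")
    rng = _rng(seed)
    ratio = (7.0 + (4.0 * math.pi * nu_n * tau_c_ns * 1e-9) ** 2) / 6.0
    out = []
    for i in range(n_residues):
        n1 = 1.0 + (rng.normal(0.0, noise_frac) if noise_frac > 0 else 0.0)
        n2 = 1.0 + (rng.normal(0.0, noise_frac) if noise_frac > 0 else 0.0)
        t1 = t1_base * n1
        t2 = (t1_base / ratio) * n2
        out.append(
            RelaxationRecord(residue=f"G{i + 1}", t1=t1, t2=t2, nu_n=nu_n)
        )
    return out
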