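"""Dual-filter virtual-screen selection of docked oligosaccharide poses.

Combinatorial virtual library screening (CVLS) docks every enumerated
oligosaccharide against a defined protein binding site and selects binders by
two orthogonal criteria:

* *affinity* — the docking score, ranked and cut at a top fraction
  (default the top 10%);
* *specificity* — the consistency of the poses returned by repeated
  (triplicate) docking runs, quantified as the mean pairwise RMSD among the
  best-scoring poses; ligands whose poses cluster within 2.5 Å are called
  "specific".

An optional hydrogen-bond filter then requires contacts between the ligand's
anionic oxygens (sulfate/carboxylate) and polar atoms of the site's key basic
residues.  The docking engine itself is pluggable: any object with a
``dock(sequence, site, run_id, n_poses, seed)`` method returning scored poses
can drive the pipeline, and a distance-based surrogate backend is provided so
the whole pipeline runs without an external docking program.

RMSD here is computed in the fixed receptor frame with no re-superposition:
poses are docked into the same site, so rigid displacement between poses is
signal, not alignment noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Protocol, Sequence

import numpy as np
import pandas as pd

from .glycan import OligoSequence, format_sequence

__all__ = [
    "SiteDefinition",
    "Pose",
    "PoseSet",
    "ScreenConfig",
    "LigandRecord",
    "ScreenReport",
    "rank_top_fraction",
    "rmsd_pair",
    "pose_consistency",
    "hbond_contacts",
    "surrogate_score",
    "run_screen",
    "poses_to_csv",
    "poses_from_csv",
]

ANIONIC_CLASSES = ("sulfate_O", "carboxylate_O")


@dataclass(frozen=True)
class SiteDefinition:
    """A protein binding site: named key residues around a centre of given radius."""

    name: str
    key_residues: tuple[str, ...]
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius: float = 16.0

    def __post_init__(self) -> None:
        if not self.key_residues:
            raise ValueError("key_residues must be non-empty")
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        object.__setattr__(self, "key_residues", tuple(self.key_residues))
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))


@dataclass(frozen=True)
class PoseAtom:
    name: str
    element: str
    charge_class: str  # sulfate_O | carboxylate_O | ring | other
    xyz: tuple[float, float, float]


@dataclass(frozen=True)
class Pose:
    """A single scored docking solution for one ligand."""

    ligand_label: str
    atoms: tuple[PoseAtom, ...]
    score: float
    run_id: int = 0

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("pose must contain at least one atom")
        coords = self.coords
        if not np.all(np.isfinite(coords)):
            raise ValueError("pose coordinates must be finite")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def anionic_coords(self) -> np.ndarray:
        pts = [a.xyz for a in self.atoms if a.charge_class in ANIONIC_CLASSES]
        return np.array(pts, dtype=float).reshape(-1, 3)


@dataclass
class PoseSet:
    """All poses for one ligand, possibly pooled from several docking runs."""

    ligand_label: str
    poses: list[Pose]

    def __post_init__(self) -> None:
        counts = {len(p.atoms) for p in self.poses}
        if len(counts) > 1:
            raise ValueError("all poses in a PoseSet must share the atom count")

    def top_poses(self, k: int) -> list[Pose]:
        """The k highest-scoring poses pooled over runs (score desc, run/order tiebreak)."""
        if len(self.poses) < k:
            raise ValueError(
                f"need at least {k} poses, got {len(self.poses)} for {self.ligand_label}"
            )
        indexed = sorted(
            enumerate(self.poses), key=lambda t: (-t[1].score, t[1].run_id, t[0])
        )
        return [p for _, p in indexed[:k]]


@dataclass(frozen=True)
class ScreenConfig:
    """Tunables of the dual-filter screen."""

    top_fraction: float = 0.10
    n_runs: int = 3
    top_k_poses: int = 6
    rmsd_specific_threshold: float = 2.5
    rmsd_aggregate: str = "mean"  # "mean" over all pairs, or "max"
    pose_selection: str = "pooled"  # "pooled" top-k or "per_run" (k/n_runs each)
    hbond_distance_cutoff: float = 3.5
    hbond_required: bool = True
    min_hbond_residues: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must be in (0, 1]")
        if self.rmsd_specific_threshold <= 0:
            raise ValueError("rmsd_specific_threshold must be positive")
        if self.rmsd_aggregate not in ("mean", "max"):
            raise ValueError("rmsd_aggregate must be 'mean' or 'max'")
        if self.pose_selection not in ("pooled", "per_run"):
            raise ValueError("pose_selection must be 'pooled' or 'per_run'")


def rank_top_fraction(
    scores: Sequence[tuple[str, float]], fraction: float
) -> list[str]:
    """Labels of the round(n*fraction) highest-scoring entries.

    Ties at the cut are broken lexicographically by label so the selection is
    deterministic.  Uses banker's-free half-up rounding on n*fraction.
    """
    if not scores:
        raise ValueError("empty score list")
    labels = [lab for lab, _ in scores]
    if len(set(labels)) != len(labels):
        raise ValueError("ligand labels must be unique")
    for lab, s in scores:
        if not math.isfinite(s):
            raise ValueError(f"non-finite score for {lab}")
    n_keep = int(math.floor(len(scores) * fraction + 0.5))
    n_keep = max(min(n_keep, len(scores)), 0)
    ranked = sorted(scores, key=lambda t: (-t[1], t[0]))
    return [lab for lab, _ in ranked[:n_keep]]


def rmsd_pair(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between two coordinate sets, no superposition."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    d = a - b
    return float(np.sqrt(np.mean(np.sum(d * d, axis=-1))))


def _select_poses(pose_set: PoseSet, config: ScreenConfig) -> list[Pose]:
    if config.pose_selection == "pooled":
        return pose_set.top_poses(config.top_k_poses)
    # per-run: equal share of the best poses from each run
    per_run = config.top_k_poses // config.n_runs
    if per_run * config.n_runs != config.top_k_poses:
        raise ValueError("top_k_poses must divide evenly across runs in per_run mode")
    out: list[Pose] = []
    run_ids = sorted({p.run_id for p in pose_set.poses})
    for rid in run_ids[: config.n_runs]:
        run_poses = [p for p in pose_set.poses if p.run_id == rid]
        out.extend(PoseSet(pose_set.ligand_label, run_poses).top_poses(per_run))
    if len(out) < config.top_k_poses:
        raise ValueError("not enough runs/poses for per_run selection")
    return out


def pose_consistency(pose_set: PoseSet, config: ScreenConfig) -> dict:
    """Consistency RMSD among the best poses, and the "specific" call.

    The top ``top_k_poses`` highest-scoring poses (pooled across runs by
    default) are compared pairwise in the receptor frame; the aggregate
    (mean over all pairs by default) is compared against the specificity
    threshold.  Invariant to the order poses are supplied in.
    """
    top = _select_poses(pose_set, config)
    coords = [p.coords for p in top]
    pair_rmsds = [
        rmsd_pair(coords[i], coords[j])
        for i in range(len(coords))
        for j in range(i + 1, len(coords))
    ]
    agg = max(pair_rmsds) if config.rmsd_aggregate == "max" else float(
        np.mean(pair_rmsds)
    )
    return {
        "rmsd": agg,
        "specific": bool(agg < config.rmsd_specific_threshold),
        "n_pairs": len(pair_rmsds),
    }


def hbond_contacts(
    pose: Pose,
    site: SiteDefinition,
    protein_polar_atoms: Sequence[tuple[str, Sequence[float]]],
    distance_cutoff: float = 3.5,
) -> list[tuple[str, int]]:
    """Count ligand-anion/protein-polar contacts within the cutoff, per residue.

    ``protein_polar_atoms`` is a list of (residue id, xyz) for H-bond capable
    protein atoms (e.g. Arg guanidinium N, Lys NZ).  Poses whose centroid
    falls outside the site radius are still evaluated (the site check is the
    caller's warning, not a hard error).
    """
    if not protein_polar_atoms:
        raise ValueError("protein polar atom list is empty")
    lig = pose.anionic_coords()
    counts: dict[str, int] = {}
    if lig.size:
        for resid, xyz in protein_polar_atoms:
            p = np.asarray(xyz, dtype=float)
            d = np.linalg.norm(lig - p, axis=1)
            n = int(np.sum(d <= distance_cutoff))
            if n:
                counts[resid] = counts.get(resid, 0) + n
    return sorted(counts.items())


def surrogate_score(
    pose: Pose,
    site: SiteDefinition,
    protein_basic_atoms: Sequence[tuple[str, Sequence[float]]],
) -> float:
    """Distance-weighted electrostatic-contact score for a docked pose.

    Sums 1/(1 + d) over every (ligand anionic atom, protein basic atom) pair,
    with d in Å, so the score strictly increases as any pair approaches.  A
    deliberately simple stand-in for a docking scoring function, used to
    exercise the screening pipeline end to end.
    """
    lig = pose.anionic_coords()
    if lig.size == 0 or not protein_basic_atoms:
        return 0.0
    prot = np.array([xyz for _, xyz in protein_basic_atoms], dtype=float)
    d = np.linalg.norm(lig[:, None, :] - prot[None, :, :], axis=2)
    return float(np.sum(1.0 / (1.0 + d)))


class DockingBackend(Protocol):  # pragma: no cover - interface definition
    def dock(
        self,
        sequence: OligoSequence,
        site: SiteDefinition,
        run_id: int,
        n_poses: int,
        seed: int,
    ) -> list[Pose]:
        ...


@dataclass
class LigandRecord:
    """Everything the screen measured for one ligand at one site."""

    label: str
    site: str
    best_score: float | None = None
    ranked: bool = False
    rmsd: float | None = None
    specific: bool | None = None
    contacted_residues: list[tuple[str, int]] = field(default_factory=list)
    n_hbonds: int = 0
    passed_hbond_filter: bool | None = None
    shortlisted: bool = False
    error: str | None = None

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["contacted_residues"] = list(self.contacted_residues)
        return d


@dataclass
class ScreenReport:
    """Per-ligand records plus the final shortlist, serialisable to CSV/JSON."""

    site: str
    config: ScreenConfig
    records: list[LigandRecord]

    @property
    def shortlist(self) -> list[str]:
        return [r.label for r in self.records if r.shortlisted]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            d = r.to_dict()
            d["contacted_residues"] = ";".join(
                f"{res}:{n}" for res, n in r.contacted_residues
            )
            rows.append(d)
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "site": self.site,
            "config": self.config.__dict__,
            "records": [r.to_dict() for r in self.records],
            "shortlist": self.shortlist,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, csv_path=None, json_path=None) -> None:
        if csv_path is not None:
            self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                fh.write(self.to_json())


def run_screen(
    library: Sequence[OligoSequence],
    backend: DockingBackend,
    site: SiteDefinition,
    config: ScreenConfig = ScreenConfig(),
    protein_polar_atoms: Sequence[tuple[str, Sequence[float]]] | None = None,
    seed: int = 0,
    poses_per_run: int | None = None,
) -> ScreenReport:
    """Run the full dual-filter screen over a ligand library at one site.

    Pipeline: single-run dock and score everything; keep the top fraction by
    best score; re-dock the shortlist in ``n_runs`` runs; compute pose
    consistency; apply the hydrogen-bond filter (if polar atoms are given and
    ``hbond_required``).  Backend failures for individual ligands are recorded
    and the screen continues.  Fully deterministic for a deterministic
    backend and fixed seed.
    """
    n_poses = poses_per_run or config.top_k_poses
    records = {
        (seq.label or format_sequence(seq)): LigandRecord(
            label=seq.label or format_sequence(seq), site=site.name
        )
        for seq in library
    }
    if len(records) != len(library):
        raise ValueError("ligand labels must be unique in the library")

    # stage 1: initial dock + score
    scored: list[tuple[str, float]] = []
    pose_cache: dict[str, list[Pose]] = {}
    for seq in library:
        label = seq.label or format_sequence(seq)
        rec = records[label]
        try:
            poses = backend.dock(seq, site, run_id=0, n_poses=n_poses, seed=seed)
        except Exception as exc:  # noqa: BLE001 - per-ligand isolation by contract
            rec.error = f"docking failed: {exc}"
            continue
        if not poses:
            rec.error = "docking returned no poses"
            continue
        rec.best_score = max(p.score for p in poses)
        pose_cache[label] = poses
        scored.append((label, rec.best_score))

    if not scored:
        raise ValueError("no ligand was successfully docked")

    # stage 2: top-fraction ranking
    shortlist = rank_top_fraction(scored, config.top_fraction)
    for label in shortlist:
        records[label].ranked = True

    # stage 3: triplicate re-dock + consistency + H-bond filter
    seq_by_label = {
        (seq.label or format_sequence(seq)): seq for seq in library
    }
    for label in shortlist:
        rec = records[label]
        seq = seq_by_label[label]
        try:
            poses: list[Pose] = []
            for run_id in range(1, config.n_runs + 1):
                poses.extend(
                    backend.dock(
                        seq, site, run_id=run_id, n_poses=n_poses,
                        seed=seed + run_id,
                    )
                )
            consistency = pose_consistency(PoseSet(label, poses), config)
        except Exception as exc:  # noqa: BLE001
            rec.error = f"re-docking failed: {exc}"
            continue
        rec.rmsd = consistency["rmsd"]
        rec.specific = consistency["specific"]

        if protein_polar_atoms:
            best = PoseSet(label, poses).top_poses(1)[0]
            contacts = hbond_contacts(
                best, site, protein_polar_atoms, config.hbond_distance_cutoff
            )
            rec.contacted_residues = contacts
            rec.n_hbonds = sum(n for _, n in contacts)
            rec.passed_hbond_filter = (
                len(contacts) >= config.min_hbond_residues
            )
        hb_ok = (
            rec.passed_hbond_filter
            if (config.hbond_required and protein_polar_atoms)
            else True
        )
        rec.shortlisted = bool(rec.specific and hb_ok)

    ordered = [records[seq.label or format_sequence(seq)] for seq in library]
    return ScreenReport(site=site.name, config=config, records=ordered)


# ---------------------------------------------------------------------------
# pose I/O: CSV with one row per atom
# ---------------------------------------------------------------------------

def poses_to_csv(pose_set: PoseSet, path) -> None:
    rows = []
    for pose_id, pose in enumerate(pose_set.poses):
        for atom in pose.atoms:
            rows.append(
                {
                    "ligand": pose.ligand_label,
                    "run_id": pose.run_id,
                    "pose_id": pose_id,
                    "atom": atom.name,
                    "element": atom.element,
                    "charge_class": atom.charge_class,
                    "x": atom.xyz[0],
                    "y": atom.xyz[1],
                    "z": atom.xyz[2],
                    "score": pose.score,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def poses_from_csv(path) -> PoseSet:
    df = pd.read_csv(path)
    poses = []
    label = str(df["ligand"].iloc[0])
    for (_, pose_id), grp in df.groupby(["run_id", "pose_id"], sort=True):
        atoms = tuple(
            PoseAtom(
                name=str(r.atom),
                element=str(r.element),
                charge_class=str(r.charge_class),
                xyz=(float(r.x), float(r.y), float(r.z)),
            )
            for r in grp.itertuples()
        )
        poses.append(
            Pose(
                ligand_label=label,
                atoms=atoms,
                score=float(grp["score"].iloc[0]),
                run_id=int(grp["run_id"].iloc[0]),
            )
        )
    return PoseSet(label, poses)
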