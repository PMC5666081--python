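"""Occupancy and energy summaries of trajectory-derived interaction tables.

Molecular-dynamics post-processing reduces a trajectory to per-frame event
and energy tables; this module turns those tables into the standard
summaries:

* hydrogen-bond occupancy — the fraction of frames in which a residue forms
  at least one inter-molecular H-bond with the ligand, averaged with equal
  weight across independent runs, and classified as *persistent* (> 50%),
  *transient* (20–50%) or *negligible* (< 20%);
* water-bridge occupancy — the fraction of frames in which at least one
  water molecule is simultaneously H-bonded to a residue and to the ligand;
* single-residue energy decomposition (SERD) summaries — per-residue mean
  interaction energy with SD, ranked by most-favourable (most negative) mean;
* total binding free-energy summaries over independent runs (mean, sample
  SD).

Energies are consumed, never computed: force-field evaluation belongs to the
simulation engine; this module owns only the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HBondCriteria",
    "EventSeries",
    "classify_occupancy",
    "hbond_occupancy",
    "water_bridge_occupancy",
    "serd_summary",
    "binding_energy_summary",
    "site_occupancy_aggregate",
    "events_from_csv",
    "energies_from_csv",
]

PERSISTENT_THRESHOLD = 0.5
TRANSIENT_THRESHOLD = 0.2


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition (applied only to raw geometry inputs)."""

    donor_acceptor_cutoff: float = 3.5  # Å
    angle_cutoff: float = 30.0  # degrees deviation from D-H...A linearity

    def __post_init__(self) -> None:
        if self.donor_acceptor_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")
        if not (0 < self.angle_cutoff <= 90):
            raise ValueError("angle cutoff must be in (0, 90]")


@dataclass(frozen=True)
class EventSeries:
    """Per-frame interaction events for one residue in one run.

    ``frames`` holds booleans or per-frame bond counts; occupancy counts a
    frame as occupied when at least one bond is present, regardless of
    multiplicity.
    """

    residue: str
    frames: tuple[int, ...]
    run_id: int = 0

    def __post_init__(self) -> None:
        frames = tuple(int(bool(f)) if isinstance(f, bool) else int(f) for f in self.frames)
        if len(frames) == 0:
            raise ValueError(f"empty frame series for residue {self.residue}")
        if any(f < 0 for f in frames):
            raise ValueError("bond counts must be non-negative")
        object.__setattr__(self, "frames", frames)

    @property
    def occupancy(self) -> float:
        present = sum(1 for f in self.frames if f >= 1)
        return present / len(self.frames)


def classify_occupancy(occupancy: float) -> str:
    """Persistent (> 0.5), transient ([0.2, 0.5]) or negligible (< 0.2)."""
    if occupancy > PERSISTENT_THRESHOLD:
        return "persistent"
    if occupancy >= TRANSIENT_THRESHOLD:
        return "transient"
    return "negligible"


def hbond_occupancy(series: Iterable[EventSeries]) -> pd.DataFrame:
    """Average per-residue H-bond occupancy across runs, with class labels.

    Runs are weighted equally regardless of length.  Returns a DataFrame
    indexed by residue with columns ``occupancy``, ``class`` and ``n_runs``.
    """
    series = list(series)
    if not series:
        raise ValueError("no event series supplied")
    per_res: dict[str, list[float]] = {}
    for s in series:
        per_res.setdefault(s.residue, []).append(s.occupancy)
    rows = {
        res: {
            "occupancy": float(np.mean(occs)),
            "class": classify_occupancy(float(np.mean(occs))),
            "n_runs": len(occs),
        }
        for res, occs in per_res.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "residue"
    return df


def water_bridge_occupancy(
    frames: Sequence[Sequence[tuple[str, str, bool, bool]]],
    residues: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Occupancy of water-mediated residue-ligand bridges.

    ``frames`` is a sequence over trajectory frames; each frame is a list of
    water contact records ``(water_id, residue, bonded_to_residue,
    bonded_to_ligand)``.  A residue is bridged in a frame when at least one
    water is simultaneously H-bonded to that residue and to the ligand.  With
    no waters at all, every listed residue gets occupancy 0.
    """
    all_res = set(residues or [])
    for frame in frames:
        for _, res, *_ in frame:
            all_res.add(res)
    counts = {res: 0 for res in sorted(all_res)}
    for frame in frames:
        bridged = {
            res
            for _, res, to_res, to_lig in frame
            if to_res and to_lig
        }
        for res in bridged:
            counts[res] += 1
    n = len(frames)
    rows = {
        res: {
            "occupancy": (c / n if n else 0.0),
            "class": classify_occupancy(c / n if n else 0.0),
        }
        for res, c in counts.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    if df.empty:
        df = pd.DataFrame(columns=["occupancy", "class"])
    df.index.name = "residue"
    return df.sort_index()


def serd_summary(
    energy_series: Mapping[str, Sequence[Sequence[float]] | Sequence[float]],
    top_n: int = 5,
) -> pd.DataFrame:
    """Per-residue mean +/- SD interaction energy and anchor ranking.

    ``energy_series`` maps residue -> per-frame energies (kcal/mol), either a
    single run (flat sequence) or several runs (sequence of sequences); runs
    are averaged with equal weight, frames within a run with equal weight.
    Residues are ranked by most-negative mean (rank 1 = top anchor).  The SD
    is the sample SD over all frames pooled across runs.
    """
    rows = {}
    for res, series in energy_series.items():
        runs = (
            [np.asarray(series, dtype=float)]
            if np.ndim(series[0]) == 0
            else [np.asarray(r, dtype=float) for r in series]
        )
        for r in runs:
            if not np.all(np.isfinite(r)):
                raise ValueError(f"non-finite energy for residue {res}")
        mean = float(np.mean([r.mean() for r in runs]))
        pooled = np.concatenate(runs)
        sd = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0
        rows[res] = {"mean": mean, "sd": sd, "n_frames": int(pooled.size)}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "residue"
    df = df.sort_index().sort_values("mean", kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    df["anchor"] = (df["rank"] <= top_n) & (df["mean"] < 0)
    return df


def binding_energy_summary(run_totals: Sequence[float]) -> dict:
    """Mean and sample SD of total binding free energy across runs.

    A single run returns the mean with SD flagged undefined (NaN).
    """
    totals = np.asarray(run_totals, dtype=float)
    if totals.size == 0:
        raise ValueError("no run totals supplied")
    if not np.all(np.isfinite(totals)):
        raise ValueError("non-finite run total")
    mean = float(totals.mean())
    if totals.size == 1:
        return {"mean": mean, "sd": float("nan"), "n_runs": 1, "sd_defined": False}
    return {
        "mean": mean,
        "sd": float(totals.std(ddof=1)),
        "n_runs": int(totals.size),
        "sd_defined": True,
    }


def site_occupancy_aggregate(
    occupancy: pd.DataFrame, residues: Sequence[str]
) -> dict:
    """Sum and mean of residue occupancies over one site's residue group.

    Both aggregates are reported because either convention can be meant by a
    statement that one site's "overall occupancy" exceeds another's.
    """
    present = [r for r in residues if r in occupancy.index]
    vals = occupancy.loc[present, "occupancy"].to_numpy(dtype=float)
    return {
        "sum": float(vals.sum()) if vals.size else 0.0,
        "mean": float(vals.mean()) if vals.size else 0.0,
        "n_residues": len(present),
    }


# ---------------------------------------------------------------------------
# CSV ingestion: (run_id, frame, residue, value) long format
# ---------------------------------------------------------------------------

def events_from_csv(path) -> list[EventSeries]:
    """Read H-bond event series from long CSV (run_id, frame, residue, value)."""
    df = pd.read_csv(path)
    out = []
    for (run_id, residue), grp in df.groupby(["run_id", "residue"], sort=True):
        grp = grp.sort_values("frame")
        out.append(
            EventSeries(
                residue=str(residue),
                frames=tuple(int(v) for v in grp["value"]),
                run_id=int(run_id),
            )
        )
    return out


def energies_from_csv(path) -> dict[str, list[list[float]]]:
    """Read per-residue energy series from long CSV (run_id, frame, residue, value)."""
    df = pd.read_csv(path)
    out: dict[str, list[list[float]]] = {}
    for (_, residue), grp in df.groupby(["run_id", "residue"], sort=True):
        grp = grp.sort_values("frame")
        out.setdefault(str(residue), []).append([float(v) for v in grp["value"]])
    return out
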