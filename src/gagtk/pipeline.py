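"""Multi-stage pipeline runner behind the command-line interface.

A pipeline config (YAML or JSON) lists stages executed in order; simulation
stages write CSV inputs, analysis stages read them and contribute numeric
results to a JSON summary that also records package version, the master
seed, and a checksum per written file.  One master seed fans out to
per-stage sub-seeds by stable string hashing, so any stage can be re-run
alone with the same randomness.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__, md_occupancy, nmr, presets, spr, synthetic

__all__ = ["PipelineError", "ConfigError", "stage_seed", "run_pipeline", "load_config"]

#: distinct exit codes: 2 config error, 3 data/stage error
EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3


class PipelineError(RuntimeError):
    """A stage failed on its data."""


class ConfigError(ValueError):
    """The pipeline configuration is invalid."""


def stage_seed(master_seed: int, stage_name: str) -> int:
    """Deterministic per-stage sub-seed derived from the master seed."""
    return synthetic.hash_stable(f"{master_seed}:{stage_name}") % (2**31)


def load_config(path: str | Path) -> dict:
    import yaml

    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError("pipeline config must be a mapping")
    return cfg


_KNOWN_TOP_KEYS = {"seed", "out_dir", "stages", "log_level"}
_KNOWN_STAGE_KEYS = {"kind", "name", "params", "input", "out"}

_SIMULATE_KINDS = {
    "sensorgram_set",
    "dimer_intensities",
    "hbond_events",
    "residue_energies",
    "relaxation",
}
_ANALYSIS_KINDS = {
    "spr_fit_kinetics",
    "spr_fit_steady_state",
    "nmr_dimer_kd",
    "nmr_tauc",
    "occupancy_hbond",
    "energy_serd",
}


def _validate(cfg: dict) -> None:
    unknown = set(cfg) - _KNOWN_TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    stages = cfg.get("stages")
    if not isinstance(stages, list) or not stages:
        raise ConfigError("config requires a non-empty 'stages' list")
    for i, stage in enumerate(stages):
        if not isinstance(stage, dict):
            raise ConfigError(f"stage {i} must be a mapping")
        unknown = set(stage) - _KNOWN_STAGE_KEYS
        if unknown:
            raise ConfigError(f"stage {i}: unknown key(s): {sorted(unknown)}")
        kind = stage.get("kind")
        if kind not in _SIMULATE_KINDS | _ANALYSIS_KINDS:
            raise ConfigError(f"stage {i}: unknown kind: {kind!r}")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _run_simulate(kind: str, params: dict, seed: int, out: Path) -> dict:
    if kind == "sensorgram_set":
        curves = synthetic.gen_sensorgrams(seed=seed, **params)
        spr.sensorgrams_to_csv(curves, out)
        return {"n_curves": len(curves)}
    if kind == "dimer_intensities":
        df = synthetic.gen_dimer_intensities(seed=seed, **params)
        df.to_csv(out, index=False)
        return {"n_rows": int(len(df))}
    if kind == "hbond_events":
        series = synthetic.gen_hbond_events(seed=seed, **params)
        rows = [
            {"run_id": s.run_id, "frame": i, "residue": s.residue, "value": v}
            for s in series
            for i, v in enumerate(s.frames)
        ]
        pd.DataFrame(rows).to_csv(out, index=False)
        return {"n_series": len(series)}
    if kind == "residue_energies":
        table = synthetic.gen_residue_energies(seed=seed, **params)
        rows = [
            {"run_id": run_id, "frame": i, "residue": res, "value": v}
            for res, runs in table.items()
            for run_id, series in enumerate(runs)
            for i, v in enumerate(series)
        ]
        pd.DataFrame(rows).to_csv(out, index=False)
        return {"n_residues": len(table)}
    if kind == "relaxation":
        recs = synthetic.gen_relaxation(seed=seed, **params)
        pd.DataFrame(
            [
                {"residue": r.residue, "t1": r.t1, "t2": r.t2, "nu_n": r.nu_n}
                for r in recs
            ]
        ).to_csv(out, index=False)
        return {"n_residues": len(recs)}
    raise ConfigError(f"unknown simulate kind {kind!r}")


def _run_analysis(kind: str, params: dict, input_path: Path) -> dict:
    if kind == "spr_fit_kinetics":
        curves = spr.sensorgrams_from_csv(input_path)
        fit = spr.fit_kinetics_global(curves, **params)
        return {
            "kon": fit.kon,
            "koff": fit.koff,
            "rmax": fit.rmax,
            "kd": fit.kd,
            "degenerate": fit.degenerate,
        }
    if kind == "spr_fit_steady_state":
        curves = spr.sensorgrams_from_csv(input_path)
        points = [spr.extract_req(sg, **params) for sg in curves]
        return spr.fit_steady_state(points)
    if kind == "nmr_dimer_kd":
        table = pd.read_csv(input_path)
        return {
            k: v for k, v in nmr.dimer_kd_from_table(table, **params).items()
            if k != "per_concentration"
        }
    if kind == "nmr_tauc":
        recs = nmr.relaxation_from_csv(input_path)
        results = [nmr.tau_c_and_mw(r, **params) for r in recs]
        tau = float(np.median([r["tau_c_ns"] for r in results]))
        mw = float(np.median([r["mw_kda_apparent"] for r in results]))
        return {"tau_c_ns_median": tau, "mw_kda_median": mw, "n_residues": len(results)}
    if kind == "occupancy_hbond":
        series = md_occupancy.events_from_csv(input_path)
        table = md_occupancy.hbond_occupancy(series)
        return {
            "occupancy": {res: float(row.occupancy) for res, row in table.iterrows()},
        }
    if kind == "energy_serd":
        energies = md_occupancy.energies_from_csv(input_path)
        table = md_occupancy.serd_summary(energies, **params)
        return {
            "mean": {res: float(row["mean"]) for res, row in table.iterrows()},
            "top_anchor": str(table.index[0]) if len(table) else None,
        }
    raise ConfigError(f"unknown analysis kind {kind!r}")


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages in order; return the summary dict.

    Raises :class:`ConfigError` for schema violations and
    :class:`PipelineError` for stage/data failures (missing inputs, fit
    errors); callers map these to distinct exit codes.
    """
    _validate(config)
    master_seed = int(config.get("seed", 0))
    base = Path(out_dir or config.get("out_dir", "."))
    base.mkdir(parents=True, exist_ok=True)

    summary: dict[str, Any] = {
        "version": __version__,
        "seed": master_seed,
        "stages": {},
        "files": {},
    }
    for i, stage in enumerate(config["stages"]):
        kind = stage["kind"]
        name = stage.get("name", f"{i:02d}_{kind}")
        params = dict(stage.get("params") or {})
        seed = stage_seed(master_seed, name)
        try:
            if kind in _SIMULATE_KINDS:
                out = base / (stage.get("out") or f"{name}.csv")
                result = _run_simulate(kind, params, seed, out)
                summary["files"][str(out.name)] = _checksum(out)
            else:
                input_rel = stage.get("input")
                if input_rel is None:
                    raise PipelineError(f"stage {name!r} requires an 'input' path")
                input_path = base / input_rel
                if not input_path.exists():
                    raise PipelineError(f"missing input: {input_path}")
                result = _run_analysis(kind, params, input_path)
        except (ConfigError, PipelineError):
            raise
        except Exception as exc:  # noqa: BLE001 - map to data error
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        summary["stages"][name] = {"kind": kind, "seed": seed, "result": result}
    return summary
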