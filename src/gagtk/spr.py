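"""1:1 Langmuir SPR binding: simulation, global kinetic fit, steady-state fit.

Surface plasmon resonance reports bound mass on a sensor surface in response
units (RU) as analyte flows over immobilised ligand.  For a single class of
independent sites (the 1:1 Langmuir model) the response obeys

    association:   R(t) = Req * (1 - exp(-(kon*C + koff) * t)),
                   Req  = Rmax * C / (C + K_D)
    dissociation:  R(t) = R_end * exp(-koff * (t - t_end))

with K_D = koff/kon.  Affinity can be determined two ways, which should
agree for a well-behaved 1:1 interaction:

* **kinetically** — fit kon and koff (shared across a concentration series
  in the global fit, or per curve with averaged rates) and take
  K_D = koff/kon;
* **at steady state** — fit the equilibrium responses Req(C) to the
  hyperbolic isotherm Req = Rmax*C/(K_D + C).

No mass-transport term is included: curves are assumed kinetically limited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "Sensorgram",
    "KineticParams",
    "IsothermPoint",
    "simulate_sensorgram",
    "fit_kinetics_global",
    "fit_kinetics_per_curve",
    "kd_from_rates",
    "fit_steady_state",
    "steady_state_response",
    "extract_req",
    "subtract_reference",
    "sensorgrams_to_csv",
    "sensorgrams_from_csv",
]


@dataclass
class Sensorgram:
    """One SPR binding curve at a single analyte concentration."""

    time: np.ndarray  # s
    response: np.ndarray  # RU
    concentration: float  # M
    t_assoc_start: float = 0.0
    t_assoc_end: float = 300.0
    t_dissoc_end: float = 600.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.shape != self.response.shape:
            raise ValueError("time and response must have the same length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (self.t_assoc_start < self.t_assoc_end <= self.t_dissoc_end):
            raise ValueError("association phase must precede dissociation")

    @property
    def association_mask(self) -> np.ndarray:
        return (self.time >= self.t_assoc_start) & (self.time <= self.t_assoc_end)

    @property
    def dissociation_mask(self) -> np.ndarray:
        return self.time > self.t_assoc_end


@dataclass(frozen=True)
class KineticParams:
    """Fitted (or generating) 1:1 rate constants; K_D = koff/kon by construction."""

    kon: float  # 1/(M s)
    koff: float  # 1/s
    rmax: float  # RU
    kon_stderr: float = float("nan")
    koff_stderr: float = float("nan")
    rmax_stderr: float = float("nan")
    residual_norm: float = float("nan")
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.kon <= 0 or self.koff <= 0 or self.rmax < 0:
            raise ValueError("rate constants must be positive, Rmax non-negative")

    @property
    def kd(self) -> float:
        return kd_from_rates(self.kon, self.koff)


@dataclass(frozen=True)
class IsothermPoint:
    concentration: float  # M
    req: float  # RU

    def __post_init__(self) -> None:
        if self.req < 0:
            raise ValueError("equilibrium response cannot be negative")


def kd_from_rates(kon: float, koff: float) -> float:
    """Equilibrium dissociation constant K_D = koff/kon (M)."""
    if kon <= 0:
        raise ValueError("kon must be positive")
    return koff / kon


def _model_response(
    t: np.ndarray,
    kon: float,
    koff: float,
    rmax: float,
    conc: float,
    t_assoc_start: float,
    t_assoc_end: float,
) -> np.ndarray:
    kd = koff / kon
    req = rmax * conc / (conc + kd) if conc > 0 else 0.0
    kobs = kon * conc + koff
    r = np.zeros_like(t)
    assoc = (t >= t_assoc_start) & (t <= t_assoc_end)
    r[assoc] = req * (1.0 - np.exp(-kobs * (t[assoc] - t_assoc_start)))
    r_end = req * (1.0 - math.exp(-kobs * (t_assoc_end - t_assoc_start)))
    dissoc = t > t_assoc_end
    r[dissoc] = r_end * np.exp(-koff * (t[dissoc] - t_assoc_end))
    return r


def simulate_sensorgram(
    params: KineticParams,
    concentration: float,
    t_assoc: float = 300.0,
    t_dissoc: float = 300.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Sensorgram:
    """Closed-form 1:1 Langmuir curve with optional additive Gaussian noise (RU)."""
    if concentration < 0:
        raise ValueError("concentration cannot be negative")
    t = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    r = _model_response(t, params.kon, params.koff, params.rmax, concentration, 0.0, t_assoc)
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng()
        r = r + rng.normal(0.0, noise_sd, size=r.shape)
    return Sensorgram(
        time=t,
        response=r,
        concentration=concentration,
        t_assoc_start=0.0,
        t_assoc_end=t_assoc,
        t_dissoc_end=t_assoc + t_dissoc,
    )


def subtract_reference(sample: Sensorgram, reference: Sensorgram) -> Sensorgram:
    """Subtract a control-surface curve point-by-point (times must match)."""
    if not np.allclose(sample.time, reference.time):
        raise ValueError("sample and reference time grids differ")
    return Sensorgram(
        time=sample.time.copy(),
        response=sample.response - reference.response,
        concentration=sample.concentration,
        t_assoc_start=sample.t_assoc_start,
        t_assoc_end=sample.t_assoc_end,
        t_dissoc_end=sample.t_dissoc_end,
    )


def _initial_guesses(sensorgrams: Sequence[Sensorgram]) -> tuple[float, float, float]:
    rmax0 = max(float(np.max(np.abs(sg.response))) for sg in sensorgrams)
    rmax0 = max(rmax0, 1e-6)
    # crude koff from the tail decay of the highest-concentration curve
    sg = max(sensorgrams, key=lambda s: s.concentration)
    mask = sg.dissociation_mask
    koff0 = 1e-3
    if np.count_nonzero(mask) > 3:
        td = sg.time[mask] - sg.t_assoc_end
        rd = sg.response[mask]
        pos = rd > max(rd.max() * 1e-3, 1e-9)
        if np.count_nonzero(pos) > 3:
            slope = np.polyfit(td[pos], np.log(rd[pos]), 1)[0]
            if slope < 0:
                koff0 = -slope
    c_mid = float(np.median([s.concentration for s in sensorgrams if s.concentration > 0]))
    kon0 = koff0 / c_mid if c_mid > 0 else 1e5
    return kon0, koff0, rmax0


def fit_kinetics_global(
    sensorgrams: Sequence[Sensorgram],
    kon_bounds: tuple[float, float] = (1e1, 1e9),
    koff_bounds: tuple[float, float] = (1e-6, 1e1),
) -> KineticParams:
    """Globally fit shared (kon, koff, Rmax) across a concentration series.

    All residuals are stacked into one least-squares problem, so every curve
    constrains the same three parameters.  Flat data (response range
    indistinguishable from zero) is flagged degenerate rather than fitted.
    """
    if len(sensorgrams) < 3:
        raise ValueError("global fit requires at least 3 concentrations")
    return _fit_shared(sensorgrams, kon_bounds, koff_bounds)


def _fit_shared(
    sensorgrams: Sequence[Sensorgram],
    kon_bounds: tuple[float, float] = (1e1, 1e9),
    koff_bounds: tuple[float, float] = (1e-6, 1e1),
) -> KineticParams:
    span = max(float(np.ptp(sg.response)) for sg in sensorgrams)
    if span <= 1e-9:
        return KineticParams(
            kon=1.0, koff=1.0, rmax=0.0, degenerate=True, residual_norm=0.0
        )

    kon0, koff0, rmax0 = _initial_guesses(sensorgrams)
    p = lmfit.Parameters()
    p.add("log_kon", value=math.log10(min(max(kon0, kon_bounds[0]), kon_bounds[1])),
          min=math.log10(kon_bounds[0]), max=math.log10(kon_bounds[1]))
    p.add("log_koff", value=math.log10(min(max(koff0, koff_bounds[0]), koff_bounds[1])),
          min=math.log10(koff_bounds[0]), max=math.log10(koff_bounds[1]))
    p.add("rmax", value=rmax0, min=0.0, max=rmax0 * 10)

    def residual(params: lmfit.Parameters) -> np.ndarray:
        kon = 10.0 ** params["log_kon"].value
        koff = 10.0 ** params["log_koff"].value
        rmax = params["rmax"].value
        res = []
        for sg in sensorgrams:
            model = _model_response(
                sg.time, kon, koff, rmax, sg.concentration,
                sg.t_assoc_start, sg.t_assoc_end,
            )
            res.append(sg.response - model)
        return np.concatenate(res)

    result = lmfit.minimize(residual, p, method="leastsq")
    kon = 10.0 ** result.params["log_kon"].value
    koff = 10.0 ** result.params["log_koff"].value
    rmax = result.params["rmax"].value

    def _stderr(name: str, value: float, log_scale: bool) -> float:
        err = result.params[name].stderr
        if err is None:
            return float("nan")
        return value * math.log(10) * err if log_scale else err

    return KineticParams(
        kon=kon,
        koff=koff,
        rmax=max(rmax, 1e-12),
        kon_stderr=_stderr("log_kon", kon, True),
        koff_stderr=_stderr("log_koff", koff, True),
        rmax_stderr=_stderr("rmax", rmax, False),
        residual_norm=float(np.linalg.norm(result.residual)),
    )


def fit_kinetics_per_curve(sensorgrams: Sequence[Sensorgram]) -> dict:
    """Fit each curve independently and report mean +/- SD of the rates.

    Mirrors instrument-software practice of fitting each concentration
    separately and averaging the rate constants.
    """
    fits = [_fit_shared([sg]) for sg in sensorgrams]
    kons = np.array([f.kon for f in fits])
    koffs = np.array([f.koff for f in fits])
    return {
        "kon_mean": float(kons.mean()),
        "kon_sd": float(kons.std(ddof=1)) if len(fits) > 1 else float("nan"),
        "koff_mean": float(koffs.mean()),
        "koff_sd": float(koffs.std(ddof=1)) if len(fits) > 1 else float("nan"),
        "kd_mean": float((koffs / kons).mean()),
        "per_curve": fits,
    }


# ---------------------------------------------------------------------------
# steady-state isotherm
# ---------------------------------------------------------------------------

def steady_state_response(c: np.ndarray, kd: float, rmax: float) -> np.ndarray:
    """Hyperbolic Langmuir isotherm Req = Rmax*C/(K_D + C)."""
    c = np.asarray(c, dtype=float)
    return rmax * c / (kd + c)


def extract_req(sg: Sensorgram, window: float = 10.0) -> IsothermPoint:
    """Equilibrium response as the mean over the last ``window`` s of association."""
    mask = (sg.time >= sg.t_assoc_end - window) & (sg.time <= sg.t_assoc_end)
    if not np.any(mask):
        raise ValueError("no samples in the late-association window")
    return IsothermPoint(
        concentration=sg.concentration, req=float(sg.response[mask].mean())
    )


def fit_steady_state(points: Sequence[IsothermPoint]) -> dict:
    """Least-squares fit of the steady-state isotherm; returns K_D, Rmax, flags.

    Requires at least 4 concentrations spanning more than a 4-fold range.
    A fit whose K_D lands above the highest tested concentration is flagged
    ill-conditioned (the plateau was never approached).
    """
    if len(points) < 4:
        raise ValueError("steady-state fit requires at least 4 concentrations")
    c = np.array([p.concentration for p in points], dtype=float)
    r = np.array([p.req for p in points], dtype=float)
    if c.max() / c.min() <= 4.0:
        raise ValueError("concentration range must span more than 4-fold")

    p = lmfit.Parameters()
    p.add("kd", value=float(np.median(c)), min=c.min() * 1e-4, max=c.max() * 1e4)
    p.add("rmax", value=float(r.max()) or 1.0, min=0.0)

    def residual(params: lmfit.Parameters) -> np.ndarray:
        return r - steady_state_response(c, params["kd"].value, params["rmax"].value)

    result = lmfit.minimize(residual, p, method="leastsq")
    kd = result.params["kd"].value
    rmax = result.params["rmax"].value
    return {
        "kd": float(kd),
        "rmax": float(rmax),
        "kd_stderr": float(result.params["kd"].stderr)
        if result.params["kd"].stderr is not None
        else float("nan"),
        "rmax_stderr": float(result.params["rmax"].stderr)
        if result.params["rmax"].stderr is not None
        else float("nan"),
        "ill_conditioned": bool(kd > c.max()),
        "residual_norm": float(np.linalg.norm(result.residual)),
    }


# ---------------------------------------------------------------------------
# CSV I/O: long format (time_s, response_RU, concentration_M, phase)
# ---------------------------------------------------------------------------

def sensorgrams_to_csv(sensorgrams: Sequence[Sensorgram], path) -> None:
    frames = []
    for sg in sensorgrams:
        phase = np.where(sg.time <= sg.t_assoc_end, "association", "dissociation")
        frames.append(
            pd.DataFrame(
                {
                    "time_s": sg.time,
                    "response_RU": sg.response,
                    "concentration_M": sg.concentration,
                    "phase": phase,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def sensorgrams_from_csv(path) -> list[Sensorgram]:
    df = pd.read_csv(path)
    out = []
    for conc, grp in df.groupby("concentration_M", sort=True):
        grp = grp.sort_values("time_s")
        assoc = grp[grp["phase"] == "association"]
        t_assoc_end = float(assoc["time_s"].max()) if len(assoc) else 300.0
        out.append(
            Sensorgram(
                time=grp["time_s"].to_numpy(),
                response=grp["response_RU"].to_numpy(),
                concentration=float(conc),
                t_assoc_start=float(grp["time_s"].min()),
                t_assoc_end=t_assoc_end,
                t_dissoc_end=float(grp["time_s"].max()),
            )
        )
    return out
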