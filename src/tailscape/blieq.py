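"""Biolayer-interferometry equilibrium analysis.

Sensorgrams are processed in the order a bench scientist would: reference
subtraction (single or double), alignment to the tail of the baseline
phase, Savitzky–Golay smoothing, extraction of the equilibrium response
r_eq as the mean of the last 20 s of the association phase, and finally a
hyperbolic single-site fit of r_eq against analyte concentration::

    r_eq = r0 + (rmax - r0) * x / (Kd + x)

Kinetic (kon/koff) fitting is deliberately out of scope: for fast 1:1
kinetics the association and dissociation transients carry little
information beyond the plateau, and the equilibrium analysis is the robust
route to Kd.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

__all__ = [
    "SensorGram",
    "EquilibriumCurve",
    "subtract_reference",
    "align_baseline",
    "sg_smooth",
    "equilibrium_response",
    "fit_equilibrium",
    "run_bli_analysis",
    "sensorgrams_to_csv",
    "sensorgrams_from_csv",
]

PHASES = ("baseline", "association", "dissociation")
SENSORGRAM_COLUMNS = ["channel_id", "role", "analyte_conc_uM", "phase",
                      "time_s", "response"]


@dataclass
class SensorGram:
    """One BLI channel: time series with phase labels.

    ``time`` is the global experiment clock (strictly increasing across
    the contiguous baseline → association → dissociation phases).
    """

    channel_id: str
    role: str                       # sample | reference | double_reference
    analyte_conc: float             # μM (0 for buffer-only reference)
    time: np.ndarray
    response: np.ndarray
    phase: np.ndarray               # str per sample point

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        self.phase = np.asarray(self.phase)
        if self.role not in ("sample", "reference", "double_reference"):
            raise ValueError(f"unknown channel role {self.role!r}")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        order = [p for p in PHASES if p in set(self.phase.tolist())]
        seen = list(dict.fromkeys(self.phase.tolist()))
        if seen != order:
            raise ValueError(
                "phases must be contiguous and ordered "
                "baseline -> association -> dissociation")

    def phase_mask(self, name: str) -> np.ndarray:
        return self.phase == name

    def with_response(self, response: np.ndarray) -> "SensorGram":
        return replace(self, response=np.asarray(response, dtype=float))


@dataclass
class EquilibriumCurve:
    concs: np.ndarray               # μM
    r_eq: np.ndarray
    kd: float = float("nan")
    r0: float = float("nan")
    rmax: float = float("nan")
    kd_se: float = float("nan")
    r0_se: float = float("nan")
    rmax_se: float = float("nan")
    converged: bool = False
    flags: dict = field(default_factory=dict)

    def to_report(self) -> dict:
        return {
            "kd_uM": self.kd, "kd_se_uM": self.kd_se,
            "r0": self.r0, "r0_se": self.r0_se,
            "rmax": self.rmax, "rmax_se": self.rmax_se,
            "converged": self.converged,
            "r_eq": [{"conc_uM": float(c), "r_eq": float(r),
                      **({"flag": self.flags[float(c)]}
                         if float(c) in self.flags else {})}
                     for c, r in zip(self.concs, self.r_eq)],
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_report(), indent=2))


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def sensorgrams_to_csv(grams: Iterable[SensorGram], path) -> None:
    frames = []
    for g in grams:
        frames.append(pd.DataFrame({
            "channel_id": g.channel_id, "role": g.role,
            "analyte_conc_uM": g.analyte_conc, "phase": g.phase,
            "time_s": g.time, "response": g.response,
        }))
    pd.concat(frames, ignore_index=True)[SENSORGRAM_COLUMNS].to_csv(
        path, index=False)


def sensorgrams_from_csv(path) -> list[SensorGram]:
    df = pd.read_csv(path)
    missing = set(SENSORGRAM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sensorgram CSV missing columns: {sorted(missing)}")
    grams = []
    for cid, sub in df.groupby("channel_id", sort=False):
        sub = sub.sort_values("time_s")
        grams.append(SensorGram(
            channel_id=str(cid), role=sub["role"].iloc[0],
            analyte_conc=float(sub["analyte_conc_uM"].iloc[0]),
            time=sub["time_s"].to_numpy(),
            response=sub["response"].to_numpy(),
            phase=sub["phase"].to_numpy()))
    return grams


# ---------------------------------------------------------------------------
# processing operations
# ---------------------------------------------------------------------------

def _interp_onto(target: SensorGram, ref: SensorGram) -> np.ndarray:
    """Reference response on the target's time grid (grids must agree to
    within one sample period)."""
    dt = np.median(np.diff(target.time))
    if (abs(target.time[0] - ref.time[0]) > dt
            or abs(target.time[-1] - ref.time[-1]) > dt):
        raise ValueError("reference time grid does not match sample grid")
    return np.interp(target.time, ref.time, ref.response)


def subtract_reference(sample: SensorGram, refs: Sequence[SensorGram],
                       scheme: str = "single") -> SensorGram:
    """Reference-subtract one sample channel.

    ``single``: subtract the loaded-sensor-vs-buffer reference.
    ``double``: additionally subtract the unloaded-sensor-vs-analyte
    reference matched to the sample's analyte concentration.
    """
    if scheme not in ("single", "double"):
        raise ValueError(f"unknown referencing scheme {scheme!r}")
    single = [r for r in refs if r.role == "reference"]
    if not single:
        raise ValueError(f"scheme {scheme!r} requires a 'reference' channel "
                         "(loaded sensor vs buffer)")
    out = sample.response - _interp_onto(sample, single[0])
    if scheme == "double":
        dbl = [r for r in refs if r.role == "double_reference"
               and np.isclose(r.analyte_conc, sample.analyte_conc)]
        if not dbl:
            raise ValueError(
                "scheme 'double' requires a 'double_reference' channel at "
                f"analyte concentration {sample.analyte_conc} uM")
        out = out - _interp_onto(sample, dbl[0])
    return sample.with_response(out)


def align_baseline(gram: SensorGram, window_s: float = 10.0) -> SensorGram:
    """Zero the trace on the mean of the last ``window_s`` s of baseline."""
    if not 0 < window_s:
        raise ValueError("window_s must be positive")
    mask = gram.phase_mask("baseline")
    if not mask.any():
        raise ValueError("sensorgram has no baseline phase")
    t = gram.time[mask]
    if t[-1] - t[0] < window_s:
        raise ValueError(
            f"baseline phase ({t[-1] - t[0]:.1f} s) shorter than the "
            f"{window_s} s alignment window")
    tail = mask & (gram.time >= t[-1] - window_s)
    return gram.with_response(gram.response - gram.response[tail].mean())


def sg_smooth(series, window_pts: int = 15, order: int = 2):
    """Savitzky–Golay smoothing (exactly reproduces polynomials of degree
    <= ``order``). Accepts a raw array or a SensorGram."""
    if window_pts % 2 == 0 or window_pts < 3:
        raise ValueError("window_pts must be an odd integer >= 3")
    if not 0 <= order < window_pts:
        raise ValueError("polynomial order must satisfy 0 <= order < window")
    if isinstance(series, SensorGram):
        return series.with_response(
            savgol_filter(series.response, window_pts, order))
    arr = np.asarray(series, dtype=float)
    return savgol_filter(arr, window_pts, order)


def equilibrium_response(gram: SensorGram, window_s: float = 20.0) -> float:
    """Mean response over the final ``window_s`` s of the association phase."""
    mask = gram.phase_mask("association")
    if not mask.any():
        raise ValueError("sensorgram has no association phase")
    t = gram.time[mask]
    if t[-1] - t[0] < window_s:
        raise ValueError(
            f"association phase ({t[-1] - t[0]:.1f} s) shorter than the "
            f"{window_s} s equilibrium window")
    tail = mask & (gram.time >= t[-1] - window_s)
    return float(gram.response[tail].mean())


def fit_equilibrium(concs, r_eq):
    """Hyperbolic single-site fit of (x, r_eq) points.

    Returns an EquilibriumCurve with estimates and asymptotic
    (Jacobian-based) standard errors.
    """
    x = np.asarray(concs, dtype=float)
    r = np.asarray(r_eq, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 concentrations to fit")
    if len(np.unique(x)) != x.size:
        raise ValueError("analyte concentrations must be distinct")
    if np.any(x <= 0):
        raise ValueError("analyte concentrations must be > 0")

    span = max(r.max() - r.min(), 1e-12)
    x0 = [float(np.median(x)), float(r.min()), float(r.max() + 0.1 * span)]

    def resid(theta):
        kd, r0, rmax = theta
        return r0 + (rmax - r0) * x / (kd + x) - r

    sol = least_squares(resid, x0=x0,
                        bounds=([1e-9, -np.inf, -np.inf],
                                [1e9, np.inf, np.inf]),
                        ftol=1e-14, xtol=1e-14, gtol=1e-14)
    kd, r0, rmax = map(float, sol.x)
    dof = max(x.size - 3, 1)
    s2 = float(np.sum(sol.fun ** 2)) / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
    return EquilibriumCurve(
        concs=x, r_eq=r, kd=kd, r0=r0, rmax=rmax,
        kd_se=float(se[0]), r0_se=float(se[1]), rmax_se=float(se[2]),
        converged=bool(sol.success))


def _plateau_flag(gram: SensorGram, window_s: float = 20.0) -> bool:
    """True if the association phase has visibly plateaued: the means of the
    last two windows differ by less than a few percent of the response (or
    by less than ~10× the standard error, whichever is larger)."""
    mask = gram.phase_mask("association")
    t = gram.time[mask]
    r = gram.response[mask]
    if t[-1] - t[0] < 2 * window_s:
        return False
    last = r[t >= t[-1] - window_s]
    prev = r[(t >= t[-1] - 2 * window_s) & (t < t[-1] - window_s)]
    sem = max(last.std(), 1e-12) / np.sqrt(last.size)
    tol = max(0.03 * abs(last.mean()), 10.0 * sem, 1e-9)
    return abs(last.mean() - prev.mean()) < tol


def run_bli_analysis(grams: Sequence[SensorGram], scheme: str = "double",
                     sg_window: int = 15, sg_order: int = 2,
                     baseline_window_s: float = 10.0,
                     eq_window_s: float = 20.0) -> EquilibriumCurve:
    """Full pipeline: reference → align → smooth → r_eq → hyperbolic fit."""
    samples = [g for g in grams if g.role == "sample"]
    refs = [g for g in grams if g.role != "sample"]
    if not samples:
        raise ValueError("no sample channels supplied")
    concs, reqs, flags = [], [], {}
    for g in sorted(samples, key=lambda s: s.analyte_conc):
        try:
            proc = subtract_reference(g, refs, scheme=scheme)
            proc = align_baseline(proc, window_s=baseline_window_s)
            proc = sg_smooth(proc, sg_window, sg_order)
            req = equilibrium_response(proc, window_s=eq_window_s)
        except ValueError as exc:
            raise ValueError(f"channel {g.channel_id}: {exc}") from exc
        concs.append(g.analyte_conc)
        reqs.append(req)
        if not _plateau_flag(proc, window_s=eq_window_s):
            flags[float(g.analyte_conc)] = "association not plateaued"
    curve = fit_equilibrium(concs, reqs)
    curve.flags = flags
    return curve
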