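"""Chemical-shift-perturbation analysis and dissociation-constant fitting.

The workflow implemented here is the standard one for NMR-detected
titrations of a labelled receptor in fast exchange:

1. compute the composite chemical-shift perturbation
   ``Δδ = sqrt(Δδ_H² + (0.154·Δδ_N)²)`` per residue at each titration point
   relative to the apo spectrum;
2. select significantly perturbed residues
   (``Δδ > mean + k·sd`` over all observable residues, default k = 1/2 —
   a deliberately permissive cutoff appropriate for a small domain whose
   binding surface is a large fraction of its residues);
3. fit each selected residue independently to the ligand-depleted
   single-site isotherm ``Δδ = Δδmax · f_B(P, L, Kd)`` with per-point
   protein and ligand concentrations (so sample dilution across the
   titration is handled exactly);
4. aggregate the per-residue Kd values: one pass of mean ± 2·sd outlier
   rejection, then mean and sd over the retained residues.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .isotherm import fraction_bound

__all__ = [
    "TitrationSeries",
    "CSPProfile",
    "ResidueFit",
    "BindingFitResult",
    "composite_csp",
    "csp_profile",
    "select_significant",
    "fit_residue",
    "aggregate_kd",
    "fold_change",
    "run_titration_analysis",
]

#: 15N scaling factor in the composite shift difference (gyromagnetic-ratio
#: weighting conventional for amide HSQC titrations).
N15_WEIGHT = 0.154

PEAKLIST_COLUMNS = [
    "residue_id", "residue_name", "point_index",
    "h_ppm", "n_ppm", "p_conc_uM", "l_conc_uM", "intensity",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TitrationSeries:
    """Per-residue peak positions across a titration.

    Attributes
    ----------
    residues : list of str
        Residue identifiers (unique).
    h_ppm, n_ppm : ndarray, shape (n_residues, n_points)
        Proton / nitrogen chemical shifts; NaN marks a peak that was not
        observed at that point (broadened beyond detection).
    p_conc, l_conc : ndarray, shape (n_points,)
        Total protein and ligand concentration at each point, μM. Point 0
        is the apo spectrum (l_conc[0] == 0).
    residue_names : list of str, optional
        Three- or one-letter residue names, cosmetic only.
    intensity : ndarray or None
        Optional peak intensities (used by slow-exchange bookkeeping).
    """

    residues: list
    h_ppm: np.ndarray
    n_ppm: np.ndarray
    p_conc: np.ndarray
    l_conc: np.ndarray
    residue_names: list | None = None
    intensity: np.ndarray | None = None

    def __post_init__(self):
        self.h_ppm = np.asarray(self.h_ppm, dtype=float)
        self.n_ppm = np.asarray(self.n_ppm, dtype=float)
        self.p_conc = np.asarray(self.p_conc, dtype=float)
        self.l_conc = np.asarray(self.l_conc, dtype=float)
        if len(set(self.residues)) != len(self.residues):
            raise ValueError("duplicate residue identifiers in TitrationSeries")
        nres, npts = self.h_ppm.shape
        if self.n_ppm.shape != (nres, npts):
            raise ValueError("h_ppm and n_ppm shapes differ")
        if len(self.residues) != nres:
            raise ValueError("residues length does not match shift array")
        if self.p_conc.shape != (npts,) or self.l_conc.shape != (npts,):
            raise ValueError("concentration arrays must have one entry per point")
        if self.l_conc[0] != 0:
            raise ValueError("point 0 must be the apo spectrum (ligand_conc = 0)")
        if np.any(np.isnan(self.h_ppm[:, 0])) or np.any(np.isnan(self.n_ppm[:, 0])):
            raise ValueError("every residue must be observed at point 0 (apo)")

    @property
    def n_points(self) -> int:
        return self.h_ppm.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format peak list (one row per residue per observed point)."""
        rows = []
        names = self.residue_names or ["UNK"] * len(self.residues)
        for i, rid in enumerate(self.residues):
            for j in range(self.n_points):
                if math.isnan(self.h_ppm[i, j]):
                    continue
                rows.append({
                    "residue_id": rid,
                    "residue_name": names[i],
                    "point_index": j,
                    "h_ppm": self.h_ppm[i, j],
                    "n_ppm": self.n_ppm[i, j],
                    "p_conc_uM": self.p_conc[j],
                    "l_conc_uM": self.l_conc[j],
                    "intensity": (self.intensity[i, j]
                                  if self.intensity is not None else np.nan),
                })
        return pd.DataFrame(rows, columns=PEAKLIST_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TitrationSeries":
        required = {"residue_id", "point_index", "h_ppm", "n_ppm",
                    "p_conc_uM", "l_conc_uM"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"peak list missing columns: {sorted(missing)}")
        points = sorted(df["point_index"].unique())
        if points != list(range(len(points))):
            raise ValueError("point_index values must be contiguous from 0")
        residues = list(dict.fromkeys(df["residue_id"]))
        npts = len(points)
        idx = {r: i for i, r in enumerate(residues)}
        h = np.full((len(residues), npts), np.nan)
        n = np.full((len(residues), npts), np.nan)
        inten = np.full((len(residues), npts), np.nan)
        p_conc = np.full(npts, np.nan)
        l_conc = np.full(npts, np.nan)
        names = {}
        for _, row in df.iterrows():
            i, j = idx[row["residue_id"]], int(row["point_index"])
            h[i, j] = row["h_ppm"]
            n[i, j] = row["n_ppm"]
            if "intensity" in df.columns:
                inten[i, j] = row.get("intensity", np.nan)
            p_conc[j] = row["p_conc_uM"]
            l_conc[j] = row["l_conc_uM"]
            if "residue_name" in df.columns:
                names[i] = row["residue_name"]
        name_list = [names.get(i, "UNK") for i in range(len(residues))]
        return cls(residues, h, n, p_conc, l_conc, residue_names=name_list,
                   intensity=inten if np.any(np.isfinite(inten)) else None)

    @classmethod
    def from_csv(cls, path) -> "TitrationSeries":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class CSPProfile:
    """Composite Δδ per residue per point, relative to the apo spectrum."""

    residues: list
    dd: np.ndarray                      # (n_residues, n_points); NaN = unobserved
    p_conc: np.ndarray
    l_conc: np.ndarray
    evaluation_point: int
    broadened: np.ndarray               # bool, residue unobserved at eval point

    @property
    def dd_eval(self) -> np.ndarray:
        return self.dd[:, self.evaluation_point]


@dataclass
class ResidueFit:
    residue: object
    kd: float
    ddmax: float
    residual: float
    converged: bool
    message: str = ""
    retained: bool = False


@dataclass
class BindingFitResult:
    """Aggregate binding result for one titration."""

    fits: list = field(default_factory=list)
    kd_mean: float = float("nan")
    kd_sd: float = float("nan")
    n_retained: int = 0
    prepass_mean: float = float("nan")
    prepass_sd: float = float("nan")
    significant: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def to_report(self) -> dict:
        return {
            "kd_mean": self.kd_mean,
            "kd_sd": self.kd_sd,
            "n_retained": self.n_retained,
            "prepass": {"kd_mean": self.prepass_mean, "kd_sd": self.prepass_sd},
            "significant_residues": [str(r) for r in self.significant],
            "warnings": list(self.warnings),
            "per_residue": [
                {"residue": str(f.residue), "kd": f.kd, "ddmax": f.ddmax,
                 "residual": f.residual, "converged": f.converged,
                 "retained": f.retained}
                for f in self.fits
            ],
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_report(), indent=2))

    def fit_table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"residue": f.residue, "kd_uM": f.kd, "ddmax_ppm": f.ddmax,
             "residual": f.residual, "converged": f.converged,
             "retained": f.retained}
            for f in self.fits
        ])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def composite_csp(dH, dN):
    """Composite shift difference ``sqrt(dH² + (0.154·dN)²)`` in ppm."""
    dH = np.asarray(dH, dtype=float)
    dN = np.asarray(dN, dtype=float)
    if not (np.all(np.isfinite(dH)) and np.all(np.isfinite(dN))):
        raise ValueError("composite_csp requires finite shift differences")
    out = np.sqrt(dH ** 2 + (N15_WEIGHT * dN) ** 2)
    return float(out) if out.ndim == 0 else out


def csp_profile(series: TitrationSeries, evaluation_point: int = -1) -> CSPProfile:
    """Per-residue Δδ at every titration point relative to point 0.

    Residues unobserved at the evaluation point are flagged ``broadened``
    and excluded from downstream statistics (never imputed).
    """
    npts = series.n_points
    ev = evaluation_point % npts
    dh = series.h_ppm - series.h_ppm[:, [0]]
    dn = series.n_ppm - series.n_ppm[:, [0]]
    dd = np.sqrt(dh ** 2 + (N15_WEIGHT * dn) ** 2)
    broadened = np.isnan(dd[:, ev])
    return CSPProfile(series.residues, dd, series.p_conc, series.l_conc,
                      ev, broadened)


def select_significant(profile: CSPProfile, k: float = 0.5,
                       population_sd: bool = True) -> list:
    """Residues with Δδ above ``mean + k·sd`` at the evaluation point.

    The mean and sd are computed over all residues observable at the
    evaluation point; the inequality is strict, so a flat profile selects
    nothing. ``population_sd`` chooses the 1/n normalisation (default).
    """
    mask = ~profile.broadened
    if mask.sum() < 2:
        raise ValueError("need at least 2 observable residues to select from")
    vals = profile.dd_eval[mask]
    thresh = vals.mean() + k * vals.std(ddof=0 if population_sd else 1)
    return [r for r, dd, ok in zip(profile.residues, profile.dd_eval, mask)
            if ok and dd > thresh]


def fit_residue(dd_series, P, L, kd0: float | None = None,
                ddmax0: float | None = None) -> ResidueFit:
    """Fit (Kd, Δδmax) for one residue against the depletion isotherm.

    ``dd_series`` may contain NaN (unobserved points, dropped). Requires at
    least 3 usable points with L > 0. Non-convergent or degenerate series
    are returned with ``converged=False`` rather than raising.
    """
    dd = np.asarray(dd_series, dtype=float)
    P = np.asarray(P, dtype=float)
    L = np.asarray(L, dtype=float)
    usable = np.isfinite(dd)
    n_pos = int(np.sum(usable & (L > 0)))
    if n_pos < 3:
        raise ValueError(f"need >= 3 observed points with ligand, got {n_pos}")
    dd, P, L = dd[usable], P[usable], L[usable]

    if float(np.nanmax(dd)) <= 0:
        return ResidueFit(None, math.nan, math.nan, math.nan, False,
                          "flat CSP series")
    kd0 = kd0 if kd0 is not None else float(np.median(L[L > 0]))
    ddmax0 = ddmax0 if ddmax0 is not None else float(np.nanmax(dd)) * 1.2

    def resid(theta):
        kd, ddmax = theta
        return ddmax * fraction_bound(P, L, kd) - dd

    try:
        sol = least_squares(resid, x0=[kd0, ddmax0],
                            bounds=([1e-9, 1e-9], [1e6, 10.0]),
                            ftol=1e-12, xtol=1e-12, gtol=1e-12)
    except Exception as exc:  # pragma: no cover - defensive
        return ResidueFit(None, math.nan, math.nan, math.nan, False, str(exc))
    kd, ddmax = map(float, sol.x)
    rss = float(np.sum(sol.fun ** 2))
    ok = bool(sol.success) and kd < 9.9e5
    return ResidueFit(None, kd, ddmax, rss, ok,
                      "" if ok else "fit did not converge or hit Kd bound")


def aggregate_kd(kds: Iterable[float], population_sd: bool = True):
    """Mean/sd of per-residue Kd values with one pass of ±2·sd rejection.

    Returns ``(kd_mean, kd_sd, retained_mask)`` where the mean and sd are
    recomputed over the retained set. The first-pass statistics use all
    inputs; the rejection is a single pass (it is not iterated).
    """
    kds = np.asarray(list(kds), dtype=float)
    if kds.size < 3:
        raise ValueError("need >= 3 converged residue fits to aggregate")
    ddof = 0 if population_sd else 1
    m0, s0 = kds.mean(), kds.std(ddof=ddof)
    # tiny relative slack so numerically identical fits are never evicted
    retained = np.abs(kds - m0) <= 2.0 * s0 + 1e-8 * max(abs(m0), 1.0)
    m1 = kds[retained].mean()
    s1 = kds[retained].std(ddof=ddof) if retained.sum() > 1 else 0.0
    return float(m1), float(s1), retained


def fold_change(kd_a: float, kd_b: float) -> float:
    """Ratio ``kd_a / kd_b`` (e.g. DNA-pre-bound vs free-peptide affinity)."""
    for name, v in (("kd_a", kd_a), ("kd_b", kd_b)):
        if not (np.isfinite(v) and v > 0):
            raise ValueError(f"{name} must be a positive finite Kd, got {v!r}")
    return kd_a / kd_b


def run_titration_analysis(series: TitrationSeries, evaluation_point: int = -1,
                           sig_k: float = 0.5,
                           population_sd: bool = True) -> BindingFitResult:
    """Full pipeline: profile → significance → per-residue fits → aggregate."""
    result = BindingFitResult()
    profile = csp_profile(series, evaluation_point)
    n_broad = int(profile.broadened.sum())
    if n_broad:
        broad = [str(r) for r, b in zip(series.residues, profile.broadened) if b]
        result.warnings.append(
            f"{n_broad} residue(s) broadened/unobserved at the evaluation "
            f"point and excluded: {', '.join(broad)}")
    significant = select_significant(profile, k=sig_k,
                                     population_sd=population_sd)
    result.significant = significant
    idx = {r: i for i, r in enumerate(series.residues)}
    for rid in significant:
        i = idx[rid]
        fit = fit_residue(profile.dd[i], series.p_conc, series.l_conc)
        fit.residue = rid
        result.fits.append(fit)
        if not fit.converged:
            result.warnings.append(f"residue {rid}: {fit.message}")

    good = [f for f in result.fits if f.converged]
    if len(good) < 3:
        raise ValueError(
            f"only {len(good)} residues gave converged fits; cannot aggregate")
    kds = [f.kd for f in good]
    m0 = float(np.mean(kds))
    s0 = float(np.std(kds, ddof=0 if population_sd else 1))
    kd_mean, kd_sd, retained = aggregate_kd(kds, population_sd=population_sd)
    for f, keep in zip(good, retained):
        f.retained = bool(keep)
    result.kd_mean, result.kd_sd = kd_mean, kd_sd
    result.prepass_mean, result.prepass_sd = m0, s0
    result.n_retained = int(retained.sum())
    return result
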