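"""Synthetic fast-exchange CSP titrations with ligand depletion.

Each residue carries an apo and a bound endpoint in (¹H, ¹⁵N) shift space;
the observed peak at each titration point sits at the population-weighted
average of the two, with the bound population given by the exact
ligand-depleted isotherm. Per-point protein and ligand concentrations are
supplied explicitly, so sample dilution is represented simply by a
decreasing protein concentration across the schedule.

An optional slow-exchange mode emits two peak records per residue (apo and
bound positions) whose intensities are linear in the bound fraction, which
is the bookkeeping needed for tail-into-nucleosome style titrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..cspfit import PEAKLIST_COLUMNS, TitrationSeries
from ..isotherm import fraction_bound

__all__ = ["TitrationSpec", "gen_titration", "ratio_schedule"]


def ratio_schedule(p0: float, ratios, dilution: float = 0.0):
    """Build a (P_i, L_i) schedule from PHD:ligand molar ratios.

    ``dilution`` is the fractional drop in protein concentration per
    titration step (0 keeps P constant). Ligand ratios are taken relative
    to the starting protein concentration, matching how a titration is
    planned from a concentrated ligand stock.
    """
    points = []
    for i, r in enumerate(ratios):
        p = p0 * (1.0 - dilution) ** i
        points.append((p, p0 * r))
    return points


@dataclass
class TitrationSpec:
    """Ground truth for one synthetic titration."""

    residues: list
    apo_shift: dict            # residue -> (h_ppm, n_ppm)
    bound_shift: dict          # residue -> (h_ppm, n_ppm)
    kd_true: float             # μM
    points: list               # [(P_uM, L_uM), ...], point 0 apo
    noise_sd: tuple = (0.0, 0.0)   # (¹H ppm, ¹⁵N ppm)
    seed: int = 0
    slow_exchange: bool = False
    residue_names: list | None = None

    def __post_init__(self):
        if len(set(self.residues)) != len(self.residues):
            raise ValueError("duplicate residue identifiers")
        if not (np.isfinite(self.kd_true) and self.kd_true > 0):
            raise ValueError(f"kd_true must be > 0, got {self.kd_true}")
        for p, l in self.points:
            if p <= 0 or l < 0:
                raise ValueError("concentrations must be P > 0 and L >= 0")
        if self.points[0][1] != 0:
            raise ValueError("first titration point must be apo (L = 0)")
        if any(s < 0 for s in self.noise_sd):
            raise ValueError("noise_sd must be >= 0")
        missing = [r for r in self.residues
                   if r not in self.apo_shift or r not in self.bound_shift]
        if missing:
            raise ValueError(f"residues missing endpoint shifts: {missing}")


def gen_titration(spec: TitrationSpec):
    """Generate a TitrationSeries (fast exchange) or a two-peaks-per-residue
    peak-list DataFrame (slow exchange) from a spec."""
    rng = np.random.default_rng(spec.seed)
    P = np.array([p for p, _ in spec.points], dtype=float)
    L = np.array([l for _, l in spec.points], dtype=float)
    fb = fraction_bound(P, L, spec.kd_true)          # per point

    apo = np.array([spec.apo_shift[r] for r in spec.residues], dtype=float)
    bound = np.array([spec.bound_shift[r] for r in spec.residues], dtype=float)
    names = spec.residue_names or ["UNK"] * len(spec.residues)

    if not spec.slow_exchange:
        # population-weighted single peak per residue
        h = apo[:, [0]] + fb[None, :] * (bound[:, [0]] - apo[:, [0]])
        n = apo[:, [1]] + fb[None, :] * (bound[:, [1]] - apo[:, [1]])
        h = h + rng.normal(0.0, spec.noise_sd[0], size=h.shape)
        n = n + rng.normal(0.0, spec.noise_sd[1], size=n.shape)
        if spec.noise_sd == (0.0, 0.0):
            # apo point is exact by construction
            h[:, 0] = apo[:, 0]
            n[:, 0] = apo[:, 1]
        return TitrationSeries(list(spec.residues), h, n, P, L,
                               residue_names=list(names))

    # slow exchange: two records per residue, intensities linear in f_B
    rows = []
    for i, rid in enumerate(spec.residues):
        for j, f in enumerate(fb):
            for label, pos, inten in (("apo", apo[i], 1.0 - f),
                                      ("bound", bound[i], f)):
                rows.append({
                    "residue_id": f"{rid}:{label}",
                    "residue_name": names[i],
                    "point_index": j,
                    "h_ppm": pos[0] + rng.normal(0.0, spec.noise_sd[0]),
                    "n_ppm": pos[1] + rng.normal(0.0, spec.noise_sd[1]),
                    "p_conc_uM": P[j],
                    "l_conc_uM": L[j],
                    "intensity": inten,
                })
    return pd.DataFrame(rows, columns=PEAKLIST_COLUMNS)
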