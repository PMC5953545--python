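"""Geometric trajectory metrics: Rg, superposition RMSD, SASA.

All metrics operate on plain (n_atoms, 3) frames plus a Topology for
selections, masses and radii. The superposition uses the Kabsch algorithm
with the proper-rotation (det = +1) correction, so mirror solutions are
never returned.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .system import Selection, Topology

__all__ = ["radius_of_gyration", "kabsch_fit", "kabsch_rmsd",
           "end_state_rmsd", "sasa"]


def _mask(top: Topology, sel) -> np.ndarray:
    return top.select(sel)


def radius_of_gyration(frame: np.ndarray, top: Topology, sel="all",
                       mass_weighted: bool = True) -> float:
    """Mass-weighted RMS distance of the selected atoms from their COM (Å)."""
    m = _mask(top, sel)
    xyz = np.asarray(frame)[m]
    w = top.mass[m] if mass_weighted else np.ones(m.sum())
    com = np.average(xyz, axis=0, weights=w)
    d2 = np.sum((xyz - com) ** 2, axis=1)
    return float(np.sqrt(np.average(d2, weights=w)))


def kabsch_fit(mobile: np.ndarray, ref: np.ndarray):
    """Optimal proper rotation R and translation t minimising
    ``|| (mobile @ R + t) - ref ||``; returns (R, t)."""
    mobile = np.asarray(mobile, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if mobile.shape != ref.shape:
        raise ValueError("fit selections must map 1:1 between frames")
    mc, rc = mobile.mean(axis=0), ref.mean(axis=0)
    H = (mobile - mc).T @ (ref - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    t = rc - mc @ R
    return R, t


def kabsch_rmsd(mobile_frame: np.ndarray, ref_frame: np.ndarray,
                top: Topology, fit_sel="all", rmsd_sel="all") -> float:
    """RMSD over ``rmsd_sel`` after least-squares fitting on ``fit_sel``.

    The rotation/translation is determined from the fit selection only and
    then applied to the whole mobile frame before the RMSD selection is
    evaluated — the superposition protocol used to measure tail spread
    after aligning on the structured core.
    """
    fit_m = _mask(top, fit_sel)
    rmsd_m = _mask(top, rmsd_sel)
    mobile = np.asarray(mobile_frame, dtype=float)
    ref = np.asarray(ref_frame, dtype=float)
    if mobile.shape != ref.shape:
        raise ValueError("frames must have identical atom counts")
    R, t = kabsch_fit(mobile[fit_m], ref[fit_m])
    moved = mobile @ R + t
    diff = moved[rmsd_m] - ref[rmsd_m]
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))


def end_state_rmsd(frames, top: Topology, fit_sel="all", rmsd_sel="all",
                   groups=None):
    """All-pairs fitted RMSD over a set of end-state frames.

    Returns ``(mean, matrix)`` where the mean is over the strict upper
    triangle. If ``groups`` (a label per frame) is given, a per-group mean
    over same-label pairs is additionally returned as a dict.
    """
    frames = [np.asarray(f, dtype=float) for f in frames]
    n = len(frames)
    if n < 2:
        raise ValueError("need >= 2 frames for pairwise RMSD")
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = kabsch_rmsd(frames[j], frames[i], top, fit_sel, rmsd_sel)
            mat[i, j] = mat[j, i] = r
    iu = np.triu_indices(n, k=1)
    mean = float(mat[iu].mean())
    if groups is None:
        return mean, mat
    groups = np.asarray(groups)
    per_group = {}
    for g in dict.fromkeys(groups.tolist()):
        idx = np.flatnonzero(groups == g)
        if len(idx) < 2:
            continue
        sub = mat[np.ix_(idx, idx)]
        per_group[g] = float(sub[np.triu_indices(len(idx), k=1)].mean())
    return mean, mat, per_group


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(frame: np.ndarray, top: Topology, sel="all", probe: float = 1.4,
         n_sphere_points: int = 960):
    """Shrake–Rupley solvent-accessible surface area.

    Every atom in the frame occludes (not only the selection); the
    returned areas cover the selected atoms only. Returns
    ``(total_A2, per_residue)`` where per_residue maps
    (chain, resid) -> Å².
    """
    xyz = np.asarray(frame, dtype=float)
    radii = np.asarray(top.radius, dtype=float)
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        raise ValueError("all atoms need a positive radius for SASA")
    m = _mask(top, sel)
    sphere = _sphere_points(n_sphere_points)
    ext = radii + probe
    tree = cKDTree(xyz)
    max_ext = ext.max()

    total = 0.0
    per_res: dict = {}
    for i in np.flatnonzero(m):
        pts = xyz[i] + ext[i] * sphere
        # candidate occluders within reach of this atom's probe sphere
        neigh = tree.query_ball_point(xyz[i], ext[i] + max_ext)
        neigh = [j for j in neigh if j != i]
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j in neigh:
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            exposed &= d2 > ext[j] ** 2
        area = 4.0 * np.pi * ext[i] ** 2 * exposed.mean()
        total += area
        key = (str(top.chain[i]), int(top.resid[i]))
        per_res[key] = per_res.get(key, 0.0) + area
    return float(total), per_res
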