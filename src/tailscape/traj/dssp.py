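"""Hydrogen-bond-pattern secondary structure (Kabsch–Sander) collapsed to
four categories: helix (G/H/I), sheet (E/B), turn (T), coil (everything
else).

The backbone amide hydrogen is built geometrically (1.0 Å from N, parallel
to the preceding carbonyl C=O), and the electrostatic H-bond energy

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)  kcal/mol

defines a bond at E < −0.5 kcal/mol. Structural elements follow the
original priority (4-helix > sheet > 3-helix > 5-helix > turn); chain
breaks end ladders because bonds are only evaluated within one contiguous
chain. Residues with missing backbone atoms are reported as coil and
flagged.
"""

from __future__ import annotations

import numpy as np

from .system import Topology

__all__ = ["dssp_classify", "ss_summary", "CATEGORIES"]

CATEGORIES = ("helix", "sheet", "turn", "coil")
Q_CONST = 0.084 * 332.0       # kcal/mol·Å
HB_CUTOFF = -0.5              # kcal/mol
NH_LENGTH = 1.0               # Å


def _backbone_table(frame, top: Topology, chain: str):
    """Ordered per-residue backbone coordinates for one chain.

    Returns (resids, coords dict of (n,3) arrays with NaN for missing,
    missing mask)."""
    frame = np.asarray(frame, dtype=float)
    in_chain = top.chain == chain
    if not in_chain.any():
        raise ValueError(f"no atoms in chain {chain!r}")
    resids = np.unique(top.resid[in_chain])
    resids.sort()
    coords = {a: np.full((len(resids), 3), np.nan) for a in "N CA C O".split()}
    for k, r in enumerate(resids):
        sel = in_chain & (top.resid == r)
        for a in coords:
            hit = sel & (top.name == a)
            if hit.any():
                coords[a][k] = frame[np.flatnonzero(hit)[0]]
    missing = np.zeros(len(resids), dtype=bool)
    for a in coords:
        missing |= np.any(np.isnan(coords[a]), axis=1)
    return resids, coords, missing


def _hbond_matrix(coords, missing):
    """hb[i, j] True when the CO of residue i accepts the NH of residue j."""
    N, C, O = coords["N"], coords["C"], coords["O"]
    n = len(N)
    # amide H: 1 Å from N, parallel to the previous residue's C=O
    H = np.full((n, 3), np.nan)
    for i in range(1, n):
        if missing[i] or missing[i - 1]:
            continue
        co = C[i - 1] - O[i - 1]
        H[i] = N[i] + NH_LENGTH * co / np.linalg.norm(co)

    hb = np.zeros((n, n), dtype=bool)
    for i in range(n):            # acceptor CO of residue i
        if missing[i]:
            continue
        for j in range(n):        # donor NH of residue j
            if j in (i, i + 1) or missing[j] or np.any(np.isnan(H[j])):
                continue
            r_on = np.linalg.norm(O[i] - N[j])
            if r_on > 5.2:        # cheap distance gate (DSSP uses CA < 9 Å)
                continue
            r_ch = np.linalg.norm(C[i] - H[j])
            r_oh = np.linalg.norm(O[i] - H[j])
            r_cn = np.linalg.norm(C[i] - N[j])
            if min(r_ch, r_oh, r_cn) < 1e-6:
                continue
            e = Q_CONST * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            hb[i, j] = e < HB_CUTOFF
    return hb


def _assign(hb, missing):
    n = hb.shape[0]

    def turn_at(i, k):
        return i + k < n and hb[i, i + k]

    helix4 = np.zeros(n, dtype=bool)
    helix3 = np.zeros(n, dtype=bool)
    helix5 = np.zeros(n, dtype=bool)
    for k, out in ((4, helix4), (3, helix3), (5, helix5)):
        for i in range(1, n):
            if turn_at(i - 1, k) and turn_at(i, k):
                out[i:i + k] = True

    sheet = np.zeros(n, dtype=bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = ((hb[i - 1, j] and hb[j, i + 1])
                    or (hb[j - 1, i] and hb[i, j + 1]))
            anti = ((hb[i, j] and hb[j, i])
                    or (hb[i - 1, j + 1] and hb[j - 1, i + 1]))
            if para or anti:
                sheet[i] = sheet[j] = True

    turn = np.zeros(n, dtype=bool)
    for k in (3, 4, 5):
        for i in range(n):
            if turn_at(i, k):
                turn[i + 1:i + k] = True

    cats = np.full(n, "coil", dtype=object)
    cats[turn] = "turn"
    cats[helix5] = "helix"
    cats[helix3] = "helix"
    cats[sheet] = "sheet"
    cats[helix4] = "helix"
    cats[missing] = "coil"
    return cats


def dssp_classify(frame, top: Topology, chain: str):
    """Four-category secondary structure for every residue of one chain.

    Returns ``(resids, categories, flags)`` where flags marks residues
    whose backbone was incomplete (reported as coil).
    """
    resids, coords, missing = _backbone_table(frame, top, chain)
    if len(resids) < 3:
        return resids, np.full(len(resids), "coil", dtype=object), missing
    hb = _hbond_matrix(coords, missing)
    return resids, _assign(hb, missing), missing


def ss_summary(records, residues=None):
    """Ensemble secondary-structure percentages.

    ``records`` is an (n_frames, n_residues) array of category labels.
    Per-residue values are the percentage of frames in each category; the
    overall value for a category is the mean of the per-residue
    percentages over ``residues`` (all by default). Returns
    ``(overall, per_residue)`` dicts keyed by category, percentages in
    0–100 summing to 100 per residue.
    """
    rec = np.asarray(records, dtype=object)
    if rec.ndim != 2 or rec.size == 0:
        raise ValueError("records must be a non-empty (frames, residues) array")
    n_frames, n_res = rec.shape
    sel = np.arange(n_res) if residues is None else np.asarray(residues)
    per_residue = {}
    for cat in CATEGORIES:
        per_residue[cat] = 100.0 * np.mean(rec == cat, axis=0)
    overall = {cat: float(per_residue[cat][sel].mean()) for cat in CATEGORIES}
    return overall, per_residue
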