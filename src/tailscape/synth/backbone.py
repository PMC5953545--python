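"""Ideal-geometry backbone construction from (φ, ψ) dihedrals.

Chains are grown atom by atom with the standard internal-to-Cartesian
(NeRF) placement using fixed ideal bond lengths and angles
(N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, ω = 180°), so a fragment's
secondary structure is fully determined by its (φ, ψ) list. Carbonyl
oxygens are placed in the peptide plane anti to the next amide nitrogen.
This is the fixture source for hydrogen-bond-based secondary-structure
tests: an ideal α-helix or β-strand built here has exactly the geometry
the assignment algorithm expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BackboneSpec", "build_backbone", "measure_dihedral",
           "backbone_dihedrals", "IDEAL"]

IDEAL = {
    "b_n_ca": 1.458, "b_ca_c": 1.525, "b_c_n": 1.329, "b_c_o": 1.231,
    "a_n_ca_c": 111.2, "a_ca_c_n": 116.2, "a_c_n_ca": 121.7,
    "a_ca_c_o": 120.5, "omega": 180.0,
}


@dataclass
class BackboneSpec:
    """Per-residue (φ°, ψ°) list; geometry is always ideal."""

    dihedrals: list          # [(phi_deg, psi_deg), ...] one per residue

    def __post_init__(self):
        if len(self.dihedrals) < 2:
            raise ValueError("backbone needs at least 2 residues")
        for phi, psi in self.dihedrals:
            for name, v in (("phi", phi), ("psi", psi)):
                if not -180.0 < v <= 180.0:
                    raise ValueError(f"{name}={v} outside (-180, 180]")


def _place(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF: position of atom d given chain a-b-c and internals of c-d."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * np.cos(angle),
                   bond * np.sin(angle) * np.cos(torsion),
                   bond * np.sin(angle) * np.sin(torsion)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_backbone(spec: BackboneSpec) -> dict:
    """Construct N/Cα/C/O coordinates for the specified chain.

    Returns a dict of (n_res, 3) arrays keyed "N", "CA", "C", "O".
    φ of residue 1 and ψ of the last residue do not affect the mainchain
    (they have no flanking atom) — ψ of the last residue is still used to
    orient its carbonyl oxygen.
    """
    dih = spec.dihedrals
    n_res = len(dih)
    g = IDEAL
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))

    # first residue in a canonical frame
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (g["b_n_ca"], 0.0, 0.0)
    ang = np.deg2rad(g["a_n_ca_c"])
    C[0] = CA[0] + g["b_ca_c"] * np.array([-np.cos(ang), np.sin(ang), 0.0])

    for i in range(1, n_res):
        psi_prev = dih[i - 1][1]
        N[i] = _place(N[i - 1], CA[i - 1], C[i - 1],
                      g["b_c_n"], g["a_ca_c_n"], psi_prev)
        CA[i] = _place(CA[i - 1], C[i - 1], N[i],
                       g["b_n_ca"], g["a_c_n_ca"], g["omega"])
        phi = dih[i][0]
        C[i] = _place(C[i - 1], N[i], CA[i],
                      g["b_ca_c"], g["a_n_ca_c"], phi)

    # carbonyl oxygens: anti to the next amide nitrogen, in-plane
    for i in range(n_res - 1):
        O[i] = _place(N[i + 1], CA[i], C[i],
                      g["b_c_o"], g["a_ca_c_o"], 180.0)
    # last residue: orient via its own psi (O anti to where N(i+1) would be)
    psi_last = dih[-1][1]
    O[-1] = _place(N[-1], CA[-1], C[-1],
                   g["b_c_o"], g["a_ca_c_o"], psi_last + 180.0)
    return {"N": N, "CA": CA, "C": C, "O": O}


def measure_dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle in degrees for four points (IUPAC convention)."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def backbone_dihedrals(coords: dict) -> list:
    """Recover per-residue (φ, ψ) from built coordinates.

    φ of the first and ψ of the last residue are undefined (returned as
    NaN) because they need a flanking residue.
    """
    N, CA, C = coords["N"], coords["CA"], coords["C"]
    n_res = len(N)
    out = []
    for i in range(n_res):
        phi = (measure_dihedral(C[i - 1], N[i], CA[i], C[i])
               if i > 0 else float("nan"))
        psi = (measure_dihedral(N[i], CA[i], C[i], N[i + 1])
               if i < n_res - 1 else float("nan"))
        out.append((phi, psi))
    return out
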