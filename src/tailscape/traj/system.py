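"""Topology / trajectory containers, atom selections, and PDB/DCD I/O.

The containers are deliberately small: a Topology is a set of parallel
per-atom arrays (chain, residue, name, element, mass, partial charge,
radius and optional Lennard-Jones parameters) and a TrajectoryEnsemble is
an (n_frames, n_atoms, 3) coordinate block. File I/O goes through
MDAnalysis; topology PDB files repurpose the occupancy column for the
partial charge and the B-factor column for the radius (a documented
convention — standard PDB has nowhere else to put them).

Selections use a small predicate language::

    "chain T resid 1-10 backbone"
    "chain D name P"
    "heavy"

Tokens: ``chain <id>``, ``resid <a>-<b>`` or ``resid <a>`` (closed range,
1-based), ``name <N1>,<N2>,...``, ``backbone`` (N/CA/C/O), ``heavy``
(non-hydrogen), ``all``. All clauses are ANDed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Topology", "TrajectoryEnsemble", "Selection",
           "write_system", "read_system"]

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass
class Topology:
    chain: np.ndarray
    resid: np.ndarray          # 1-based within chain
    resname: np.ndarray
    name: np.ndarray
    element: np.ndarray
    mass: np.ndarray           # amu
    charge: np.ndarray         # e
    radius: np.ndarray         # Å
    lj_eps: np.ndarray | None = None    # kcal/mol
    lj_sigma: np.ndarray | None = None  # Å

    def __post_init__(self):
        n = len(self.chain)
        for attr in ("resid", "resname", "name", "element", "mass",
                     "charge", "radius"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"topology array {attr!r} length mismatch")
        if np.any(self.mass <= 0):
            raise ValueError("masses must be > 0")
        if np.any(self.radius < 0):
            raise ValueError("radii must be >= 0")

    @property
    def n_atoms(self) -> int:
        return len(self.chain)

    def select(self, sel) -> np.ndarray:
        """Boolean mask for a Selection or selection string."""
        if isinstance(sel, str):
            sel = Selection(sel)
        return sel.mask(self)


@dataclass
class TrajectoryEnsemble:
    coords: np.ndarray          # (n_frames, n_atoms, 3) Å

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def __getitem__(self, i) -> np.ndarray:
        return self.coords[i]


@dataclass
class Selection:
    """Parsed predicate over (chain, resid range, atom-name class)."""

    expr: str
    chain: str | None = field(init=False, default=None)
    resid_range: tuple | None = field(init=False, default=None)
    names: tuple | None = field(init=False, default=None)
    backbone: bool = field(init=False, default=False)
    heavy: bool = field(init=False, default=False)

    def __post_init__(self):
        tokens = self.expr.split()
        i = 0
        while i < len(tokens):
            tok = tokens[i].lower()
            if tok == "all":
                i += 1
            elif tok == "backbone":
                self.backbone = True
                i += 1
            elif tok == "heavy":
                self.heavy = True
                i += 1
            elif tok == "chain":
                self.chain = tokens[i + 1]
                i += 2
            elif tok == "resid":
                spec = tokens[i + 1]
                if "-" in spec:  # "3-10"; resids are 1-based, never negative
                    lo, _, hi = spec.partition("-")
                    self.resid_range = (int(lo), int(hi))
                else:
                    self.resid_range = (int(spec), int(spec))
                i += 2
            elif tok == "name":
                self.names = tuple(tokens[i + 1].split(","))
                i += 2
            else:
                raise ValueError(f"unknown selection token {tokens[i]!r} "
                                 f"in {self.expr!r}")

    def mask(self, top: Topology) -> np.ndarray:
        m = np.ones(top.n_atoms, dtype=bool)
        if self.chain is not None:
            m &= top.chain == self.chain
        if self.resid_range is not None:
            lo, hi = self.resid_range
            m &= (top.resid >= lo) & (top.resid <= hi)
        if self.names is not None:
            m &= np.isin(top.name, self.names)
        if self.backbone:
            m &= np.isin(top.name, BACKBONE_NAMES)
        if self.heavy:
            m &= top.element != "H"
        if not m.any():
            raise ValueError(f"selection {self.expr!r} matches no atoms")
        return m


# ---------------------------------------------------------------------------
# MDAnalysis-backed I/O
# ---------------------------------------------------------------------------

def _make_universe(top: Topology, ens: TrajectoryEnsemble):
    import MDAnalysis as mda

    chains = list(dict.fromkeys(top.chain.tolist()))
    # residues must be unique (chain, resid) pairs in order of appearance
    res_keys = []
    res_index = np.empty(top.n_atoms, dtype=int)
    for i in range(top.n_atoms):
        key = (top.chain[i], int(top.resid[i]))
        if not res_keys or res_keys[-1] != key:
            res_keys.append(key)
        res_index[i] = len(res_keys) - 1
    seg_of_res = [chains.index(c) for c, _ in res_keys]

    u = mda.Universe.empty(
        n_atoms=top.n_atoms, n_residues=len(res_keys),
        n_segments=len(chains), atom_resindex=res_index,
        residue_segindex=seg_of_res, trajectory=True)
    u.add_TopologyAttr("names", top.name.tolist())
    u.add_TopologyAttr("elements", top.element.tolist())
    u.add_TopologyAttr("masses", top.mass)
    u.add_TopologyAttr("resids", [r for _, r in res_keys])
    u.add_TopologyAttr("resnames",
                       [top.resname[res_index == k][0] for k in range(len(res_keys))])
    u.add_TopologyAttr("segids", chains)
    u.add_TopologyAttr("chainIDs", top.chain.tolist())
    # documented convention: occupancy = partial charge, tempfactor = radius
    u.add_TopologyAttr("occupancies", top.charge)
    u.add_TopologyAttr("tempfactors", top.radius)
    u.load_new(ens.coords.astype(np.float32), order="fac")
    return u


def write_system(top: Topology, ens: TrajectoryEnsemble, pdb_path,
                 dcd_path=None) -> None:
    """Write topology+trajectory as multi-model PDB (and optionally DCD).

    If ``dcd_path`` is given the PDB holds only the first frame (serving as
    the topology file) and all frames go to the DCD.
    """
    import MDAnalysis as mda

    u = _make_universe(top, ens)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if dcd_path is None:
            with mda.Writer(str(pdb_path), multiframe=True,
                            n_atoms=top.n_atoms) as w:
                for _ in u.trajectory:
                    w.write(u.atoms)
        else:
            u.trajectory[0]
            u.atoms.write(str(pdb_path))
            with mda.Writer(str(dcd_path), n_atoms=top.n_atoms) as w:
                for _ in u.trajectory:
                    w.write(u.atoms)


def read_system(pdb_path, dcd_path=None):
    """Read (Topology, TrajectoryEnsemble) written by :func:`write_system`."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if dcd_path is None:
            u = mda.Universe(str(pdb_path))
        else:
            u = mda.Universe(str(pdb_path), str(dcd_path))
        atoms = u.atoms
        chain = (atoms.chainIDs if hasattr(atoms, "chainIDs")
                 else atoms.segids)
        top = Topology(
            chain=np.asarray(chain, dtype=object),
            resid=atoms.resids.copy(),
            resname=np.asarray(atoms.resnames, dtype=object),
            name=np.asarray(atoms.names, dtype=object),
            element=np.asarray(
                atoms.elements if hasattr(atoms, "elements")
                else [n[0] for n in atoms.names], dtype=object),
            mass=atoms.masses.copy().astype(float),
            charge=atoms.occupancies.copy().astype(float),
            radius=atoms.tempfactors.copy().astype(float),
        )
        coords = np.array([atoms.positions.copy() for _ in u.trajectory],
                          dtype=float)
    return top, TrajectoryEnsemble(coords)
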