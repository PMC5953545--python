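"""Shared fixtures: synthetic titrations with ground truth, backbone/topology
converters, and a reference schedule mirroring a typical NMR titration."""

import numpy as np
import pytest

from tailscape.synth import (BackboneSpec, TitrationSpec, build_backbone,
                             ratio_schedule)
from tailscape.traj.system import Topology

#: PHD:ligand molar-ratio ladder used throughout (apo first).
TITRATION_RATIOS = [0, 0.1, 0.25, 0.5, 1, 2, 5, 10]
#: analyte ladder for BLI work, μM
BLI_CONCS = [20, 10, 5, 2.5, 1.3, 0.6, 0.3]

HELIX = (-57.0, -47.0)
EXTENDED = (-139.0, 135.0)


def make_titration_spec(kd_true=12.0, p0=50.0, n_responders=14, n_null=30,
                        noise=(0.0, 0.0), seed=0, dilution=0.0):
    """Titration with known responders (CSP endpoints drawn once per seed)
    and null residues whose apo == bound shifts."""
    from tailscape.studies import responder_titration_spec

    return responder_titration_spec(
        kd_true, p0=p0, n_responders=n_responders, n_null=n_null,
        noise=noise, seed=seed, dilution=dilution)


def backbone_topology(bb, chain="A"):
    """(Topology, frame) for a built backbone dict."""
    n_res = len(bb["N"])
    names, resid, el, coords = [], [], [], []
    for i in range(n_res):
        for a in ("N", "CA", "C", "O"):
            names.append(a)
            resid.append(i + 1)
            el.append("C" if a == "CA" else a[0])
            coords.append(bb[a][i])
    n = len(names)
    top = Topology(
        chain=np.array([chain] * n), resid=np.array(resid),
        resname=np.array(["ALA"] * n), name=np.array(names),
        element=np.array(el), mass=np.full(n, 12.0),
        charge=np.zeros(n), radius=np.full(n, 1.5))
    return top, np.array(coords)


def backbone_to_mdtraj(bb):
    """mdtraj Trajectory (nm) for the same backbone, for oracle comparisons."""
    import mdtraj as md

    n_res = len(bb["N"])
    top = md.Topology()
    ch = top.add_chain()
    xyz = []
    for i in range(n_res):
        res = top.add_residue("ALA", ch)
        for a, e in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            top.add_atom(a, md.element.get_by_symbol(e), res)
            xyz.append(bb[a][i])
    return md.Trajectory(np.asarray(xyz)[None] / 10.0, top)


@pytest.fixture
def helix15():
    return build_backbone(BackboneSpec([HELIX] * 15))


@pytest.fixture
def hairpin14():
    """Two antiparallel strands joined by a type-II' turn."""
    turn = [(60.0, -120.0), (-80.0, 0.0)]
    return build_backbone(BackboneSpec([EXTENDED] * 6 + turn + [EXTENDED] * 6))
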