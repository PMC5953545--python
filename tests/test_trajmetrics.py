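"""Rg, Kabsch RMSD (vs quaternion oracle), SASA, occupancy, energies."""

import numpy as np
import pytest

from tailscape.synth import TrajSpec, gen_tail_trajectory
from tailscape.traj import (end_state_rmsd, interaction_energy, kabsch_rmsd,
                            occupancy_grid, per_residue_energy,
                            radius_of_gyration, sasa)
from tailscape.traj.system import Topology, TrajectoryEnsemble


def point_topology(n, radius=1.9, charge=None, chain="A"):
    charge = np.zeros(n) if charge is None else np.asarray(charge, float)
    return Topology(
        chain=np.array([chain] * n), resid=np.arange(1, n + 1),
        resname=np.array(["X"] * n), name=np.array(["CA"] * n),
        element=np.array(["C"] * n), mass=np.full(n, 1.0),
        charge=charge, radius=np.full(n, radius))


def random_rigid_motion(rng):
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q, rng.normal(scale=20.0, size=3)


# ---------------------------------------------------------------------------
# radius of gyration
# ---------------------------------------------------------------------------

def test_rg_single_atom_is_zero():
    top = point_topology(1)
    assert radius_of_gyration(np.zeros((1, 3)), top) == 0.0


def test_rg_two_unit_masses_two_angstroms_apart():
    top = point_topology(2)
    frame = np.array([[0.0, 0, 0], [2.0, 0, 0]])
    assert radius_of_gyration(frame, top) == pytest.approx(1.0)


def test_rg_unit_square():
    top = point_topology(4)
    frame = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    assert radius_of_gyration(frame, top) == pytest.approx(np.sqrt(0.5))


def test_rg_mass_weighting_matters():
    top = point_topology(2)
    top.mass[:] = [1.0, 3.0]
    frame = np.array([[0.0, 0, 0], [4.0, 0, 0]])
    # COM at 3.0; Rg = sqrt((1*9 + 3*1)/4) = sqrt(3)
    assert radius_of_gyration(frame, top) == pytest.approx(np.sqrt(3.0))
    assert radius_of_gyration(frame, top, mass_weighted=False) == \
        pytest.approx(2.0)


def test_rg_rigid_motion_invariant():
    rng = np.random.default_rng(0)
    top = point_topology(12)
    frame = rng.normal(scale=5.0, size=(12, 3))
    base = radius_of_gyration(frame, top)
    for _ in range(5):
        R, t = random_rigid_motion(rng)
        assert radius_of_gyration(frame @ R + t, top) == pytest.approx(base)


# ---------------------------------------------------------------------------
# Kabsch RMSD vs quaternion oracle
# ---------------------------------------------------------------------------

def quaternion_rmsd(mobile, ref):
    """Independent optimal-superposition RMSD (Horn's quaternion method)."""
    P = mobile - mobile.mean(axis=0)
    Q = ref - ref.mean(axis=0)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz]])
    lam = np.linalg.eigvalsh(K)[-1]
    e2 = (np.sum(P ** 2) + np.sum(Q ** 2) - 2.0 * lam) / len(P)
    return float(np.sqrt(max(e2, 0.0)))


def test_identical_frames_zero_rmsd():
    rng = np.random.default_rng(1)
    top = point_topology(8)
    frame = rng.normal(size=(8, 3))
    assert kabsch_rmsd(frame, frame, top) == pytest.approx(0.0, abs=1e-12)


def test_rigid_motion_gives_zero_rmsd():
    rng = np.random.default_rng(2)
    top = point_topology(10)
    frame = rng.normal(scale=8.0, size=(10, 3))
    R, t = random_rigid_motion(rng)
    assert kabsch_rmsd(frame @ R + t, frame, top) == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("n_atoms", [5, 12, 25, 50])
def test_matches_quaternion_oracle(n_atoms):
    rng = np.random.default_rng(n_atoms)
    top = point_topology(n_atoms)
    for _ in range(10):
        a = rng.normal(scale=6.0, size=(n_atoms, 3))
        b = a + rng.normal(scale=1.5, size=(n_atoms, 3))
        R, t = random_rigid_motion(rng)
        assert kabsch_rmsd(b @ R + t, a, top) == pytest.approx(
            quaternion_rmsd(b, a), abs=1e-6)


def test_fitted_rmsd_never_exceeds_unfitted():
    rng = np.random.default_rng(3)
    top = point_topology(15)
    for _ in range(10):
        a = rng.normal(scale=5.0, size=(15, 3))
        b = a + rng.normal(scale=2.0, size=(15, 3))
        raw = float(np.sqrt(np.mean(np.sum((b - a) ** 2, axis=1))))
        assert kabsch_rmsd(b, a, top) <= raw + 1e-9


def test_fit_and_rmsd_selections_differ():
    # fit on the "core" (first 5 atoms), measure the "tail" (last 5)
    rng = np.random.default_rng(4)
    top = point_topology(10)
    core = rng.normal(scale=4.0, size=(5, 3))
    tail_a = rng.normal(scale=4.0, size=(5, 3)) + 10.0
    tail_b = tail_a + rng.normal(scale=3.0, size=(5, 3))
    a = np.vstack([core, tail_a])
    b = np.vstack([core, tail_b])
    r = kabsch_rmsd(b, a, top, fit_sel="resid 1-5", rmsd_sel="resid 6-10")
    expect = float(np.sqrt(np.mean(np.sum((tail_b - tail_a) ** 2, axis=1))))
    assert r == pytest.approx(expect, abs=1e-9)


def test_atom_count_mismatch_rejected():
    top = point_topology(4)
    with pytest.raises(ValueError):
        kabsch_rmsd(np.zeros((3, 3)), np.zeros((4, 3)), top)


# ---------------------------------------------------------------------------
# end-state RMSD
# ---------------------------------------------------------------------------

def test_end_state_identical_frames():
    top = point_topology(6)
    f = np.arange(18.0).reshape(6, 3)
    mean, mat = end_state_rmsd([f, f.copy(), f.copy()], top)
    assert mean == pytest.approx(0.0, abs=1e-12)


def test_end_state_two_frames_equals_pairwise():
    rng = np.random.default_rng(5)
    top = point_topology(6)
    a = rng.normal(size=(6, 3))
    b = rng.normal(size=(6, 3))
    mean, _ = end_state_rmsd([a, b], top)
    assert mean == pytest.approx(kabsch_rmsd(b, a, top))


def test_within_group_mean_much_smaller_than_all_pairs():
    rng = np.random.default_rng(6)
    top = point_topology(8)
    c1 = rng.normal(scale=3.0, size=(8, 3))
    c2 = c1 + 60.0 + rng.normal(scale=3.0, size=(8, 3))
    frames, labels = [], []
    for k in range(3):
        frames.append(c1 + rng.normal(scale=0.2, size=(8, 3)))
        labels.append("g1")
        frames.append(c2 + rng.normal(scale=0.2, size=(8, 3)))
        labels.append("g2")
    mean, _, per_group = end_state_rmsd(frames, top, groups=labels)
    within = np.mean(list(per_group.values()))
    assert within < 0.25 * mean


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def test_isolated_atom_closed_form():
    top = point_topology(1, radius=1.9)
    total, per_res = sasa(np.zeros((1, 3)), top)
    assert total == pytest.approx(4 * np.pi * 3.3 ** 2, rel=1e-3)
    assert per_res[("A", 1)] == pytest.approx(total)


def test_fully_enclosed_atom_zero():
    # cage of large atoms around a small one
    shell = []
    for th in np.linspace(0, np.pi, 6):
        for ph in np.linspace(0, 2 * np.pi, 12, endpoint=False):
            shell.append([3.0 * np.sin(th) * np.cos(ph),
                          3.0 * np.sin(th) * np.sin(ph), 3.0 * np.cos(th)])
    frame = np.vstack([[0.0, 0, 0], shell])
    top = point_topology(len(frame))
    top.radius[:] = 1.0
    top.radius[1:] = 2.5
    total, _ = sasa(frame, top, sel="resid 1")
    assert total == pytest.approx(0.0, abs=1e-9)


def test_disjoint_atoms_additive():
    top = point_topology(2, radius=1.9)
    frame = np.array([[0.0, 0, 0], [50.0, 0, 0]])
    total, _ = sasa(frame, top)
    single = 4 * np.pi * 3.3 ** 2
    assert total == pytest.approx(2 * single, rel=1e-3)


def test_sasa_converges_under_point_doubling():
    rng = np.random.default_rng(7)
    frame = rng.normal(scale=3.0, size=(20, 3))
    top = point_topology(20, radius=1.7)
    t1, _ = sasa(frame, top, n_sphere_points=960)
    t2, _ = sasa(frame, top, n_sphere_points=1920)
    assert abs(t2 - t1) / t2 < 0.005


def test_missing_radius_rejected():
    top = point_topology(2)
    top.radius[1] = 0.0
    with pytest.raises(ValueError):
        sasa(np.zeros((2, 3)), top)


# ---------------------------------------------------------------------------
# occupancy grids
# ---------------------------------------------------------------------------

def static_ensemble(pos, n_frames):
    coords = np.tile(np.asarray(pos, float)[None], (n_frames, 1, 1))
    return TrajectoryEnsemble(coords)


def test_static_atom_single_voxel():
    top = point_topology(1)
    ens = static_ensemble([[0.25, 0.25, 0.25]], 100)
    g = occupancy_grid(ens, top, sel="all", align_fit_sel="all")
    assert g.values.max() == pytest.approx(1.0)
    assert (g.values > 0).sum() == 1


def test_alternating_atom_half_occupancy():
    top = point_topology(2)
    # one fixed anchor defines the alignment; the second atom alternates
    coords = np.zeros((10, 2, 3))
    coords[:, 0] = [20.0, 0.0, 0.0]
    coords[::2, 1] = [0.25, 0.25, 0.25]
    coords[1::2, 1] = [5.25, 0.25, 0.25]
    g = occupancy_grid(TrajectoryEnsemble(coords), top, sel="resid 2",
                       align_fit_sel="resid 1-2")
    vals = np.sort(g.values[g.values > 0])
    assert np.allclose(vals, [0.5, 0.5])


def test_occupancy_bounded_and_frame_order_invariant():
    e, t = gen_tail_trajectory(TrajSpec(40, 8, collapse=0.7, seed=9))
    g1 = occupancy_grid(e, t, sel="chain T", align_fit_sel="chain D")
    assert g1.values.min() >= 0.0 and g1.values.max() <= 1.0
    rng = np.random.default_rng(0)
    perm = rng.permutation(e.n_frames)
    g2 = occupancy_grid(TrajectoryEnsemble(e.coords[perm]), t, sel="chain T",
                        align_fit_sel="chain D")
    assert np.array_equal(g1.values > 0, g2.values > 0)
    assert np.allclose(g1.values, g2.values)


def test_collapsed_tail_mass_hugs_surface():
    from tailscape.synth.tail import surface_distance
    e, t = gen_tail_trajectory(TrajSpec(200, 10, collapse=1.0, seed=7))
    g = occupancy_grid(e, t, sel="chain T", align_fit_sel="chain D")
    X, Y, Z = g.voxel_centers()
    centers = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    d = surface_distance(centers)
    mass = g.values.ravel()
    assert mass[d <= 5.0].sum() / mass.sum() >= 0.9


def test_count_mode_differs_from_fraction_mode():
    top = point_topology(2)
    # both atoms in the same voxel every frame: fraction 1.0, count 2.0
    ens = static_ensemble([[0.2, 0.2, 0.2], [0.3, 0.3, 0.3]], 5)
    gf = occupancy_grid(ens, top, sel="all", align_fit_sel="all")
    gc = occupancy_grid(ens, top, sel="all", align_fit_sel="all", mode="count")
    assert gf.values.max() == pytest.approx(1.0)
    assert gc.values.max() == pytest.approx(2.0)


def test_dx_output_is_parseable(tmp_path):
    top = point_topology(1)
    g = occupancy_grid(static_ensemble([[0.0, 0, 0]], 3), top,
                       sel="all", align_fit_sel="all")
    p = tmp_path / "grid.dx"
    g.write_dx(p)
    text = p.read_text()
    assert "gridpositions" in text and "data follows" in text
    n_items = int(text.split("items")[1].split("data")[0])
    assert n_items == g.values.size


# ---------------------------------------------------------------------------
# interaction energies
# ---------------------------------------------------------------------------

def test_unit_charges_at_reference_distance():
    top = point_topology(2, charge=[1.0, -1.0])
    top.chain[1] = "B"
    frame = np.array([[0.0, 0, 0], [3.320636, 0, 0]])
    e = interaction_energy(frame, top, "chain A", "chain B", dielectric=1.0)
    assert e == pytest.approx(-100.0, abs=1e-3)


def test_zero_charges_zero_energy():
    top = point_topology(4)
    top.chain[2:] = "B"
    frame = np.arange(12.0).reshape(4, 3)
    assert interaction_energy(frame, top, "chain A", "chain B") == 0.0


def test_energy_linear_in_charge():
    rng = np.random.default_rng(8)
    q = rng.normal(size=6)
    top = point_topology(6, charge=q)
    top.chain[3:] = "B"
    frame = rng.normal(scale=4.0, size=(6, 3))
    e1 = interaction_energy(frame, top, "chain A", "chain B")
    top.charge[:3] *= 2.0
    e2 = interaction_energy(frame, top, "chain A", "chain B")
    assert e2 == pytest.approx(2.0 * e1)


def test_overlapping_selections_rejected():
    top = point_topology(3, charge=[1, 1, -1])
    with pytest.raises(ValueError, match="overlap"):
        interaction_energy(np.zeros((3, 3)), top, "resid 1-2", "resid 2-3")


def test_distance_dependent_dielectric_screens():
    top = point_topology(2, charge=[1.0, -1.0])
    top.chain[1] = "B"
    frame = np.array([[0.0, 0, 0], [5.0, 0, 0]])
    e_vac = interaction_energy(frame, top, "chain A", "chain B", dielectric=1.0)
    e_scr = interaction_energy(frame, top, "chain A", "chain B")
    assert abs(e_scr) == pytest.approx(abs(e_vac) / 20.0)   # eps = 4r = 20


# ---------------------------------------------------------------------------
# per-residue aggregation
# ---------------------------------------------------------------------------

def test_single_sample_sem_absent():
    e, t = gen_tail_trajectory(TrajSpec(1, 6, collapse=0.5, seed=1))
    dec = per_residue_energy([(e, t)], tail_chains=("T",))
    assert dec.n_samples == 1
    assert dec.sem_undefined
    assert np.all(np.isnan(dec.sem))


def test_identical_samples_zero_sem():
    e, t = gen_tail_trajectory(TrajSpec(5, 6, collapse=0.5, seed=2))
    dec = per_residue_energy([(e, t), (e, t)], tail_chains=("T",))
    assert dec.n_samples == 2
    assert np.allclose(dec.sem, 0.0)


def test_sample_count_two_per_simulation():
    # two tail chains per topology -> 2 samples per simulation
    e, t = gen_tail_trajectory(TrajSpec(4, 5, collapse=0.5, seed=3))
    t2 = Topology(**{k: (v.copy() if hasattr(v, "copy") else v)
                     for k, v in vars(t).items()})
    t2.chain = np.where(t2.chain == "T", "U", t2.chain)
    sims = [(e, t), (e, t2)]
    # one chain each here; use both chains in one topology instead
    both = Topology(
        chain=np.concatenate([t.chain[:5], ["U"] * 5, t.chain[5:]]),
        resid=np.concatenate([t.resid[:5], np.arange(1, 6), t.resid[5:]]),
        resname=np.concatenate([t.resname[:5], ["TLR"] * 5, t.resname[5:]]),
        name=np.concatenate([t.name[:5], ["CA"] * 5, t.name[5:]]),
        element=np.concatenate([t.element[:5], ["C"] * 5, t.element[5:]]),
        mass=np.concatenate([t.mass[:5], np.full(5, 110.0), t.mass[5:]]),
        charge=np.concatenate([t.charge[:5], np.ones(5), t.charge[5:]]),
        radius=np.concatenate([t.radius[:5], np.full(5, 1.9), t.radius[5:]]))
    coords = np.concatenate(
        [e.coords[:, :5], e.coords[:, :5] + [0, 0, 60.0], e.coords[:, 5:]],
        axis=1)
    dec = per_residue_energy([(TrajectoryEnsemble(coords), both)],
                             tail_chains=("T", "U"))
    assert dec.n_samples == 2


def test_neutralisation_weakens_binding_energy():
    charges = [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
    quad = list(charges)
    for i in (2, 4, 6, 8):
        quad[i] = 0.0
    eF, tF = gen_tail_trajectory(
        TrajSpec(40, 10, collapse=0.8, tail_charges=charges, seed=3))
    eQ, tQ = gen_tail_trajectory(
        TrajSpec(40, 10, collapse=0.8, tail_charges=quad, seed=3))
    dF = per_residue_energy([(eF, tF)], tail_chains=("T",))
    dQ = per_residue_energy([(eQ, tQ)], tail_chains=("T",))
    assert abs(dQ.total) < abs(dF.total)


def test_mismatched_group_topologies_rejected():
    e1, t1 = gen_tail_trajectory(TrajSpec(2, 6, collapse=0.5, seed=1))
    e2, t2 = gen_tail_trajectory(TrajSpec(2, 8, collapse=0.5, seed=1))
    with pytest.raises(ValueError, match="mismatch"):
        per_residue_energy([(e1, t1), (e2, t2)], tail_chains=("T",))
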