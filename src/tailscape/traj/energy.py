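"""Pairwise tail–DNA interaction energies and their ensemble aggregation.

The energy model is a screened Coulomb sum with a distance-dependent
dielectric (ε(r) = 4r by default) plus optional Lennard-Jones terms::

    E = Σ_{i∈A, j∈B} 332.0636 · q_i q_j / (ε(r_ij) · r_ij)

It is a deliberately simple surrogate for solvated per-residue
decompositions: absolute values are qualitative, but the aggregation
statistics (per-residue means, SEM over tail×simulation samples, group
totals) are exact, and orderings under charge neutralisation are
physically meaningful.

Sampling convention: each of the two tail copies in a simulation is one
observation of the tail ensemble, so a group of S simulations yields
2·S samples; reported errors are the SEM across those samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .system import Topology, TrajectoryEnsemble

__all__ = ["interaction_energy", "per_residue_energy", "EnergyDecomposition"]

COULOMB_KCAL = 332.0636  # kcal·Å/(mol·e²)


def _dielectric(model):
    if model == "distance":           # ε(r) = 4r
        return lambda r: 4.0 * r
    if isinstance(model, (int, float)):
        eps = float(model)
        return lambda r: np.full_like(r, eps)
    if callable(model):
        return model
    raise ValueError(f"unknown dielectric model {model!r}")


def interaction_energy(frame, top: Topology, sel_a, sel_b,
                       dielectric="distance", lennard_jones: bool = False) -> float:
    """Screened Coulomb (+ optional LJ) energy between two disjoint
    selections, kcal/mol."""
    ma, mb = top.select(sel_a), top.select(sel_b)
    if np.any(ma & mb):
        raise ValueError("selections overlap; interaction energy undefined")
    xyz = np.asarray(frame, dtype=float)
    ra, rb = xyz[ma], xyz[mb]
    qa, qb = top.charge[ma], top.charge[mb]
    diff = ra[:, None, :] - rb[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    if np.any(r < 1e-9):
        raise ValueError("zero interatomic distance between selections")
    eps_fn = _dielectric(dielectric)
    e = float(np.sum(COULOMB_KCAL * np.outer(qa, qb) / (eps_fn(r) * r)))
    if lennard_jones:
        if top.lj_eps is None or top.lj_sigma is None:
            raise ValueError("topology carries no Lennard-Jones parameters")
        eps_ij = np.sqrt(np.outer(top.lj_eps[ma], top.lj_eps[mb]))
        sig_ij = 0.5 * (top.lj_sigma[ma][:, None] + top.lj_sigma[mb][None, :])
        sr6 = (sig_ij / r) ** 6
        e += float(np.sum(4.0 * eps_ij * (sr6 ** 2 - sr6)))
    return e


@dataclass
class EnergyDecomposition:
    """Per-residue mean ± SEM over samples, plus the group totals."""

    residues: np.ndarray               # tail residue ids
    mean: np.ndarray                   # kcal/mol per residue
    sem: np.ndarray                    # NaN when n_samples == 1
    n_samples: int
    samples: np.ndarray                # (n_samples, n_residues)
    total: float = field(init=False)
    sem_undefined: bool = field(init=False)

    def __post_init__(self):
        self.total = float(np.sum(self.mean))
        self.sem_undefined = self.n_samples < 2


def per_residue_energy(simulations, tail_chains=("T", "U"), dna_sel="chain D",
                       dielectric="distance") -> EnergyDecomposition:
    """Aggregate per-tail-residue DNA interaction energies over a group.

    ``simulations`` is a sequence of ``(TrajectoryEnsemble, Topology)``
    pairs forming one group (same chemistry and initial-conformation set);
    every topology must expose the same tail residues on each chain listed
    in ``tail_chains`` (chains absent from a topology are skipped, so
    single-tail systems are accepted and contribute one sample each).

    Each (simulation, tail chain) pair is one sample; a sample's value per
    residue is the frame-averaged interaction energy of that residue with
    the DNA selection. Returns per-residue group mean and SEM over samples
    and the chemistry-level total (sum of per-residue means).
    """
    if not simulations:
        raise ValueError("need at least one simulation in the group")
    ref_resids = None
    sample_rows = []
    for ens, top in simulations:
        present = [c for c in tail_chains if np.any(top.chain == c)]
        if not present:
            raise ValueError(f"no tail chains {tail_chains} in topology")
        for chain in present:
            resids = np.unique(top.resid[top.chain == chain])
            resids.sort()
            if ref_resids is None:
                ref_resids = resids
            elif not np.array_equal(resids, ref_resids):
                raise ValueError(
                    "mismatched tail residue sets across the group")
            per_res = np.zeros(len(resids))
            for k, r in enumerate(resids):
                sel = f"chain {chain} resid {r}"
                vals = [interaction_energy(ens[f], top, sel, dna_sel,
                                           dielectric=dielectric)
                        for f in range(ens.n_frames)]
                per_res[k] = float(np.mean(vals))
            sample_rows.append(per_res)

    samples = np.vstack(sample_rows)
    n = samples.shape[0]
    mean = samples.mean(axis=0)
    sem = (samples.std(axis=0, ddof=1) / np.sqrt(n) if n > 1
           else np.full(samples.shape[1], np.nan))
    return EnergyDecomposition(residues=ref_resids, mean=mean, sem=sem,
                               n_samples=n, samples=samples)
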