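"""Reproduction protocols: replicate recovery studies with known truth.

These drivers compose the generators and fitting pipelines into the
standard end-to-end checks for this kind of analysis: simulate a titration
or sensorgram set with a known dissociation constant under realistic noise,
run the full pipeline, and summarise the recovered Kd over replicate seeds.
They are used both by the test suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .blieq import run_bli_analysis
from .cspfit import run_titration_analysis
from .synth import BLISpec, TitrationSpec, gen_bli, gen_titration, \
    ratio_schedule

__all__ = ["responder_titration_spec", "nmr_kd_recovery",
           "bli_kd_recovery", "TITRATION_RATIOS", "BLI_LADDER"]

#: receptor:ligand molar-ratio ladder of a typical tail-peptide titration
TITRATION_RATIOS = (0, 0.1, 0.25, 0.5, 1, 2, 5, 10)
#: analyte concentrations (μM) of the reference BLI dilution series
BLI_LADDER = (20.0, 10.0, 5.0, 2.5, 1.3, 0.6, 0.3)

#: default shift noise, ppm (¹H, ¹⁵N) — typical peak-picking precision
NMR_NOISE = (0.002, 0.01)


def responder_titration_spec(kd_true: float, p0: float = 50.0,
                             n_responders: int = 14, n_null: int = 30,
                             noise=NMR_NOISE, seed: int = 0,
                             dilution: float = 0.0) -> TitrationSpec:
    """Titration spec with ``n_responders`` binding-site residues (CSP
    endpoints drawn once from the seed) among ``n_null`` spectator residues
    whose bound state equals their apo state."""
    rng = np.random.default_rng(seed)
    n = n_responders + n_null
    residues = [f"r{i}" for i in range(n)]
    apo = {r: (8.0 + 0.6 * rng.random(), 112.0 + 12.0 * rng.random())
           for r in residues}
    bound = {}
    for i, r in enumerate(residues):
        if i < n_responders:
            bound[r] = (apo[r][0] + 0.05 + 0.25 * rng.random(),
                        apo[r][1] + 0.3 + 1.5 * rng.random())
        else:
            bound[r] = apo[r]
    return TitrationSpec(
        residues=residues, apo_shift=apo, bound_shift=bound, kd_true=kd_true,
        points=ratio_schedule(p0, list(TITRATION_RATIOS), dilution=dilution),
        noise_sd=tuple(noise), seed=seed)


def nmr_kd_recovery(kd_true: float, n_replicates: int = 20,
                    base_seed: int = 0, noise=NMR_NOISE) -> dict:
    """Full CSP pipeline over replicate noisy titrations.

    Returns the per-replicate aggregate Kd values and their median (μM).
    """
    kds = []
    for k in range(n_replicates):
        spec = responder_titration_spec(kd_true, noise=noise,
                                        seed=base_seed + k)
        result = run_titration_analysis(gen_titration(spec))
        kds.append(result.kd_mean)
    return {"kd_true": kd_true, "replicates": kds,
            "median": float(np.median(kds))}


def bli_kd_recovery(kd_true: float = 7.0, n_replicates: int = 20,
                    base_seed: int = 0, concs=BLI_LADDER,
                    noise_sd: float = 0.01) -> dict:
    """Full BLI pipeline (double referencing → baseline alignment →
    Savitzky–Golay → r_eq → hyperbolic fit) over replicate sensorgram sets."""
    kds = []
    for k in range(n_replicates):
        spec = BLISpec(analyte_concs=list(concs), kd_true=kd_true,
                       noise_sd=noise_sd, seed=base_seed + k)
        curve = run_bli_analysis(gen_bli(spec), scheme="double")
        kds.append(curve.kd)
    return {"kd_true": kd_true, "replicates": kds,
            "median": float(np.median(kds))}
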