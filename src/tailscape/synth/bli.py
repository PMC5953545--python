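"""Synthetic 1:1 BLI sensorgrams with reference-channel artifacts.

The binding signal follows simple 1:1 kinetics with
``koff = kon * Kd`` and an association plateau at the closed-form
equilibrium response ``Req = (rmax - r0) * C / (C + Kd)``. The default
kon of 0.1 μM⁻¹s⁻¹ is fast enough that a 300 s association phase
plateaus at every concentration of interest, matching the fast-kinetics
regime where only the equilibrium analysis is meaningful.

Channel artifacts emulate what double referencing is for:

* a linear instrument drift common to the loaded sensors (sample and the
  loaded-vs-buffer ``reference`` channel);
* an analyte-dependent optical offset common to everything dipped in
  analyte (sample and the unloaded ``double_reference`` channels);
* white noise everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..blieq import SensorGram

__all__ = ["BLISpec", "gen_bli"]


@dataclass
class BLISpec:
    analyte_concs: list                  # μM
    kd_true: float                       # μM
    kon: float = 0.1                     # 1/(μM·s)
    rmax: float = 1.0                    # response units (nm)
    r0: float = 0.0
    phase_durations: tuple = (180.0, 300.0, 300.0)
    sample_rate: float = 10.0            # Hz
    drift_rate: float = 1e-4             # response/s, loaded-sensor drift
    optical_offset: float = 0.01         # response per μM analyte (artifact)
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.kon <= 0:
            raise ValueError("kon must be > 0")
        if self.kd_true <= 0:
            raise ValueError("kd_true must be > 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if any(d <= 0 for d in self.phase_durations):
            raise ValueError("phase durations must all be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _time_and_phase(spec: BLISpec):
    tb, ta, td = spec.phase_durations
    dt = 1.0 / spec.sample_rate
    t = np.arange(0.0, tb + ta + td, dt)
    phase = np.where(t < tb, "baseline",
                     np.where(t < tb + ta, "association", "dissociation"))
    return t, phase, tb, ta


def _binding_signal(spec: BLISpec, conc: float, t, phase, tb, ta):
    """Noise-free specific binding trace (zero during baseline)."""
    koff = spec.kon * spec.kd_true
    kobs = spec.kon * conc + koff
    req = (spec.rmax - spec.r0) * conc / (conc + spec.kd_true)
    sig = np.zeros_like(t)
    assoc = phase == "association"
    dissoc = phase == "dissociation"
    sig[assoc] = req * (1.0 - np.exp(-kobs * (t[assoc] - tb)))
    r_end = req * (1.0 - np.exp(-kobs * ta))
    sig[dissoc] = r_end * np.exp(-koff * (t[dissoc] - tb - ta))
    return sig


def gen_bli(spec: BLISpec) -> list[SensorGram]:
    """Generate sample + reference channels for every analyte concentration.

    Returns one ``sample`` and one ``double_reference`` channel per
    concentration plus a single loaded-vs-buffer ``reference`` channel.
    """
    rng = np.random.default_rng(spec.seed)
    t, phase, tb, ta = _time_and_phase(spec)
    in_analyte = phase != "baseline"

    def noise():
        return rng.normal(0.0, spec.noise_sd, size=t.shape)

    drift = spec.drift_rate * t
    grams = []
    for i, conc in enumerate(spec.analyte_concs):
        optical = np.where(in_analyte, spec.optical_offset * conc, 0.0)
        sig = _binding_signal(spec, conc, t, phase, tb, ta)
        grams.append(SensorGram(
            channel_id=f"sample_{i}", role="sample", analyte_conc=conc,
            time=t, response=spec.r0 + sig + drift + optical + noise(),
            phase=phase))
        grams.append(SensorGram(
            channel_id=f"dblref_{i}", role="double_reference",
            analyte_conc=conc, time=t,
            response=optical + noise(), phase=phase))
    grams.append(SensorGram(
        channel_id="ref_buffer", role="reference", analyte_conc=0.0,
        time=t, response=spec.r0 + drift + noise(), phase=phase))
    return grams
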