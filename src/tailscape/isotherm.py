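"""Single-site binding isotherm under ligand depletion.

When the ligand concentration is comparable to the receptor concentration
(the usual situation in NMR-detected titrations, where the observed protein
is at tens of micromolar), the free-ligand approximation fails and the
bound fraction must be obtained from the exact quadratic solution of the
1:1 equilibrium::

    f_B = ((L + P + Kd) - sqrt((L + P + Kd)^2 - 4 P L)) / (2 P)

with P the total receptor concentration, L the total ligand concentration
and Kd the dissociation constant (all in the same concentration units,
micromolar throughout this package).
"""

from __future__ import annotations

import numbers

import numpy as np

__all__ = ["fraction_bound"]


def _check_finite_nonneg(name: str, value, allow_zero: bool = True) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if allow_zero:
        if np.any(arr < 0):
            raise ValueError(f"{name} must be >= 0, got {value!r}")
    else:
        if np.any(arr <= 0):
            raise ValueError(f"{name} must be > 0, got {value!r}")
    return arr


def fraction_bound(P, L, Kd):
    """Fraction of receptor bound at total concentrations ``P`` and ``L``.

    Parameters
    ----------
    P : float or array-like
        Total receptor (observed species) concentration, μM. Must be > 0.
    L : float or array-like
        Total ligand concentration, μM. Must be >= 0.
    Kd : float
        Dissociation constant, μM. Must be >= 0 (0 is the stoichiometric
        limit, where the bound fraction is ``min(L, P) / P``).

    Returns
    -------
    float or ndarray
        Bound fraction in [0, 1]; scalar if all inputs are scalar.
    """
    scalar = all(isinstance(x, numbers.Number) for x in (P, L, Kd))
    P = _check_finite_nonneg("P", P, allow_zero=False)
    L = _check_finite_nonneg("L", L)
    Kd = _check_finite_nonneg("Kd", Kd)

    s = L + P + Kd
    disc = s * s - 4.0 * P * L
    # disc >= (L - P + Kd)^2 - 4 P Kd ... analytically >= 0; clip rounding
    f = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * P)
    f = np.clip(f, 0.0, 1.0)
    return float(f) if scalar else f
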