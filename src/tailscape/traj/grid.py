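"""Voxel occupancy maps of atom locations over an ensemble.

Frames are rigid-body fitted to a reference (the first frame by default,
or an externally supplied structure such as a crystal model), then the
selected heavy atoms are binned on an isotropic grid (1.0 Å spacing by
default). Occupancy is the fraction of frames in which at least one
selected atom falls in the voxel ("fraction" mode); "count" mode records
the mean number of atoms per frame instead. The grid auto-sizes to cover
all selected atoms in all fitted frames with a 2 Å margin.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .metrics import kabsch_fit
from .system import Topology, TrajectoryEnsemble

__all__ = ["OccupancyGrid", "occupancy_grid"]

MARGIN = 2.0  # Å


@dataclass
class OccupancyGrid:
    origin: np.ndarray          # Å, corner of voxel (0,0,0)
    spacing: float              # Å, isotropic
    values: np.ndarray          # (nx, ny, nz)
    mode: str = "fraction"

    @property
    def shape(self):
        return self.values.shape

    def voxel_centers(self):
        nx, ny, nz = self.values.shape
        axes = [self.origin[d] + (np.arange(n) + 0.5) * self.spacing
                for d, n in enumerate((nx, ny, nz))]
        return np.meshgrid(*axes, indexing="ij")

    def write_dx(self, path) -> None:
        """Write the grid in OpenDX format (as used by visualisation tools)."""
        nx, ny, nz = self.values.shape
        ox, oy, oz = self.origin
        s = self.spacing
        lines = [
            f"object 1 class gridpositions counts {nx} {ny} {nz}",
            f"origin {ox:.6f} {oy:.6f} {oz:.6f}",
            f"delta {s:.6f} 0.000000 0.000000",
            f"delta 0.000000 {s:.6f} 0.000000",
            f"delta 0.000000 0.000000 {s:.6f}",
            f"object 2 class gridconnections counts {nx} {ny} {nz}",
            f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
        ]
        flat = self.values.ravel(order="C")
        for i in range(0, flat.size, 3):
            lines.append(" ".join(f"{v:.6g}" for v in flat[i:i + 3]))
        lines.append('attribute "dep" string "positions"')
        lines.append('object "density" class field')
        Path(path).write_text("\n".join(lines) + "\n")


def occupancy_grid(ens: TrajectoryEnsemble, top: Topology, sel="heavy",
                   align_fit_sel="all", reference=None, spacing: float = 1.0,
                   mode: str = "fraction") -> OccupancyGrid:
    """Occupancy map of the selected atoms over all frames.

    ``reference`` is an (n_atoms, 3) frame to superpose onto; by default
    the first frame of the ensemble.
    """
    if mode not in ("fraction", "count"):
        raise ValueError("mode must be 'fraction' or 'count'")
    sel_m = top.select(sel)
    fit_m = top.select(align_fit_sel)
    ref = np.asarray(reference if reference is not None else ens[0],
                     dtype=float)

    fitted = np.empty((ens.n_frames, int(sel_m.sum()), 3))
    for f in range(ens.n_frames):
        frame = ens[f]
        R, t = kabsch_fit(frame[fit_m], ref[fit_m])
        fitted[f] = (frame @ R + t)[sel_m]

    lo = fitted.reshape(-1, 3).min(axis=0) - MARGIN
    hi = fitted.reshape(-1, 3).max(axis=0) + MARGIN
    origin = np.floor(lo / spacing) * spacing
    shape = np.ceil((hi - origin) / spacing).astype(int) + 1

    values = np.zeros(tuple(shape))
    for f in range(ens.n_frames):
        idx = np.floor((fitted[f] - origin) / spacing).astype(int)
        if np.any(idx < 0) or np.any(idx >= shape):
            raise RuntimeError("atom outside auto-sized grid (internal error)")
        if mode == "fraction":
            seen = np.unique(idx, axis=0)
            values[seen[:, 0], seen[:, 1], seen[:, 2]] += 1.0
        else:
            np.add.at(values, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    values /= ens.n_frames
    return OccupancyGrid(origin=origin, spacing=float(spacing),
                         values=values, mode=mode)
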