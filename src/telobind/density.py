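"""Spatial occupancy densities on a regular voxel grid.

After superposing frames on a reference selection, the occupancy of a voxel
is the fraction of frames in which at least one atom of the analysed
selection lies inside it — the quantity whose high-probability isosurfaces
show the conformations available to interface side chains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import FrameEnsemble
from .rotations import best_fit_rotation

__all__ = ["OccupancyGrid", "occupancy_density"]


@dataclass
class OccupancyGrid:
    """Voxel occupancies with origin/spacing metadata (nm)."""

    origin: np.ndarray         # (3,)
    spacing: float
    values: np.ndarray         # (nx, ny, nz), per-voxel frame fraction

    def voxel_of(self, point: np.ndarray) -> tuple[int, int, int]:
        ijk = np.floor((np.asarray(point) - self.origin) / self.spacing)
        return tuple(int(v) for v in ijk)


def occupancy_density(
    ensemble: FrameEnsemble,
    selection: np.ndarray,
    grid_spacing: float = 0.05,
    fit_selection: np.ndarray | None = None,
    padding: float = 0.1,
) -> OccupancyGrid:
    """Per-voxel fraction of frames with >= 1 selected atom inside.

    ``fit_selection`` (default: the analysed selection itself) defines the
    rigid-body superposition reference; frames are fitted onto frame 0 of
    that selection before counting.
    """
    sel = np.asarray(selection, int)
    if sel.size == 0:
        raise ValueError("empty selection")
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    fit_sel = sel if fit_selection is None else np.asarray(fit_selection, int)

    coords = ensemble.coords
    if fit_sel.size < 3:
        # too few atoms to define an orientation; analyse raw coordinates
        moved = coords[:, sel, :].copy()
    else:
        masses = ensemble.masses(fit_sel)
        w = masses / masses.sum()
        ref = coords[0, fit_sel]
        ref_c = ref - np.average(ref, axis=0, weights=w)
        moved = np.empty((ensemble.n_frames, sel.size, 3))
        for f in range(ensemble.n_frames):
            x = coords[f, fit_sel]
            cx = np.average(x, axis=0, weights=w)
            R = best_fit_rotation(x - cx, ref_c, masses)
            moved[f] = (coords[f, sel] - cx) @ R

    lo = moved.reshape(-1, 3).min(axis=0) - padding
    hi = moved.reshape(-1, 3).max(axis=0) + padding
    shape = np.maximum(np.ceil((hi - lo) / grid_spacing).astype(int), 1)
    values = np.zeros(shape)
    for f in range(ensemble.n_frames):
        ijk = np.floor((moved[f] - lo) / grid_spacing).astype(int)
        ijk = np.clip(ijk, 0, shape - 1)
        uniq = np.unique(ijk, axis=0)
        values[uniq[:, 0], uniq[:, 1], uniq[:, 2]] += 1.0
    values /= ensemble.n_frames
    return OccupancyGrid(origin=lo, spacing=grid_spacing, values=values)
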