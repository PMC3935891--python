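"""Shrake-Rupley solvent-accessible surface area.

Quasi-uniform test points (Fibonacci sphere) are placed on each atom's
expanded sphere of radius r_vdw + probe; a point is accessible iff it lies
outside every neighbouring atom's expanded sphere, and the atom's area is
the accessible fraction times 4 pi (r_vdw + probe)^2.  Areas are reported
per atom (nm^2) together with hydrophobic (C, S), hydrophilic (everything
else: N, O, P, H, ...) and overall totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import BONDI_RADII_NM, HYDROPHOBIC_ELEMENTS
from .ensemble import FrameEnsemble

__all__ = ["sasa", "SasaResult", "fibonacci_sphere"]


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)


@dataclass
class SasaResult:
    per_atom: np.ndarray       # nm^2, aligned to the atom table
    hydrophobic: float         # nm^2 total over C and S atoms
    hydrophilic: float         # nm^2 total over all other elements
    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def sasa(
    ensemble: FrameEnsemble,
    frame: int,
    probe_radius: float = 0.14,
    n_sphere_points: int = 960,
    radii_override: dict[str, float] | None = None,
    subset: np.ndarray | None = None,
) -> SasaResult:
    """Per-atom SASA of one frame, nm^2.

    probe_radius : solvent probe, nm (0.14 = water).
    radii_override : element -> vdW radius (nm), merged over the Bondi set;
        an element absent from both tables raises.
    subset : atom indices to compute (neighbours still occlude).
    """
    radii_table = dict(BONDI_RADII_NM)
    if radii_override:
        radii_table.update({k.upper(): v for k, v in radii_override.items()})
    elements = [str(e).upper() for e in ensemble.atoms["element"]]
    missing = sorted({e for e in elements if e not in radii_table})
    if missing:
        raise ValueError(f"no vdW radius for element(s) {missing}; "
                         "supply radii_override")
    radii = np.array([radii_table[e] for e in elements]) + probe_radius

    xyz = ensemble.coords[frame]
    n = len(elements)
    targets = np.arange(n) if subset is None else np.asarray(subset, int)
    unit = fibonacci_sphere(n_sphere_points)

    per_atom = np.zeros(n)
    for i in targets:
        pts = xyz[i] + radii[i] * unit
        # neighbours whose expanded spheres can reach atom i's surface
        d = np.linalg.norm(xyz - xyz[i], axis=1)
        nb = np.flatnonzero((d < radii + radii[i]) & (np.arange(n) != i))
        if nb.size:
            d2 = np.min(
                np.sum((pts[:, None, :] - xyz[nb][None, :, :]) ** 2, axis=2)
                - radii[nb][None, :] ** 2, axis=1)
            acc = np.count_nonzero(d2 > 0.0)
        else:
            acc = n_sphere_points
        per_atom[i] = acc / n_sphere_points * 4.0 * np.pi * radii[i] ** 2

    el = np.array(elements)
    in_target = np.zeros(n, bool)
    in_target[targets] = True
    phobic = float(per_atom[in_target
                            & np.isin(el, list(HYDROPHOBIC_ELEMENTS))].sum())
    philic = float(per_atom[in_target
                            & ~np.isin(el, list(HYDROPHOBIC_ELEMENTS))].sum())
    return SasaResult(per_atom=per_atom, hydrophobic=phobic,
                      hydrophilic=philic)
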