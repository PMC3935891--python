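"""In-memory container for multi-frame structures with force-field metadata.

A :class:`FrameEnsemble` couples a constant per-atom table (identity,
partial charge, Lennard-Jones parameters, hydrogen-bond donor/acceptor
flags) with per-frame coordinates in nm.  It is the common currency of the
interface-statistics operations: hydrogen bonds, interaction energies, SASA,
entropies, rotations and occupancy densities all consume it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import ATOMIC_MASSES

__all__ = ["FrameEnsemble"]

#: columns every atom table must carry
ATOM_COLUMNS = ["name", "element", "resid", "resname", "chain",
                "charge", "sigma", "epsilon", "donor", "acceptor"]


@dataclass
class FrameEnsemble:
    """Per-atom metadata plus per-frame coordinates.

    atoms : DataFrame indexed 0..n_atoms-1 with columns
        name, element, resid, resname, chain, charge (e), sigma (nm),
        epsilon (kJ/mol), donor (bool), acceptor (bool) and optionally mass
        (amu; filled from the element table when absent).
    coords : (n_frames, n_atoms, 3) array, nm.
    times : (n_frames,) array, ps.
    bonded_hydrogens : donor atom index -> indices of its bonded hydrogens.
    meta : free-form provenance (seeds, generator ground truth, ...).
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    times: np.ndarray | None = None
    bonded_hydrogens: dict[int, list[int]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("coords atom count does not match atom table")
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atom table lacks columns: {missing}")
        if self.times is None:
            self.times = np.arange(self.coords.shape[0], dtype=float)
        if "mass" not in self.atoms.columns:
            self.atoms = self.atoms.assign(
                mass=[ATOMIC_MASSES.get(str(e).upper(), 12.0)
                      for e in self.atoms["element"]])
        if not np.all(np.isfinite(self.atoms["charge"].to_numpy(float))):
            raise ValueError("non-finite partial charges")
        for d, hs in self.bonded_hydrogens.items():
            if self.atoms.at[d, "donor"] and not hs:
                raise ValueError(f"donor atom {d} has no bonded hydrogen")

    # -- basic queries -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def indices(self, chain: str | None = None, resid=None,
                resname: str | None = None, name: str | None = None,
                element: str | None = None) -> np.ndarray:
        """Atom indices matching the given identity filters (AND-combined)."""
        mask = np.ones(self.n_atoms, dtype=bool)
        a = self.atoms
        if chain is not None:
            mask &= (a["chain"] == chain).to_numpy()
        if resid is not None:
            resid = np.atleast_1d(resid)
            mask &= a["resid"].isin(resid).to_numpy()
        if resname is not None:
            mask &= (a["resname"] == resname).to_numpy()
        if name is not None:
            mask &= (a["name"] == name).to_numpy()
        if element is not None:
            mask &= (a["element"].str.upper() == element.upper()).to_numpy()
        return np.flatnonzero(mask)

    def donors(self, subset: np.ndarray | None = None) -> np.ndarray:
        idx = np.flatnonzero(self.atoms["donor"].to_numpy(bool))
        if subset is not None:
            idx = np.intersect1d(idx, subset)
        return idx

    def acceptors(self, subset: np.ndarray | None = None) -> np.ndarray:
        idx = np.flatnonzero(self.atoms["acceptor"].to_numpy(bool))
        if subset is not None:
            idx = np.intersect1d(idx, subset)
        return idx

    def masses(self, idx: np.ndarray | None = None) -> np.ndarray:
        m = self.atoms["mass"].to_numpy(float)
        return m if idx is None else m[idx]
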