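"""Non-bonded interaction energies between atom groups.

Sum over cross pairs within a cutoff of the Coulomb term
k_e q_i q_j / r_ij (k_e = 138.935458 kJ mol^-1 nm e^-2) plus the
Lennard-Jones term 4 eps [(sigma/r)^12 - (sigma/r)^6] with
Lorentz-Berthelot combination rules.  Plain truncation, no Ewald: intended
for the toy systems and for per-residue decomposition of pre-extracted
interface frames.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import COULOMB_K
from .ensemble import FrameEnsemble

__all__ = ["interaction_energy", "per_residue_interaction_energy"]


def interaction_energy(
    ensemble: FrameEnsemble,
    frame: int,
    group: np.ndarray,
    environment: np.ndarray,
    cutoff: float = 1.0,
    split: bool = False,
):
    """Group-environment interaction energy in one frame, kJ/mol.

    Parameters
    ----------
    group, environment : disjoint atom index arrays (overlap raises).
    cutoff : pair distance truncation, nm.
    split : return ``(coulomb, lennard_jones)`` instead of their sum.
    """
    group = np.asarray(group, dtype=int)
    environment = np.asarray(environment, dtype=int)
    if np.intersect1d(group, environment).size:
        raise ValueError("group and environment overlap")
    a = ensemble.atoms
    for idx in (group, environment):
        bad = [int(i) for i in idx
               if not np.isfinite(a.at[i, "charge"])
               or not np.isfinite(a.at[i, "sigma"])
               or not np.isfinite(a.at[i, "epsilon"])]
        if bad:
            names = ", ".join(f"{a.at[i, 'name']}({i})" for i in bad[:5])
            raise ValueError(f"missing charge/LJ parameters for atoms: {names}")

    xyz = ensemble.coords[frame]
    d = np.linalg.norm(xyz[group][:, None, :] - xyz[environment][None, :, :],
                       axis=2)
    within = (d <= cutoff) & (d > 0)
    if not within.any():
        return (0.0, 0.0) if split else 0.0

    qi = a["charge"].to_numpy(float)[group][:, None]
    qj = a["charge"].to_numpy(float)[environment][None, :]
    si = a["sigma"].to_numpy(float)[group][:, None]
    sj = a["sigma"].to_numpy(float)[environment][None, :]
    ei = a["epsilon"].to_numpy(float)[group][:, None]
    ej = a["epsilon"].to_numpy(float)[environment][None, :]

    with np.errstate(divide="ignore", invalid="ignore"):
        coul = np.where(within, COULOMB_K * qi * qj / d, 0.0)
        sig = 0.5 * (si + sj)            # Lorentz
        eps = np.sqrt(ei * ej)           # Berthelot
        sr6 = np.where(within, (sig / np.where(d > 0, d, 1.0)) ** 6, 0.0)
        lj = 4.0 * eps * (sr6**2 - sr6)
        lj = np.where(within, lj, 0.0)
    if split:
        return float(coul.sum()), float(lj.sum())
    return float(coul.sum() + lj.sum())


def per_residue_interaction_energy(
    ensemble: FrameEnsemble,
    frame: int,
    group_chain: str,
    environment_chain: str,
    cutoff: float = 1.0,
) -> pd.DataFrame:
    """Interaction energy of each residue of ``group_chain`` with the whole
    ``environment_chain``, one row per residue."""
    env = ensemble.indices(chain=environment_chain)
    a = ensemble.atoms
    rows = []
    gidx = ensemble.indices(chain=group_chain)
    for resid in sorted(set(int(r) for r in a["resid"].to_numpy()[gidx])):
        ridx = ensemble.indices(chain=group_chain, resid=resid)
        coul, lj = interaction_energy(ensemble, frame, ridx, env,
                                      cutoff=cutoff, split=True)
        rows.append(dict(resid=resid,
                         resname=a.at[int(ridx[0]), "resname"],
                         coulomb_kj=coul, lj_kj=lj, total_kj=coul + lj))
    return pd.DataFrame(rows)
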