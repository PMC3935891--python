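"""Quasi-harmonic conformational entropy from coordinate fluctuations.

After rigid-body superposition onto a reference, the mass-weighted
covariance of the selected coordinates is diagonalized; each eigenvalue
lambda_i (amu nm^2) defines an effective harmonic mode of frequency
omega_i = sqrt(kT / lambda_i) (1/ps, using 1 amu nm^2 ps^-2 = 1 kJ/mol),
and the entropy is the quantum harmonic-oscillator sum

    S_i = k_B [ x/(e^x - 1) - ln(1 - e^-x) ],   x = hbar omega_i / kT,

which is bounded and non-negative mode by mode.  The classical oscillator
form k_B [1 - ln x] is available as an option.  Per-residue entropies come
from that residue's own block covariance, normalized per atom, which is the
natural way to compare the flexibility of individual residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import KB, HBAR, DEFAULT_T
from .ensemble import FrameEnsemble
from .rotations import best_fit_rotation

__all__ = ["EntropySpectrum", "quasiharmonic_entropy", "oscillator_entropy",
           "superpose_frames"]

#: gas constant in J K^-1 mol^-1 for reporting (KB is kJ)
_KB_J = KB * 1000.0


@dataclass
class EntropySpectrum:
    """Eigenvalues, mode frequencies and per-mode entropies of a selection.

    eigenvalues : mass-weighted covariance eigenvalues, amu nm^2.
    frequencies : omega_i = sqrt(kT/lambda_i), ps^-1.
    mode_entropy : per-mode S_i, J K^-1 mol^-1.
    n_dropped : near-singular modes removed.
    """

    eigenvalues: np.ndarray
    frequencies: np.ndarray
    mode_entropy: np.ndarray

    n_dropped: int = 0

    @property
    def total(self) -> float:
        """Total entropy of the selection, J K^-1 mol^-1."""
        return float(self.mode_entropy.sum())


def oscillator_entropy(x: np.ndarray, classical: bool = False) -> np.ndarray:
    """Harmonic-oscillator entropy (units of k_B) at x = hbar*omega/kT."""
    x = np.asarray(x, dtype=float)
    if classical:
        with np.errstate(divide="ignore"):
            return np.where(x > 0, 1.0 - np.log(x), np.inf)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        s = x / np.expm1(x) - np.log1p(-np.exp(-x))
    return np.where(np.isfinite(s), s, 0.0)  # x -> inf limit is 0


def superpose_frames(coords: np.ndarray, masses: np.ndarray,
                     reference: np.ndarray | None = None) -> np.ndarray:
    """Remove rigid-body motion: fit every frame onto the reference
    (default: frame 0) by mass-weighted rotation + translation."""
    ref = coords[0] if reference is None else reference
    w = masses / masses.sum()
    ref_c = ref - np.average(ref, axis=0, weights=w)
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        x = coords[f]
        xc = x - np.average(x, axis=0, weights=w)
        R = best_fit_rotation(xc, ref_c, masses)
        out[f] = xc @ R
    return out


def _spectrum(coords: np.ndarray, masses: np.ndarray, kT: float,
              lambda_floor: float = 1e-12) -> EntropySpectrum:
    n_frames, n_atoms, _ = coords.shape
    sqm = np.sqrt(np.repeat(masses, 3))
    flat = coords.reshape(n_frames, 3 * n_atoms)
    dev = (flat - flat.mean(axis=0)) * sqm
    cov = dev.T @ dev / n_frames
    lam = np.linalg.eigvalsh(cov)
    lam = lam[::-1]
    keep = lam > lambda_floor
    dropped = int((~keep).sum())
    lam = lam[keep]
    if lam.size == 0:
        return EntropySpectrum(eigenvalues=np.empty(0),
                               frequencies=np.empty(0),
                               mode_entropy=np.empty(0), n_dropped=dropped)
    omega = np.sqrt(kT / lam)
    x = HBAR * omega / kT
    s = oscillator_entropy(x) * _KB_J
    return EntropySpectrum(eigenvalues=lam, frequencies=omega,
                           mode_entropy=s, n_dropped=dropped)


def quasiharmonic_entropy(
    ensemble: FrameEnsemble,
    selection: np.ndarray | None = None,
    T: float = DEFAULT_T,
    fit: bool = True,
    classical: bool = False,
    per_residue: bool = True,
) -> tuple[EntropySpectrum, pd.DataFrame | None]:
    """Quasi-harmonic entropy of a selection, plus a per-residue table.

    Frames are superposed on the selection (mass-weighted rigid fit to frame
    0) before the covariance, which removes the six rigid-body modes.  The
    per-residue table reports S per atom (J K^-1 mol^-1 per atom) from each
    residue's own block covariance, with and without hydrogens in the atom
    normalization.
    """
    sel = (np.arange(ensemble.n_atoms) if selection is None
           else np.sort(np.asarray(selection, int)))
    if sel.size == 0:
        raise ValueError("empty selection")
    coords = ensemble.coords[:, sel, :]
    masses = ensemble.masses(sel)
    kT = KB * T
    if ensemble.n_frames < 3 * sel.size:
        warnings.warn(
            f"{ensemble.n_frames} frames for {sel.size} atoms: fewer than "
            "3N frames makes the covariance rank-deficient", stacklevel=2)
    if fit:
        coords = superpose_frames(coords, masses)
    if classical:
        spec = _spectrum(coords, masses, kT)
        x = HBAR * spec.frequencies / kT
        spec = EntropySpectrum(
            eigenvalues=spec.eigenvalues, frequencies=spec.frequencies,
            mode_entropy=oscillator_entropy(x, classical=True) * _KB_J,
            n_dropped=spec.n_dropped)
    else:
        spec = _spectrum(coords, masses, kT)

    table = None
    if per_residue:
        a = ensemble.atoms
        rows = []
        key = a[["chain", "resid"]].astype(str).agg("|".join, axis=1)
        for res in pd.unique(key.iloc[sel]):
            ridx = sel[np.asarray(key.iloc[sel] == res)]
            rspec = _spectrum(coords[:, np.searchsorted(sel, ridx), :],
                              ensemble.masses(ridx), kT)
            if classical:
                x = HBAR * rspec.frequencies / kT
                s_tot = float((oscillator_entropy(x, classical=True)
                               * _KB_J).sum())
            else:
                s_tot = rspec.total
            el = a["element"].iloc[ridx].str.upper()
            n_all = len(ridx)
            n_heavy = int((el != "H").sum())
            chain, resid = res.split("|")
            rows.append(dict(chain=chain, resid=int(resid),
                             resname=a["resname"].iloc[ridx[0]],
                             S_total_J_per_K=s_tot,
                             S_per_atom=s_tot / n_all,
                             S_per_heavy_atom=(s_tot / n_heavy
                                               if n_heavy else np.nan)))
        table = pd.DataFrame(rows)
    return spec, table
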