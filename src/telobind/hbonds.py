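"""Hydrogen-bond and water-bridge detection with occupancy/lifetime tables.

Geometric criterion (explicit, overridable): donor-acceptor distance
<= 0.35 nm and D-H-A angle >= 150 degrees for at least one hydrogen bonded
to the donor — the common convention in MD analysis.  A water bridge is one
water molecule simultaneously hydrogen-bonded (either role) to a protein
residue and to a DNA base within the same frame.  Lifetimes use the strict
continuous-run definition: the mean length of maximal consecutive-on runs,
with no grace frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import FrameEnsemble

__all__ = ["HBondCriteria", "detect_hbonds", "detect_water_bridges",
           "hbond_statistics", "base_contact_probability"]


@dataclass(frozen=True)
class HBondCriteria:
    """d_max: donor-acceptor cutoff (nm); angle_min: D-H-A cutoff (deg)."""

    d_max: float = 0.35
    angle_min: float = 150.0

    def __post_init__(self):
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not 0 < self.angle_min <= 180:
            raise ValueError("angle_min must lie in (0, 180]")


def _angles_deg(d_pos, h_pos, a_pos):
    """D-H-A angles in degrees for stacked position triplets."""
    v1 = d_pos - h_pos
    v2 = a_pos - h_pos
    cos = np.einsum("ij,ij->i", v1, v2) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1) + 1e-300)
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def detect_hbonds(
    ensemble: FrameEnsemble,
    frame: int,
    criteria: HBondCriteria = HBondCriteria(),
    donor_subset: np.ndarray | None = None,
    acceptor_subset: np.ndarray | None = None,
) -> set[tuple[int, int]]:
    """Hydrogen bonds in one frame as a set of (donor_atom, acceptor_atom).

    A pair is bonded iff dist(D, A) <= d_max and angle(D-H-A) >= angle_min
    for at least one hydrogen bonded to the donor.  Donor-acceptor role
    pairs are directional, so a doubly-capable pair (e.g. two waters) is
    never double-counted as the same undirected bond.
    """
    xyz = ensemble.coords[frame]
    donors = ensemble.donors(donor_subset)
    acceptors = ensemble.acceptors(acceptor_subset)
    for d in donors:
        if not ensemble.bonded_hydrogens.get(int(d)):
            raise ValueError(f"donor atom {d} has no annotated hydrogens")
    out: set[tuple[int, int]] = set()
    if donors.size == 0 or acceptors.size == 0:
        return out
    d_pos = xyz[donors]
    a_pos = xyz[acceptors]
    dist = np.linalg.norm(d_pos[:, None, :] - a_pos[None, :, :], axis=2)
    close = np.argwhere(dist <= criteria.d_max)
    resid = ensemble.atoms["resid"].to_numpy()
    chain = ensemble.atoms["chain"].to_numpy()
    for di, ai in close:
        d, a = int(donors[di]), int(acceptors[ai])
        if d == a:
            continue
        # never bond within one residue (covalent neighbourhood)
        if resid[d] == resid[a] and chain[d] == chain[a]:
            continue
        hs = ensemble.bonded_hydrogens[d]
        ang = _angles_deg(np.tile(xyz[d], (len(hs), 1)), xyz[hs],
                          np.tile(xyz[a], (len(hs), 1)))
        if np.any(ang >= criteria.angle_min):
            out.add((d, a))
    return out


def _residue_key(ensemble, atom):
    a = ensemble.atoms
    return (a.at[atom, "chain"], int(a.at[atom, "resid"]),
            a.at[atom, "resname"])


def detect_water_bridges(
    ensemble: FrameEnsemble,
    frame: int,
    criteria: HBondCriteria = HBondCriteria(),
    protein_chain: str = "A",
    dna_chain: str = "B",
    water_resname: str = "HOH",
) -> set[tuple]:
    """Water bridges in one frame: {(protein_residue, dna_residue, water)}.

    A bridge exists when one water is hydrogen-bonded (as donor or acceptor)
    to a protein residue and, simultaneously, to a DNA residue.
    """
    water_idx = ensemble.indices(resname=water_resname)
    prot_idx = ensemble.indices(chain=protein_chain)
    dna_idx = ensemble.indices(chain=dna_chain)
    bonds = (detect_hbonds(ensemble, frame, criteria,
                           donor_subset=water_idx, acceptor_subset=None)
             | detect_hbonds(ensemble, frame, criteria,
                             donor_subset=None, acceptor_subset=water_idx))
    prot_set, dna_set, wat_set = set(prot_idx), set(dna_idx), set(water_idx)
    partners: dict[int, dict[str, set]] = {}
    for d, a in bonds:
        for w, other in ((d, a), (a, d)):
            if w in wat_set:
                wresid = int(ensemble.atoms.at[w, "resid"])
                rec = partners.setdefault(wresid, {"p": set(), "d": set()})
                if other in prot_set:
                    rec["p"].add(_residue_key(ensemble, other))
                elif other in dna_set:
                    rec["d"].add(_residue_key(ensemble, other))
    bridges = set()
    for wresid, rec in partners.items():
        for pr in rec["p"]:
            for dr in rec["d"]:
                bridges.add((pr, dr, ("W", wresid, water_resname)))
    return bridges


def _run_lengths(on: np.ndarray) -> list[int]:
    runs, count = [], 0
    for v in on:
        if v:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    return runs


def hbond_statistics(
    ensemble: FrameEnsemble,
    criteria: HBondCriteria = HBondCriteria(),
    protein_chain: str = "A",
    dna_chain: str = "B",
    water_resname: str = "HOH",
    report_threshold: float = 0.05,
    include_bridges: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Occupancy and mean lifetime for every protein-DNA contact pair.

    Returns ``(report, full)``: the report keeps pairs with occupancy >=
    ``report_threshold`` (the conventional 5% cut for contact tables); the
    full table keeps everything.  Lifetime is the mean maximal consecutive-on
    run length, converted to time units via the frame spacing.
    """
    if ensemble.n_frames < 2:
        raise ValueError("need >= 2 frames for statistics")
    prot_idx = ensemble.indices(chain=protein_chain)
    dna_idx = ensemble.indices(chain=dna_chain)
    dt = float(np.mean(np.diff(ensemble.times))) if ensemble.n_frames > 1 else 1.0

    series: dict[tuple, np.ndarray] = {}
    for f in range(ensemble.n_frames):
        pairs = set()
        for d, a in detect_hbonds(ensemble, f, criteria,
                                  donor_subset=prot_idx,
                                  acceptor_subset=dna_idx):
            pairs.add((_residue_key(ensemble, d), _residue_key(ensemble, a),
                       "direct"))
        for d, a in detect_hbonds(ensemble, f, criteria,
                                  donor_subset=dna_idx,
                                  acceptor_subset=prot_idx):
            pairs.add((_residue_key(ensemble, a), _residue_key(ensemble, d),
                       "direct"))
        if include_bridges:
            for pr, dr, _w in detect_water_bridges(
                    ensemble, f, criteria, protein_chain, dna_chain,
                    water_resname):
                pairs.add((pr, dr, "water-mediated"))
        for key in pairs:
            series.setdefault(key, np.zeros(ensemble.n_frames, bool))[f] = True

    rows = []
    for (pres, dres, kind), on in sorted(series.items()):
        occ = on.mean()
        runs = _run_lengths(on)
        life = float(np.mean(runs)) * dt if runs else 0.0
        rows.append(dict(protein_residue=f"{pres[2]}{pres[1]}:{pres[0]}",
                         dna_residue=f"{dres[2]}{dres[1]}:{dres[0]}",
                         type=kind, occupancy=float(occ),
                         mean_lifetime=life))
    full = pd.DataFrame(rows, columns=["protein_residue", "dna_residue",
                                       "type", "occupancy", "mean_lifetime"])
    report = full[full["occupancy"] >= report_threshold].reset_index(drop=True)
    return report, full


def base_contact_probability(
    ensemble: FrameEnsemble,
    criteria: HBondCriteria = HBondCriteria(),
    protein_chain: str = "A",
    dna_chain: str = "B",
    water_resname: str = "HOH",
) -> pd.DataFrame:
    """Per-base probability of >= 1 direct or water-mediated bond (union).

    The probability that a base is involved, at any given time, in at least
    one hydrogen bond to the protein — a union over that base's contacts,
    never a sum.
    """
    prot_idx = ensemble.indices(chain=protein_chain)
    dna_idx = ensemble.indices(chain=dna_chain)
    bases = sorted({_residue_key(ensemble, int(i)) for i in dna_idx},
                   key=lambda k: k[1])
    hit = {b: np.zeros(ensemble.n_frames, bool) for b in bases}
    for f in range(ensemble.n_frames):
        touched = set()
        for d, a in detect_hbonds(ensemble, f, criteria,
                                  donor_subset=prot_idx,
                                  acceptor_subset=dna_idx):
            touched.add(_residue_key(ensemble, a))
        for d, a in detect_hbonds(ensemble, f, criteria,
                                  donor_subset=dna_idx,
                                  acceptor_subset=prot_idx):
            touched.add(_residue_key(ensemble, d))
        for _pr, dr, _w in detect_water_bridges(ensemble, f, criteria,
                                                protein_chain, dna_chain,
                                                water_resname):
            touched.add(dr)
        for b in touched:
            if b in hit:
                hit[b][f] = True
    return pd.DataFrame(
        [dict(base=f"{b[2]}{b[1]}:{b[0]}", probability=float(hit[b].mean()))
         for b in bases])
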