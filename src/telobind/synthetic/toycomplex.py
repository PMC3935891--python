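"""Toy protein/DNA/water complexes with scripted contact dynamics.

Each requested donor-acceptor contact follows an independent two-state
telegraph (Markov) chain: per frame, an "on" contact switches off with
probability ``k_off`` and an "off" contact switches on with probability
``k_on = k_off * p_on / (1 - p_on)``, so the stationary on-fraction is
exactly ``p_on``.  When a contact is on, the geometry satisfies standard
hydrogen-bond criteria by a wide margin (donor-acceptor 0.28 nm, colinear
D-H-A); when off, the donor sits at 0.60 nm.  Water bridges place a single
water that simultaneously donates to a protein acceptor and to a DNA-base
acceptor.  The per-frame ground-truth on/off ledger is kept in
``ensemble.meta["contact_states"]`` so detectors can be checked frame by
frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..ensemble import FrameEnsemble

__all__ = ["ContactSpec", "ToyComplexSpec", "make_toy_complex"]

_ON_DIST = 0.28   # nm, donor-acceptor when formed
_OFF_DIST = 0.60  # nm, donor-acceptor when broken
_DH_BOND = 0.10   # nm, donor-hydrogen bond length
_SLOT = 3.0       # nm, spacing between base slots
_MIN_ANGLE = np.pi / 3  # minimum angular separation of contacts on one base

# element -> (partial charge e, LJ sigma nm, LJ epsilon kJ/mol)
_DEFAULT_FF = {
    "N": (-0.40, 0.325, 0.71),
    "H": (0.31, 0.107, 0.066),
    "O": (-0.55, 0.296, 0.88),
    "C": (0.20, 0.340, 0.36),
    "P": (1.10, 0.374, 0.84),
}


@dataclass(frozen=True)
class ContactSpec:
    """One scripted contact.

    protein_res / dna_base : 0-based indices into the toy layout.
    p_on : stationary occupancy target in [0, 1].
    k_off : per-frame on->off switching probability in (0, 1].
    kind : "direct" (protein N-H donates to base N7) or "bridge" (a water
        simultaneously donates to the protein carbonyl O and to base N7).
    """

    protein_res: int
    dna_base: int
    p_on: float
    k_off: float = 0.1
    kind: str = "direct"

    def __post_init__(self):
        if not 0.0 <= self.p_on <= 1.0:
            raise ValueError("p_on must lie in [0, 1]")
        if not 0.0 < self.k_off <= 1.0:
            raise ValueError("k_off must lie in (0, 1]")
        if self.kind not in ("direct", "bridge"):
            raise ValueError(f"unknown contact kind {self.kind!r}")
        if 0.0 < self.p_on < 1.0 and self.k_on > 1.0:
            raise ValueError(
                "k_on = k_off*p_on/(1-p_on) exceeds 1; lower k_off")

    @property
    def k_on(self) -> float:
        """off->on rate consistent with the stationary occupancy."""
        if self.p_on >= 1.0:
            return 1.0
        return self.k_off * self.p_on / (1.0 - self.p_on)


@dataclass(frozen=True)
class ToyComplexSpec:
    n_frames: int = 1000
    n_protein_residues: int = 4
    n_dna_bases: int = 4
    n_waters: int = 4
    contacts: tuple[ContactSpec, ...] = ()
    forcefield: dict = field(default_factory=lambda: dict(_DEFAULT_FF))
    frame_dt: float = 1.0  # ps

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        used_res, used_wat = set(), 0
        for c in self.contacts:
            if c.protein_res >= self.n_protein_residues:
                raise ValueError("contact references a missing protein residue")
            if c.dna_base >= self.n_dna_bases:
                raise ValueError("contact references a missing DNA base")
            if c.protein_res in used_res:
                raise ValueError("each protein residue may appear in one contact")
            used_res.add(c.protein_res)
            if c.kind == "bridge":
                used_wat += 1
        if used_wat > self.n_waters:
            raise ValueError("not enough waters for the requested bridges")


def _telegraph(n: int, p_on: float, k_off: float, k_on: float,
               rng: np.random.Generator) -> np.ndarray:
    """Boolean state series of a two-state Markov chain at stationarity."""
    if p_on <= 0.0:
        return np.zeros(n, dtype=bool)
    if p_on >= 1.0:
        return np.ones(n, dtype=bool)
    s = np.empty(n, dtype=bool)
    s[0] = rng.random() < p_on
    u = rng.random(n - 1)
    for t in range(1, n):
        s[t] = (u[t - 1] >= k_off) if s[t - 1] else (u[t - 1] < k_on)
    return s


class _Builder:
    """Accumulates atoms; returns positions by index."""

    def __init__(self, ff):
        self.rows, self.xyz0, self.ff = [], [], ff
        self.bonded_h: dict[int, list[int]] = {}

    def add(self, name, element, resid, resname, chain, pos,
            donor=False, acceptor=False) -> int:
        q, sig, eps = self.ff.get(element, (0.0, 0.3, 0.2))
        self.rows.append(dict(name=name, element=element, resid=resid,
                              resname=resname, chain=chain, charge=q,
                              sigma=sig, epsilon=eps, donor=donor,
                              acceptor=acceptor))
        self.xyz0.append(np.asarray(pos, dtype=float))
        return len(self.rows) - 1


def make_toy_complex(spec: ToyComplexSpec, seed: int = 0) -> FrameEnsemble:
    """Build a multi-frame toy complex realizing ``spec``.

    Layout: DNA base j occupies a slot at (0, 3j, 0) nm with its acceptor
    N7 at the slot origin; contacting groups approach the acceptor along
    per-contact directions in the xz-plane, at least 60 degrees apart
    (more than ~6 contacts on one base is geometrically infeasible and
    raises).  Unused residues and waters are parked far from every slot.
    """
    rng = np.random.default_rng(seed)
    b = _Builder(spec.forcefield)

    # angular slots per base
    per_base: dict[int, list[ContactSpec]] = {}
    for c in spec.contacts:
        per_base.setdefault(c.dna_base, []).append(c)
    for j, cs in per_base.items():
        if len(cs) * _MIN_ANGLE > 2 * np.pi + 1e-9:
            raise ValueError(
                f"base {j}: {len(cs)} contacts cannot be placed >=60 deg apart")

    # --- DNA bases (chain B) ------------------------------------------
    base_acceptor = {}
    for j in range(spec.n_dna_bases):
        org = np.array([0.0, _SLOT * j, 0.0])
        base_acceptor[j] = b.add("N7", "N", j + 1, "DG", "B", org,
                                 acceptor=True)
        b.add("C8", "C", j + 1, "DG", "B", org + [0.0, 0.13, 0.0])
        b.add("P", "P", j + 1, "DG", "B", org + [0.0, -0.15, 0.0])

    # --- protein residues (chain A) -----------------------------------
    # per-contact moving atoms: (atom indices, on-positions, off-positions)
    movers: list[tuple[list[int], np.ndarray, np.ndarray]] = []
    states: dict[tuple, np.ndarray] = {}
    contact_atoms: dict[tuple, tuple[int, int]] = {}

    res_of_contact = {c.protein_res: c for c in spec.contacts}
    angle_cursor: dict[int, int] = {}
    water_cursor = 0
    park = np.array([30.0, 0.0, 0.0])

    def _direction(base_j):
        k = angle_cursor.get(base_j, 0)
        angle_cursor[base_j] = k + 1
        phi = k * _MIN_ANGLE
        return np.array([np.cos(phi), 0.0, np.sin(phi)])

    for i in range(spec.n_protein_residues):
        resid, resname, chain = i + 1, "PRS", "A"
        c = res_of_contact.get(i)
        if c is None:
            org = park + [0.0, 2.0 * i, 0.0]
            n = b.add("N", "N", resid, resname, chain, org, donor=True)
            h = b.add("HN", "H", resid, resname, chain, org + [_DH_BOND, 0, 0])
            b.add("CA", "C", resid, resname, chain, org + [0.25, 0, 0])
            b.add("O", "O", resid, resname, chain, org + [0.4, 0, 0],
                  acceptor=True)
            b.bonded_h[n] = [h]
            continue

        u = _direction(c.dna_base)
        a_pos = b.xyz0[base_acceptor[c.dna_base]]
        key = (c.protein_res, c.dna_base, c.kind)
        states[key] = _telegraph(spec.n_frames, c.p_on, c.k_off, c.k_on, rng)

        if c.kind == "direct":
            # donor N at a + d*u, H colinear between them
            on_n, off_n = a_pos + _ON_DIST * u, a_pos + _OFF_DIST * u
            n = b.add("N", "N", resid, resname, chain, off_n, donor=True)
            h = b.add("HN", "H", resid, resname, chain,
                      off_n - _DH_BOND * u)
            ca = b.add("CA", "C", resid, resname, chain, off_n + 0.25 * u)
            o = b.add("O", "O", resid, resname, chain, off_n + 0.40 * u,
                      acceptor=True)
            b.bonded_h[n] = [h]
            on_pos = np.stack([on_n, on_n - _DH_BOND * u,
                               on_n + 0.25 * u, on_n + 0.40 * u])
            off_pos = np.stack([off_n, off_n - _DH_BOND * u,
                                off_n + 0.25 * u, off_n + 0.40 * u])
            movers.append(([n, h, ca, o], on_pos, off_pos))
            contact_atoms[key] = (n, base_acceptor[c.dna_base])
        else:  # water bridge
            # water O at a + d*u donates H2 toward the base acceptor and H1
            # toward the protein carbonyl O (at ~104.5 deg from -u)
            theta = np.deg2rad(104.5)
            v = np.array([np.cos(theta) * u[0] - np.sin(theta) * u[2], 0.0,
                          np.sin(theta) * u[0] + np.cos(theta) * u[2]])
            ow_on = a_pos + _ON_DIST * u
            ow_off = a_pos + (_OFF_DIST + 1.5) * u
            prot_o_on = ow_on + _ON_DIST * v
            prot_o_off = ow_off + _ON_DIST * v

            wid = spec.n_dna_bases + spec.n_protein_residues + water_cursor + 1
            ow = b.add("OW", "O", wid, "HOH", "W", ow_off,
                       donor=True, acceptor=True)
            h1 = b.add("HW1", "H", wid, "HOH", "W", ow_off + _DH_BOND * v)
            h2 = b.add("HW2", "H", wid, "HOH", "W", ow_off - _DH_BOND * u)
            b.bonded_h[ow] = [h1, h2]
            water_cursor += 1

            o = b.add("O", "O", resid, resname, chain, prot_o_off,
                      acceptor=True)
            n = b.add("N", "N", resid, resname, chain,
                      prot_o_off + 0.3 * v, donor=True)
            h = b.add("HN", "H", resid, resname, chain,
                      prot_o_off + 0.4 * v)
            b.bonded_h[n] = [h]

            on_pos = np.stack([ow_on, ow_on + _DH_BOND * v,
                               ow_on - _DH_BOND * u, prot_o_on,
                               prot_o_on + 0.3 * v, prot_o_on + 0.4 * v])
            off_pos = np.stack([ow_off, ow_off + _DH_BOND * v,
                                ow_off - _DH_BOND * u, prot_o_off,
                                prot_o_off + 0.3 * v, prot_o_off + 0.4 * v])
            movers.append(([ow, h1, h2, o, n, h], on_pos, off_pos))
            contact_atoms[key] = (ow, base_acceptor[c.dna_base])

    # --- bulk waters (chain W), parked --------------------------------
    for w in range(spec.n_waters - water_cursor):
        wid = spec.n_dna_bases + spec.n_protein_residues + water_cursor + w + 1
        org = park + [10.0, 2.0 * w, 0.0]
        ow = b.add("OW", "O", wid, "HOH", "W", org, donor=True, acceptor=True)
        h1 = b.add("HW1", "H", wid, "HOH", "W", org + [_DH_BOND, 0, 0])
        h2 = b.add("HW2", "H", wid, "HOH", "W", org + [0, 0, _DH_BOND])
        b.bonded_h[ow] = [h1, h2]

    atoms = pd.DataFrame(b.rows)
    base = np.stack(b.xyz0)
    coords = np.repeat(base[None, :, :], spec.n_frames, axis=0)
    for (key, st), (idx, on_pos, off_pos) in zip(states.items(), movers):
        coords[:, idx, :] = np.where(st[:, None, None], on_pos[None],
                                     off_pos[None])

    return FrameEnsemble(
        atoms=atoms,
        coords=coords,
        times=np.arange(spec.n_frames) * spec.frame_dt,
        bonded_hydrogens=b.bonded_h,
        meta={"contact_states": states, "contact_atoms": contact_atoms,
              "seed": seed, "spec": spec},
    )
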