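"""Readers and writers for the pipeline's on-disk formats.

- umbrella window series: xvg-dialect text ("#"/"@" comments, "time value"
  columns) so GROMACS pull output and synthetic output share one reader,
  with a JSON sidecar {center, force_constant, kT, seed} per window;
- multi-model PDB frames plus a TSV sidecar carrying charges, LJ parameters
  and donor/acceptor flags keyed by (chain, resid, atom name);
- TSV tables for PMFs, WHAM constants and statistics;
- OpenDX text grids for occupancy densities.

Units on disk: nm and kJ/mol (kcal/mol only in final report tables).
Every writer stamps a header with the tool version, config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .constants import KB, DEFAULT_T, KJ_PER_KCAL
from .ensemble import FrameEnsemble
from .synthetic.umbrella import UmbrellaWindow
from .wham import PMFProfile, WindowSamples

__all__ = ["write_window_series", "read_window_series", "read_window_dir",
           "write_pmf_tsv", "read_pmf_tsv", "write_frames_pdb",
           "read_frames", "write_dx", "config_hash"]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(seed=None, extra: dict | None = None, comment="#") -> str:
    fields = {"tool": f"telobind {__version__}"}
    if seed is not None:
        fields["seed"] = seed
    if extra:
        fields.update(extra)
    fields["config_hash"] = config_hash(fields)
    return "".join(f"{comment} {k}: {v}\n" for k, v in fields.items())


# --- umbrella window series (xvg dialect) -------------------------------

def write_window_series(path, samples: WindowSamples) -> None:
    """Write one window's series as xvg text plus a JSON sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(seed=samples.seed,
                         extra={"center_nm": samples.window.center,
                                "force_constant": samples.window.force_constant}))
        fh.write('@    title "umbrella window reaction coordinate"\n')
        fh.write('@    xaxis label "time"\n@    yaxis label "r (nm)"\n')
        for t, v in enumerate(samples.values):
            fh.write(f"{t:d}\t{v:.17g}\n")
    sidecar = {"center": samples.window.center,
               "force_constant": samples.window.force_constant,
               "kT": samples.kT, "seed": samples.seed}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))


def read_window_series(path) -> WindowSamples:
    """Parse an xvg-dialect series and its JSON sidecar."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing window metadata sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    values = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#") or s.startswith("@"):
                continue
            parts = s.split()
            try:
                values.append(float(parts[1] if len(parts) > 1 else parts[0]))
            except (ValueError, IndexError) as e:
                raise ValueError(f"{path}:{ln}: malformed data line "
                                 f"{s!r}") from e
    if not values:
        raise ValueError(f"{path}: no data lines (empty series)")
    window = UmbrellaWindow(center=float(meta["center"]),
                            force_constant=float(meta["force_constant"]))
    return WindowSamples(window=window, values=np.array(values),
                         kT=float(meta.get("kT", KB * DEFAULT_T)),
                         seed=meta.get("seed"))


def read_window_dir(directory) -> list[WindowSamples]:
    """All window series (``*.xvg``) in a directory, sorted by bias center."""
    files = sorted(Path(directory).glob("*.xvg"))
    if not files:
        raise FileNotFoundError(f"no .xvg window files in {directory}")
    samples = [read_window_series(f) for f in files]
    return sorted(samples, key=lambda s: s.window.center)


# --- PMF tables ----------------------------------------------------------

def write_pmf_tsv(path, pmf: PMFProfile, seed=None) -> None:
    """PMF as TSV (r_nm, G_kJ_mol, G_kcal_mol, err_kJ_mol) plus an F_i
    table alongside (``<stem>_F.tsv``)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(seed=seed, extra={"kT_kJ_mol": pmf.kT}))
        fh.write("r_nm\tG_kJ_mol\tG_kcal_mol\terr_kJ_mol\n")
        for r, g, e in zip(pmf.bin_centers, pmf.G, pmf.err):
            fh.write(f"{r:.6g}\t{g:.8g}\t{g / KJ_PER_KCAL:.8g}\t{e:.6g}\n")
    fpath = path.with_name(path.stem + "_F.tsv")
    with open(fpath, "w") as fh:
        fh.write(_header(seed=seed))
        fh.write("window\tF_kJ_mol\n")
        for i, f in enumerate(pmf.F):
            fh.write(f"{i}\t{f:.8g}\n")


def read_pmf_tsv(path) -> PMFProfile:
    df = pd.read_csv(path, sep="\t", comment="#")
    kT = KB * DEFAULT_T
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "kT_kJ_mol" in line:
                kT = float(line.rsplit(":", 1)[1])
            if not line.startswith("#"):
                break
    f_file = Path(path).with_name(Path(path).stem + "_F.tsv")
    F = (pd.read_csv(f_file, sep="\t", comment="#")["F_kJ_mol"].to_numpy()
         if f_file.exists() else np.zeros(0))
    return PMFProfile(bin_centers=df["r_nm"].to_numpy(),
                      G=df["G_kJ_mol"].to_numpy(),
                      err=df["err_kJ_mol"].to_numpy(), kT=kT, F=F)


# --- multi-model PDB + sidecar ------------------------------------------

SIDECAR_COLUMNS = ["chain", "resid", "name", "charge", "sigma", "epsilon",
                   "donor", "acceptor"]


def write_frames_pdb(path, ensemble: FrameEnsemble, sidecar_path=None) -> None:
    """Write frames as a multi-model PDB (coordinates nm -> Angstrom) and
    the force-field metadata as a TSV sidecar."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_frames, n_atoms = ensemble.n_frames, ensemble.n_atoms
    arr = struc.AtomArrayStack(n_frames, n_atoms)
    arr.coord = ensemble.coords * 10.0  # nm -> A
    a = ensemble.atoms
    arr.chain_id = a["chain"].to_numpy(str)
    arr.res_id = a["resid"].to_numpy(int)
    arr.res_name = a["resname"].to_numpy(str)
    arr.atom_name = a["name"].to_numpy(str)
    arr.element = a["element"].str.upper().to_numpy(str)
    arr.hetero = np.array([rn == "HOH" for rn in a["resname"]])
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))

    if sidecar_path is None:
        sidecar_path = Path(path).with_suffix(".ff.tsv")
    side = a[["chain", "resid", "name", "charge", "sigma", "epsilon",
              "donor", "acceptor"]].copy()
    # bonded hydrogens serialized as a per-donor comma list of atom names
    hnames = []
    for i in range(n_atoms):
        hs = ensemble.bonded_hydrogens.get(i, [])
        hnames.append(",".join(a.at[h, "name"] for h in hs))
    side["bonded_h"] = hnames
    side.to_csv(sidecar_path, sep="\t", index=False)


def read_frames(path, sidecar_path=None) -> FrameEnsemble:
    """Multi-model PDB -> FrameEnsemble (Angstrom -> nm), metadata joined
    from the TSV sidecar keyed by (chain, resid, atom name)."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure()  # raises on inconsistent atom counts
    except Exception as e:
        raise ValueError(f"{path}: inconsistent MODEL blocks: {e}") from e
    coords = stack.coord / 10.0
    atoms = pd.DataFrame({
        "name": stack.atom_name, "element": stack.element,
        "resid": stack.res_id.astype(int), "resname": stack.res_name,
        "chain": stack.chain_id,
    })
    if sidecar_path is None:
        sidecar_path = Path(path).with_suffix(".ff.tsv")
    if not Path(sidecar_path).exists():
        raise FileNotFoundError(f"missing force-field sidecar {sidecar_path}")
    side = pd.read_csv(sidecar_path, sep="\t",
                       dtype={"chain": str, "name": str})
    merged = atoms.merge(side, on=["chain", "resid", "name"], how="left",
                         validate="one_to_one")
    missing = merged["charge"].isna()
    if missing.any():
        row = merged[missing].iloc[0]
        raise ValueError("sidecar lacks a row for atom "
                         f"{row['chain']}/{row['resid']}/{row['name']}")
    merged["donor"] = merged["donor"].astype(bool)
    merged["acceptor"] = merged["acceptor"].astype(bool)

    bonded: dict[int, list[int]] = {}
    if "bonded_h" in merged.columns:
        lookup: dict[tuple, int] = {
            (c, r, n): i for i, (c, r, n) in
            enumerate(zip(merged["chain"], merged["resid"], merged["name"]))}
        for i, cell in enumerate(merged["bonded_h"].fillna("")):
            names = [s for s in str(cell).split(",") if s and s != "nan"]
            hs = [lookup[(merged.at[i, "chain"], merged.at[i, "resid"], n)]
                  for n in names if (merged.at[i, "chain"],
                                     merged.at[i, "resid"], n) in lookup]
            if hs:
                bonded[i] = hs
    ens_atoms = merged.drop(columns=[c for c in ("bonded_h",)
                                     if c in merged.columns])
    return FrameEnsemble(atoms=ens_atoms, coords=coords,
                         bonded_hydrogens=bonded)


# --- OpenDX grids --------------------------------------------------------

def write_dx(path, grid, seed=None) -> None:
    """Occupancy grid as OpenDX text (origin/spacing in nm)."""
    v = grid.values
    nx, ny, nz = v.shape
    with open(path, "w") as fh:
        fh.write(_header(seed=seed))
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6g} {:.6g} {:.6g}\n".format(*grid.origin))
        fh.write(f"delta {grid.spacing:.6g} 0 0\n")
        fh.write(f"delta 0 {grid.spacing:.6g} 0\n")
        fh.write(f"delta 0 0 {grid.spacing:.6g}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items "
                 f"{v.size} data follows\n")
        flat = v.ravel()
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{x:.6g}" for x in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
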