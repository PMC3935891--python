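# telobind

Umbrella-sampling free-energy analysis for protein–DNA binding.

`telobind` reconstructs the free-energy profile G(r) of a DNA-binding
protein along the cylindrical reaction coordinate r — the xy-plane
projection of the protein–DNA center-of-mass distance, with the DNA axis on
z — from harmonically biased umbrella windows, and converts it into
standard-state binding free energies resolved by binding mode. It was built
for the analysis of telomeric repeat-binding factors (the shelterin
components TRF1 and TRF2, whose Myb-like DNA-binding domains engage the
5′-TTAGGG-3′ repeat), but nothing in it is specific to that system: any set
of GROMACS-pull-style window files with harmonic biases can be analysed.

The package covers:

- **WHAM** (`telobind.wham`): self-consistent weighted-histogram solution
  of G(r) and the per-window constants F_i, with autocorrelation-aware
  effective sample counts and block-bootstrap uncertainties;
- **standard-state thermodynamics** (`telobind.thermo`):
  ΔG° = −kT ln[d∫₀^{r*}P dr / (h∫_{r*}^{r_max}P dr)], with the unbound
  shell radius r_max fixed by the standard volume V° = 1.661 nm³ and the
  tight/intermediate/loose mode boundaries (r* = 2.0/2.4/3.0 nm), plus
  ΔΔG between systems;
- **reweighting** (`telobind.reweight`): per-frame unbias factors
  exp[(w_i − F_i)/kT], equilibrium observable profiles along r and 2D
  free-energy surfaces over (r, rotation angle);
- **interface statistics** (`telobind.hbonds`, `.energetics`, `.sasa`,
  `.entropy`, `.rotations`, `.density`): direct and water-mediated hydrogen
  bonds with occupancies and lifetimes, Coulomb + Lennard-Jones interaction
  energies, Shrake–Rupley SASA with a hydrophobic/hydrophilic split,
  quasi-harmonic conformational entropies, Kabsch best-fit rotations with
  Euler decomposition, and spatial occupancy grids;
- **synthetic ensembles** (`telobind.synthetic`): Metropolis-adjusted
  Brownian sampling on analytic binding landscapes and toy complexes with
  telegraph contact dynamics — ground-truth-known inputs for every stage.

## Worked example

From nothing to a mode-resolved binding free-energy table, entirely from
synthetic data (16 windows, 1.5–4.5 nm, k = 700 kJ mol⁻¹ nm⁻², 2 × 10⁴
saved samples per window):

```sh
cat > config.json <<'EOF'
{"n_steps": 200000, "stride": 10, "n_walkers": 16, "d_nm": 1.93}
EOF
telobind --seed 7 --config config.json --out windows simulate
telobind --seed 7 --config config.json --out analysis wham windows --n-boot 16
telobind --seed 7 --config config.json --out analysis bindfe analysis/pmf.tsv --system demo
```

prints

```
wrote 16 windows to windows (min adjacent overlap 0.066)
wrote analysis/pmf.tsv (4659 WHAM iterations)
system         mode  r_star_nm  dG0_kcal_mol
  demo        tight        2.0     -2.271120
  demo intermediate        2.4     -6.274030
  demo        loose        3.0     -6.602379
```

The default synthetic landscape is a 25 kJ/mol Gaussian well at
r = 1.8 nm with a flat plateau beyond 3 nm. The tight mode (r* = 2.0 nm)
cuts through the well, so its ΔG° is the least negative; widening the bound
state to the intermediate (2.4 nm) and loose (3.0 nm) boundaries captures
the whole well and ΔG° saturates near −6.6 kcal/mol — the nesting
ΔG°(loose) ≤ ΔG°(intermediate) ≤ ΔG°(tight) holds for any profile with a
flat plateau. `d_nm` is the axial fluctuation range of the bound protein
(estimate it from bound-state z samples with `estimate_d`, which also emits
a sensitivity table over estimator conventions).

The same stages are available as library calls (`make_windows`,
`generate_umbrella_dataset`, `wham_solve`, `bootstrap_pmf_errors`,
`probability_from_pmf`, `mode_table`, `delta_delta_g`, ...); the other
subcommands (`reweight`, `hbonds`, `sasa`, `entropy`, `angles`, `density`,
`report`) wrap the corresponding modules. `docs/methods.md` documents the
model, estimators and numerical choices.

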