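# Methods

`telobind` analyses umbrella-sampling simulations of a protein binding
double-stranded DNA along a cylindrical reaction coordinate: the xy-plane
projection r of the distance between the protein's and the DNA's centers of
mass, with the DNA axis aligned with z. The package covers the full chain
from biased window time series to standard-state binding free energies,
unbiased observable profiles, and interface statistics, and ships a
synthetic-data generator so every estimator can be validated against a
closed form.

Internal units are nm, kJ/mol, ps, amu and elementary charge; with these,
1 amu nm² ps⁻² = 1 kJ/mol exactly. Final binding tables are reported in
kcal/mol. Constants: k_B = 0.0083144621 kJ mol⁻¹ K⁻¹, k_e = 138.935458
kJ mol⁻¹ nm e⁻², ħ = 0.0635077993 kJ ps mol⁻¹, default T = 300 K.

## Synthetic ensembles

The generator emulates the *equilibrium statistics* of umbrella-sampled
protein–DNA dissociation; it does not emulate inertial dynamics, explicit
solvent, or force-field detail.

**Landscape.** The default radial potential is a Gaussian well of depth
25 kJ/mol at r_min = 1.8 nm with width 0.25 nm, clamped to exactly zero
beyond r_plateau = 3.0 nm (the small Gaussian tail value at the plateau
edge, ~2×10⁻⁴ kJ/mol, is subtracted inside the well so the plateau is flat
by construction — the standard-state shell integrals rely on that
flatness). The axial confinement is harmonic with spring 10 kJ mol⁻¹ nm⁻²,
giving bound-state axial fluctuations of about ±1 nm, commensurate with a
~7 nm simulation box. This mimics the scale and shape of a protein–DNA
dissociation profile: a single barrierless funnel into the bound state.

**Sampler.** Positions evolve by overdamped Brownian proposals
(Euler–Maruyama, D_c = 0.1 nm²/ps, Δt = 0.01 ps) with a Metropolis accept
step (MALA). The accept step makes the stationary distribution exactly
Boltzmann at any stable time step; without it, the O(Δt) discretization
bias inflates the biased window variances by ~15 % at k = 700 kJ mol⁻¹ nm⁻²
and leaves a systematic ~0.1 kT floor in the recovered profile that no
amount of sampling removes. A time step too large for the local stiffness
is detected as a collapsed acceptance rate (< 5 % after 500 steps) and
raised as an integration-instability error naming Δt.

The per-window step budget (default 10⁶ steps, stride 10 → 10⁵ saved
samples) is split across 16 independent walkers propagated as one
vectorized batch and stored back to back, so within-walker autocorrelation
is preserved for the inefficiency estimators. Biased windows draw their
walker starting points from the exact biased Boltzmann marginal
p(r) ∝ r·exp(−β[U_r + w])  by inverse-CDF sampling: a displaced umbrella
window on a funnel landscape is bistable (well vs plateau basin) with
hopping times far beyond any affordable burn-in, so equilibrium
initialization — not burn-in — is what guarantees correct basin occupancy.
Unbiased runs start at the well minimum and burn in. A given seed fully
determines the output; window i of a dataset uses seed base+i.

**Toy complexes.** Interface statistics are validated on generated
multi-frame complexes in which each requested protein–DNA contact follows
an independent two-state telegraph (Markov) chain with stationary occupancy
p_on = k_on/(k_on + k_off), started from the stationary distribution. An
"on" contact places the donor–acceptor pair at 0.28 nm with a colinear
D–H–A arrangement; "off" places it at 0.60 nm — both far from the detection
cutoffs, so detection is unambiguous. Water bridges place a single water
donating simultaneously to a protein carbonyl oxygen and a DNA base
acceptor at the tetrahedral water angle. Contacts sharing a base approach
it along directions ≥ 60° apart (more than six contacts per base is
rejected as geometrically infeasible). The per-frame ground-truth on/off
ledger is stored in the ensemble metadata for frame-wise checks.

## WHAM

The profile G(r) is reconstructed by direct self-consistent iteration of
the binned WHAM equations in log space, with the bias evaluated at bin
centers (midpoint rule), gauge F₀ = 0 during iteration and min G = 0 on
output. Defaults: bin width 0.05 nm (≥ 4 bins per bias standard deviation
at k = 700 and 300 K), tolerance 10⁻⁸ kT on max |ΔF_i|, 10⁵ iteration cap;
non-convergence raises with the last residual. Bins inside the covered
range with no counts are reported as gaps (NaN), never interpolated.

Each window enters with its effective sample count N_i/g_i, where the
statistical inefficiency g = 1 + 2 Σ C(t) is the initial-positive-sequence
estimator of the normalized autocorrelation (FFT-based, truncated at the
first non-positive lag; a constant series is flagged and assigned g = n).

Uncertainties come from a block bootstrap: each replicate resamples every
window's series in contiguous blocks of length ⌈g⌉ and re-solves WHAM on
the fixed bin grid; per-bin errors are the replicate standard deviations
after gauge alignment. Replicate profiles can be returned so the error of
any derived functional (e.g. ΔG°) is propagated by recomputing it per
replicate.

The midpoint rule leaves a second-order discretization residual of at most
kT(β k s Δ/4)²/2 per bin (s = window spacing, Δ = bin width; ~0.15 kT at
the defaults), which matters only when G is integrated into a single
number; for that reason integral quantities are computed on a finer
0.025 nm grid (see below).

Because the sampler moves in the xy-plane, the marginal the WHAM recovers
is U_eff(r) = U_r(r) − kT ln(r/r_ref): the 2D Jacobian is part of the
marginal and is deliberately *not* removed — the standard-state integrals
below consume exactly this marginal density. Comparisons between a
recovered profile and an analytic one are made after removing the mean
offset over the comparison range, the only gauge-invariant definition.

## Standard-state binding free energy

The marginal density P(r) = exp(−G(r)/kT) (no added 2πr factor — the polar
angle is already integrated out) is integrated over the bound and unbound
regions:

    ΔG° = −kT ln [ d ∫₀^{r*} P dr / ( h ∫_{r*}^{r_max} P dr ) ]

with r* the binding-mode boundary, d the axial range of the bound protein's
fluctuations, h the box length along z, and r_max = √(r*² + V°/(π h)) the
radius at which the cylindrical shell [r*, r_max] × h holds exactly the
standard volume V° = 1/(N_A · 1 mol L⁻¹) = 1.661 nm³. On an exactly flat
2D density (P ∝ r) this reduces to the closed form
ΔG° = −kT ln(π r*² d / V°), which the tests verify to < 10⁻⁶ kcal/mol.
Integrals use the trapezoid rule with exact boundary interpolation; below
the first bin center the density is linearly extrapolated (clamped at 0) so
the bound integral formally starts at r = 0. A warning is issued when the
profile varies by more than 0.5 kT across the unbound shell, since the
construction assumes a flat plateau there; on a flat plateau, integrating
the unbound state to the shell radius or to the full sampled range (with
the volume ratio re-derived) agree to < 0.05 kcal/mol.

Binding modes follow the tight/intermediate/loose convention
(r* = 2.0/2.4/3.0 nm: sequence-specific major-groove contact, recognition-
helix contact, any linker-mediated contact). ΔG° is monotone across nested
modes by construction. Between-system differences are reported as
ΔΔG(mode) = ΔG°_b − ΔG°_a (positive: system a binds more strongly).

d defaults to the central 95 % inter-quantile range of z over tight-mode
frames; since that estimator is a convention, a sensitivity table with the
90 %/95 %/99 %/peak-to-peak alternatives is always emitted.

When ΔG° is computed from a synthetic profile for validation, the WHAM is
re-solved at 0.025 nm bins: the integral of the profile is sensitive to the
midpoint-rule residual, and halving the bin width pushes that residual
(∝ Δ²) below the bootstrap resolution of the 1.6-million-sample datasets
used in the checks.

## Reweighting

A frame j from window i carries the unbiasing factor
w_j ∝ exp[(w_i(r_j) − F_i)/kT] with F_i from the converged WHAM solve.
Because exp(−F_i/kT) equals the biased partition function of window i, each
window's weighted sum estimates N_i⟨A⟩, so frames pool across windows
without further normalization. Observable profiles along r report the
weighted mean per bin with a frame bootstrap (resampling frames uniformly
and recomputing the weighted mean — resampling proportional to weight would
understate the error of heavy-tailed weight distributions by an order of
magnitude). Bins with Kish effective size (Σw)²/Σw² below 20 are masked,
not reported. 2D free-energy surfaces over (r, rotation angle) are the
−kT ln of the weighted joint histogram, min-gauged, with empty cells
masked; the default angular grid is 24 × 15°.

The Boltzmann inversion of the reweighted 1D r-histogram is the package's
internal consistency check against the WHAM profile. The two estimators
discretize the bias differently (per-frame vs bin-center), so the check
allows, besides the combined block-bootstrap errors of both estimators, the
analytic second-order midpoint bound above; cells dominated by one or two
high-weight frames (Kish n_eff < 50) are excluded as undetermined.

## Interface observables

**Hydrogen bonds.** Geometric criterion d(D–A) ≤ 0.35 nm and
∠(D–H–A) ≥ 150°, the common MD-analysis convention; both numbers are
explicit parameters. Donor/acceptor roles come from the force-field
sidecar; pairs within one residue are excluded. A water bridge is one water
hydrogen-bonded (either role) to a protein residue and a DNA residue in the
same frame. Occupancy is the fraction of frames with the contact present;
lifetime is the mean length of maximal consecutive-on runs with no grace
frames, converted to time by the frame spacing. Report tables keep contacts
with occupancy ≥ 0.05 by default; the full table is always available.
Per-base contact probability is the union (never the sum) of that base's
direct and water-mediated contacts.

**Interaction energies.** Σ over cross pairs within a plain 1.0 nm cutoff
of k_e q_i q_j/r + 4ε[(σ/r)¹² − (σ/r)⁶] with Lorentz–Berthelot combination;
no Ewald — intended for toy systems and per-residue decomposition of
extracted interface frames, not for absolute solvated energetics.

**SASA.** Shrake–Rupley with a Fibonacci-lattice point set (960 points
default), probe 0.14 nm, Bondi radii; hydrophobic class = {C, S}, all other
elements hydrophilic. Validated against the isolated-sphere and two-sphere
spherical-cap closed forms.

**Quasi-harmonic entropy.** Frames are superposed (mass-weighted Kabsch
fit to frame 0) before the mass-weighted covariance; eigenvalues λ give
mode frequencies ω = √(kT/λ) and per-mode quantum oscillator entropies
S/k_B = x/(eˣ−1) − ln(1−e⁻ˣ), x = ħω/kT. The quantum form is the default
because it is bounded and non-negative per mode; the classical form
1 − ln x (which lies below it and diverges for stiff modes) is available
as an option. Near-zero eigenvalues (λ ≤ 10⁻¹² amu nm²) are dropped with
the count reported; the superposition removes the six rigid-body modes.
Per-residue entropies use each residue's own block covariance normalized
per atom, reported both with and without hydrogens in the atom count since
the normalization convention is not universal.

**Rotations.** Orientation is the mass-weighted Kabsch rotation carrying
the reference structure onto the instantaneous one (det +1 enforced;
collinear inputs rejected), decomposed as R = R_x R_y R_z with
θ_y ∈ [−π/2, π/2] and the gimbal-lock convention θ_x = 0 when
|cos θ_y| < 10⁻⁸.

**Occupancy densities.** After superposition on a fit selection, each
voxel of a regular grid (default 0.05 nm) records the fraction of frames
with at least one selected atom inside; grids are written as OpenDX text
with origin/spacing metadata. Selections with fewer than three atoms skip
the rotational fit (an orientation is undefined).

## Problem sizes and determinism

The validation datasets are 16 windows × 10⁵ saved samples (1.6 × 10⁶
reaction-coordinate samples, ~2 min end to end on one CPU) for the
free-energy chain, and 10⁴–2 × 10⁴ frame toy complexes for the contact
statistics. Every stochastic component takes an explicit seed; identical
seeds give byte-identical outputs. Output files carry a header with the
tool version, configuration hash and seed.

## Known limitations

- The generator validates estimators, not force fields: passing tests
  demonstrate the analysis chain is correct on data whose ground truth is
  known, not that any particular MD system is converged. In particular the
  synthetic landscape has no barrier, no orientational coupling by default,
  and its windows are initialized at equilibrium — real umbrella runs
  inherit their starting configurations from steered MD and must document
  their own equilibration.
- WHAM here is 1D with midpoint bias discretization; 2D surfaces come from
  reweighting, not 2D WHAM, and no MBAR-style covariance propagation
  between bins is attempted.
- Interaction energies use plain cutoff electrostatics; for real
  trajectories the observable-profile machinery also accepts precomputed
  per-frame energy tables.
- The frame-level reweighted density estimator is unreliable in bins
  dominated by a few high-weight frames; such bins are masked by the Kish
  criterion rather than reported.
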