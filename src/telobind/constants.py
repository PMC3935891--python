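"""Physical constants and lookup tables.

Internal units throughout the package: length nm, energy kJ/mol, time ps,
mass amu, charge e, temperature K.  With these choices
1 amu nm^2 ps^-2 == 1 kJ/mol exactly, so mass-weighted covariances feed the
entropy formulas without conversion factors.  Final binding free-energy
tables are reported in kcal/mol.
"""

#: Boltzmann constant, kJ mol^-1 K^-1
KB = 0.0083144621

#: Avogadro constant, mol^-1
N_AVOGADRO = 6.02214076e23

#: kJ per kcal
KJ_PER_KCAL = 4.184

#: Coulomb prefactor k_e = 1/(4 pi eps0), kJ mol^-1 nm e^-2
COULOMB_K = 138.935458

#: Reduced Planck constant, kJ ps mol^-1
HBAR = 0.0635077993

#: Default simulation temperature, K
DEFAULT_T = 300.0

#: Standard-state volume per molecule at 1 mol/L, nm^3 (1e24 / N_A)
V_STANDARD = 1e24 / N_AVOGADRO


def standard_volume_nm3() -> float:
    """Volume per molecule at the 1 M standard concentration, in nm^3.

    V = 1 / (N_A * 1 mol/L) expressed in cubic nanometres.
    """
    litres_per_nm3 = 1e-24
    return 1.0 / (N_AVOGADRO * litres_per_nm3)


#: Bondi van der Waals radii, nm, by element symbol
BONDI_RADII_NM = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "F": 0.147,
    "P": 0.180,
    "S": 0.180,
    "CL": 0.175,
    "K": 0.275,
    "NA": 0.227,
    "MG": 0.173,
    "BR": 0.185,
    "I": 0.198,
}

#: Atomic masses, amu, by element symbol
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "K": 39.098,
    "NA": 22.990,
    "MG": 24.305,
    "BR": 79.904,
    "I": 126.904,
}

#: Elements counted as hydrophobic for the SASA split
HYDROPHOBIC_ELEMENTS = frozenset({"C", "S"})
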