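"""Structural observable kernels against closed forms: hydrogen bonds,
water bridges, interaction energies, SASA, quasi-harmonic entropy,
rotations/Euler angles and occupancy densities."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import norm

import telobind as tb
from telobind.constants import KB, HBAR, COULOMB_K
from telobind.entropy import oscillator_entropy
from telobind.hbonds import HBondCriteria, detect_hbonds
from telobind.rotations import rotation_xyz, euler_xyz, best_fit_rotation
from telobind.sasa import fibonacci_sphere

from conftest import make_atoms

KT300 = KB * 300.0


def two_atom_ensemble(pos_b, q_a=0.0, q_b=0.0):
    atoms = make_atoms([("A1", "C", 1, "A", q_a, False, False),
                        ("B1", "C", 2, "B", q_b, False, False)])
    coords = np.array([[[0.0, 0.0, 0.0], pos_b]])
    return tb.FrameEnsemble(atoms=atoms, coords=coords)


@pytest.fixture(scope="module")
def telegraph_complex():
    spec = tb.ToyComplexSpec(n_frames=10_000, contacts=(
        tb.ContactSpec(protein_res=0, dna_base=0, p_on=0.9, k_off=0.1),
        tb.ContactSpec(protein_res=1, dna_base=1, p_on=0.3, k_off=0.1,
                       kind="bridge"),
        tb.ContactSpec(protein_res=2, dna_base=2, p_on=0.5, k_off=0.5),
        tb.ContactSpec(protein_res=3, dna_base=2, p_on=0.5, k_off=0.5),
    ))
    return tb.make_toy_complex(spec, seed=17)


class TestDetectHbonds:
    def build(self, d_da, angle_offset_deg=0.0):
        """Donor N at origin with H toward +x; acceptor at distance d."""
        a = np.deg2rad(angle_offset_deg)
        acc = d_da * np.array([np.cos(a), np.sin(a), 0.0])
        atoms = make_atoms([("N", "N", 1, "A", -0.4, True, False),
                            ("HN", "H", 1, "A", 0.3, False, False),
                            ("O", "O", 2, "B", -0.5, False, True)])
        coords = np.array([[[0, 0, 0], [0.1, 0, 0], acc]])
        return tb.FrameEnsemble(atoms=atoms, coords=coords,
                                bonded_hydrogens={0: [1]})

    def test_ideal_geometry_detected(self):
        assert detect_hbonds(self.build(0.28), 0) == {(0, 2)}

    def test_long_distance_rejected(self):
        assert detect_hbonds(self.build(0.60), 0) == set()

    def test_angle_cutoff(self):
        # acceptor 45 deg off the N-H axis: D-H-A angle ~ 128 deg < 150
        assert detect_hbonds(self.build(0.30, 45.0), 0) == set()

    def test_rigid_motion_invariance(self):
        ens = self.build(0.28)
        R = rotation_xyz(0.4, -0.2, 1.1)
        moved = tb.FrameEnsemble(atoms=ens.atoms,
                                 coords=ens.coords @ R.T + 5.0,
                                 bonded_hydrogens=ens.bonded_hydrogens)
        assert detect_hbonds(moved, 0) == {(0, 2)}

    def test_framewise_match_with_generator_ledger(self, telegraph_complex):
        ens = telegraph_complex
        key = (0, 0, "direct")
        donor, acceptor = ens.meta["contact_atoms"][key]
        states = ens.meta["contact_states"][key]
        for f in range(0, ens.n_frames, 97):
            found = (donor, acceptor) in detect_hbonds(ens, f)
            assert found == bool(states[f])

    def test_missing_hydrogens_raise(self):
        ens = self.build(0.28)
        ens.bonded_hydrogens = {}
        with pytest.raises(ValueError, match="hydrogen"):
            detect_hbonds(ens, 0)


class TestWaterBridges:
    def test_scripted_bridge_occupancy(self, telegraph_complex):
        ens = telegraph_complex
        key = (1, 1, "bridge")
        states = ens.meta["contact_states"][key]
        hits = np.array([len(tb.detect_water_bridges(ens, f)) > 0
                         for f in range(0, ens.n_frames, 11)])
        assert np.array_equal(hits, states[::11])

    def test_water_bonded_to_protein_only_is_no_bridge(self):
        # water donating to a protein O, nothing near the DNA chain
        atoms = make_atoms([("OW", "O", 9, "W", -0.5, True, True),
                            ("HW1", "H", 9, "W", 0.3, False, False),
                            ("HW2", "H", 9, "W", 0.3, False, False),
                            ("O", "O", 1, "A", -0.5, False, True),
                            ("N7", "N", 2, "B", -0.4, False, True)])
        atoms.loc[0, "resname"] = "HOH"
        coords = np.array([[[0, 0, 0], [0.1, 0, 0], [0, 0.1, 0],
                            [0.28, 0, 0], [5, 5, 5]]])
        ens = tb.FrameEnsemble(atoms=atoms, coords=coords,
                               bonded_hydrogens={0: [1, 2]})
        assert tb.detect_water_bridges(ens, 0, water_resname="X") == set()
        ens.atoms.loc[0, "resname"] = "HOH"
        assert tb.detect_water_bridges(ens, 0) == set()


class TestHbondStatistics:
    def test_telegraph_occupancy_and_lifetime(self, telegraph_complex):
        ens = telegraph_complex
        _, full = tb.hbond_statistics(ens)
        row = full[(full["protein_residue"] == "PRS1:A")
                   & (full["type"] == "direct")].iloc[0]
        p_on, k_off, n = 0.9, 0.1, ens.n_frames
        phi = 1 - k_off - k_off * p_on / (1 - p_on)
        se_occ = np.sqrt(p_on * (1 - p_on) / n * (1 + phi) / (1 - phi))
        assert abs(row["occupancy"] - p_on) < 3 * se_occ
        # run lengths are geometric with mean 1/k_off
        n_runs = n * p_on * k_off
        se_life = (1 / k_off) / np.sqrt(n_runs)
        assert abs(row["mean_lifetime"] - 1 / k_off) < 3 * se_life

    def test_alternating_series_bookkeeping(self):
        from telobind.hbonds import _run_lengths
        on = np.array([True, False] * 50)
        assert on.mean() == 0.5
        runs = _run_lengths(on)
        assert np.mean(runs) == 1.0 and len(runs) == 50

    def test_always_on_pair(self):
        spec = tb.ToyComplexSpec(n_frames=250, contacts=(
            tb.ContactSpec(protein_res=0, dna_base=0, p_on=1.0),))
        ens = tb.make_toy_complex(spec, seed=3)
        _, full = tb.hbond_statistics(ens)
        row = full.iloc[0]
        assert row["occupancy"] == 1.0
        assert row["mean_lifetime"] == 250.0

    def test_report_threshold_filters(self, telegraph_complex):
        report, full = tb.hbond_statistics(telegraph_complex,
                                           report_threshold=0.4)
        assert (report["occupancy"] >= 0.4).all()
        assert len(full) >= len(report)


class TestBaseContactProbability:
    def test_union_of_two_independent_bonds(self, telegraph_complex):
        """Two p=0.5 telegraph bonds on one base: union probability 0.75."""
        ens = telegraph_complex
        table = tb.base_contact_probability(ens)
        probs = dict(zip(table["base"], table["probability"]))
        # fast-switching chains (k_off = 0.5): modest autocorrelation
        assert probs["DG3:B"] == pytest.approx(0.75, abs=0.04)
        assert probs["DG4:B"] == 0.0

    def test_never_exceeds_one(self, telegraph_complex):
        table = tb.base_contact_probability(telegraph_complex)
        assert (table["probability"] <= 1.0).all()


class TestInteractionEnergy:
    def test_coulomb_hand_value(self):
        """+1e and -1e at 0.5 nm: k_e q1 q2 / r = -277.87 kJ/mol."""
        ens = two_atom_ensemble([0.5, 0.0, 0.0], q_a=1.0, q_b=-1.0)
        ens.atoms["epsilon"] = 0.0
        e = tb.interaction_energy(ens, 0, np.array([0]), np.array([1]))
        assert e == pytest.approx(COULOMB_K * -1.0 / 0.5, rel=1e-12)
        assert e == pytest.approx(-277.87, abs=0.01)

    def test_lj_zero_at_sigma(self):
        ens = two_atom_ensemble([0.3, 0.0, 0.0])  # sigma = 0.3 for both
        e = tb.interaction_energy(ens, 0, np.array([0]), np.array([1]))
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_coulomb_bilinearity(self):
        e1 = tb.interaction_energy(
            two_atom_ensemble([0.7, 0, 0], 0.5, -0.5), 0,
            np.array([0]), np.array([1]), split=True)[0]
        e2 = tb.interaction_energy(
            two_atom_ensemble([0.7, 0, 0], 1.0, -1.0), 0,
            np.array([0]), np.array([1]), split=True)[0]
        assert e2 == pytest.approx(4 * e1, rel=1e-12)

    def test_symmetry_in_group_exchange(self):
        ens = two_atom_ensemble([0.45, 0.2, -0.1], 0.3, -0.8)
        a = tb.interaction_energy(ens, 0, np.array([0]), np.array([1]))
        b = tb.interaction_energy(ens, 0, np.array([1]), np.array([0]))
        assert a == pytest.approx(b, rel=1e-12)

    def test_cutoff_truncates(self):
        ens = two_atom_ensemble([1.5, 0, 0], 1.0, -1.0)
        assert tb.interaction_energy(ens, 0, np.array([0]), np.array([1]),
                                     cutoff=1.0) == 0.0

    def test_overlap_rejected(self):
        ens = two_atom_ensemble([0.5, 0, 0])
        with pytest.raises(ValueError, match="overlap"):
            tb.interaction_energy(ens, 0, np.array([0]), np.array([0]))


class TestSasa:
    def test_isolated_sphere_closed_form(self, single_atom_ensemble):
        res = tb.sasa(single_atom_ensemble, 0, probe_radius=0.14,
                      radii_override={"C": 0.15})
        assert res.total == pytest.approx(4 * np.pi * 0.29**2, rel=0.005)

    def test_distant_atoms_are_isolated(self):
        ens = two_atom_ensemble([2.0, 0.0, 0.0])
        res = tb.sasa(ens, 0)
        iso = 4 * np.pi * (0.17 + 0.14) ** 2
        assert res.per_atom[0] == pytest.approx(iso, rel=0.005)
        assert res.per_atom[1] == pytest.approx(iso, rel=0.005)
        assert res.total <= 2 * iso + 1e-9

    def test_two_overlapping_spheres_cap_formula(self):
        """Equal spheres at distance D: accessible area per sphere is
        4 pi R^2 - 2 pi R (R - D/2)."""
        d = 0.35
        ens = two_atom_ensemble([d, 0.0, 0.0])
        res = tb.sasa(ens, 0, n_sphere_points=960)
        R = 0.17 + 0.14
        expect = 4 * np.pi * R**2 - 2 * np.pi * R * (R - d / 2)
        assert res.per_atom[0] == pytest.approx(expect, rel=0.01)
        assert res.per_atom[1] == pytest.approx(expect, rel=0.01)

    def test_hydrophobic_hydrophilic_split(self):
        atoms = make_atoms([("C1", "C", 1, "A", 0.0, False, False),
                            ("O1", "O", 2, "A", -0.5, False, True)])
        coords = np.array([[[0.0, 0, 0], [5.0, 0, 0]]])
        ens = tb.FrameEnsemble(atoms=atoms, coords=coords)
        res = tb.sasa(ens, 0)
        assert res.hydrophobic == pytest.approx(4 * np.pi * 0.31**2, rel=0.01)
        assert res.hydrophilic == pytest.approx(4 * np.pi * 0.292**2,
                                                rel=0.01)

    def test_unknown_element_without_override(self):
        atoms = make_atoms([("X1", "XX", 1, "A", 0.0, False, False)])
        ens = tb.FrameEnsemble(atoms=atoms, coords=np.zeros((1, 1, 3)))
        with pytest.raises(ValueError, match="radius"):
            tb.sasa(ens, 0)
        res = tb.sasa(ens, 0, radii_override={"XX": 0.2})
        assert res.total == pytest.approx(4 * np.pi * 0.34**2, rel=0.005)

    def test_point_lattice_is_quasi_uniform(self):
        pts = fibonacci_sphere(500)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
        assert np.abs(pts.mean(axis=0)).max() < 0.01


class TestQuasiharmonicEntropy:
    def gaussian_ensemble(self, sigma2, n=20_000, seed=0):
        """Rigid triangle with one Gaussian coordinate on atom 2."""
        rng = np.random.default_rng(seed)
        base = np.array([[0, 0, 0], [0.5, 0, 0], [0, 0.5, 0]], float)
        coords = np.repeat(base[None], n, axis=0).copy()
        coords[:, 2, 2] = rng.normal(scale=np.sqrt(sigma2), size=n)
        atoms = make_atoms([("C1", "C", 1, "A", 0, False, False),
                            ("C2", "C", 1, "A", 0, False, False),
                            ("C3", "C", 2, "A", 0, False, False)])
        return tb.FrameEnsemble(atoms=atoms, coords=coords)

    def test_frozen_selection_zero_entropy(self):
        ens = self.gaussian_ensemble(1e-30, n=100)
        spec, _ = tb.quasiharmonic_entropy(ens, np.array([0, 1]),
                                           fit=False, per_residue=False)
        assert spec.total == pytest.approx(0.0, abs=1e-6)
        assert spec.n_dropped == 6  # every mode singular, count reported

    def test_gaussian_oscillator_closed_form(self):
        sigma2, m = 4e-4, 12.011
        ens = self.gaussian_ensemble(sigma2)
        spec, _ = tb.quasiharmonic_entropy(ens, fit=False, per_residue=False)
        x = HBAR * np.sqrt(KT300 / (m * sigma2)) / KT300
        s_theory = oscillator_entropy(np.array([x]))[0] * KB * 1000
        assert spec.eigenvalues.size == 1
        assert spec.total == pytest.approx(s_theory, rel=0.02)

    def test_entropy_monotone_in_variance(self):
        s = []
        for sigma2 in (1e-4, 4e-4, 1.6e-3):
            ens = self.gaussian_ensemble(sigma2)
            spec, _ = tb.quasiharmonic_entropy(ens, fit=False,
                                               per_residue=False)
            s.append(spec.total)
        assert s[0] < s[1] < s[2]

    def test_superposition_removes_rigid_body_modes(self):
        """A noisy rigid body, after fitting, keeps only internal modes."""
        rng = np.random.default_rng(1)
        base = rng.normal(size=(6, 3))
        n = 4000
        coords = np.empty((n, 6, 3))
        for f in range(n):
            R = Rotation.random(random_state=rng).as_matrix()
            shift = rng.normal(scale=0.5, size=3)
            coords[f] = base @ R.T + shift + rng.normal(scale=1e-3,
                                                        size=(6, 3))
        atoms = make_atoms([(f"C{i}", "C", 1, "A", 0, False, False)
                            for i in range(6)])
        ens = tb.FrameEnsemble(atoms=atoms, coords=coords)
        spec, _ = tb.quasiharmonic_entropy(ens, fit=True, per_residue=False)
        lam = np.sort(spec.eigenvalues)[::-1]
        # 18 dof - 6 rigid-body: the 12 internal noise modes dominate and
        # the residual rigid-body eigenvalues are orders of magnitude smaller
        assert lam.size >= 12
        assert lam.size == 12 or lam[11] / max(lam[12], 1e-300) > 1e2

    def test_per_residue_table(self, telegraph_complex):
        sel = telegraph_complex.indices(chain="A")
        _, table = tb.quasiharmonic_entropy(telegraph_complex, sel)
        assert {"S_per_atom", "S_per_heavy_atom"} <= set(table.columns)
        assert (table["S_per_atom"] >= 0).all()

    def test_classical_form_available(self):
        ens = self.gaussian_ensemble(4e-4)
        spec_q, _ = tb.quasiharmonic_entropy(ens, fit=False,
                                             per_residue=False)
        spec_c, _ = tb.quasiharmonic_entropy(ens, fit=False, classical=True,
                                             per_residue=False)
        # the classical oscillator entropy 1 - ln x lies below the quantum
        # form for x > 0 (and diverges to -inf for stiff modes, which is why
        # the quantum form is the default)
        assert spec_c.total < spec_q.total


class TestRotations:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        R = best_fit_rotation(pts, pts)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-12)
        assert euler_xyz(np.eye(3)) == (0.0, 0.0, 0.0)

    def test_recovers_applied_rotation(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3))
        R0 = rotation_xyz(0.3, -0.7, 1.2)
        R = best_fit_rotation(pts @ R0.T, pts, masses=rng.uniform(1, 16, 12))
        assert np.abs(R - R0).max() < 1e-9

    def test_scipy_cross_check(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 3))
        R0 = Rotation.random(random_state=rng).as_matrix()
        ours = best_fit_rotation(pts @ R0.T, pts)
        theirs, _ = Rotation.align_vectors(pts @ R0.T, pts)
        np.testing.assert_allclose(ours, theirs.as_matrix(), atol=1e-9)

    def test_noisy_rotation_proper(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(20, 3))
        R0 = rotation_xyz(-1.0, 0.4, 2.5)
        noisy = pts @ R0.T + rng.normal(scale=0.01, size=(20, 3))
        R = best_fit_rotation(noisy, pts)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert np.abs(R - R0).max() < 0.05

    def test_collinear_rejected(self):
        pts = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="collinear"):
            best_fit_rotation(pts, pts)

    def test_pure_z_rotation(self):
        a, b, c = euler_xyz(rotation_xyz(0.0, 0.0, 0.3))
        assert (a, b) == (0.0, 0.0)
        assert c == pytest.approx(0.3, abs=1e-12)

    def test_euler_round_trip_random(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            R = Rotation.random(random_state=rng).as_matrix()
            a, b, c = euler_xyz(R)
            assert abs(b) <= np.pi / 2 + 1e-12
            np.testing.assert_allclose(rotation_xyz(a, b, c), R, atol=1e-10)

    def test_gimbal_lock_convention(self):
        R = rotation_xyz(0.7, np.pi / 2, -0.2)  # degenerate: only a-c fixed
        a, b, c = euler_xyz(R)
        assert a == 0.0
        np.testing.assert_allclose(rotation_xyz(a, b, c), R, atol=1e-9)

    def test_non_rotation_rejected(self):
        with pytest.raises(ValueError, match="rotation"):
            euler_xyz(np.diag([1.0, 1.0, -1.0]))


class TestOccupancyDensity:
    def test_static_atom_single_voxel(self, single_atom_ensemble):
        grid = tb.occupancy_density(single_atom_ensemble, np.array([0]),
                                    grid_spacing=0.1)
        assert grid.values.max() == 1.0
        assert (grid.values == 1.0).sum() == 1

    def test_alternating_atom_half_occupancy(self):
        atoms = make_atoms([("C1", "C", 1, "A", 0, False, False)])
        coords = np.zeros((10, 1, 3))
        coords[1::2, 0, 0] = 1.0
        ens = tb.FrameEnsemble(atoms=atoms, coords=coords)
        grid = tb.occupancy_density(ens, np.array([0]), grid_spacing=0.2)
        vals = np.sort(grid.values.ravel())[::-1]
        assert vals[0] == pytest.approx(0.5)
        assert vals[1] == pytest.approx(0.5)
        assert vals[2] == 0.0

    def test_gaussian_cell_integrals(self):
        rng = np.random.default_rng(5)
        n, sigma, h = 40_000, 0.1, 0.1
        atoms = make_atoms([("C1", "C", 1, "A", 0, False, False)])
        coords = rng.normal(scale=sigma, size=(n, 1, 3))
        ens = tb.FrameEnsemble(atoms=atoms, coords=coords)
        grid = tb.occupancy_density(ens, np.array([0]), grid_spacing=h,
                                    padding=0.05)
        # check the fullest voxels against the product of 1D cell integrals
        flat = grid.values.ravel()
        for idx in np.argsort(flat)[::-1][:5]:
            ijk = np.unravel_index(idx, grid.values.shape)
            lo = grid.origin + np.array(ijk) * h
            p = np.prod([norm.cdf((lo[d] + h) / sigma)
                         - norm.cdf(lo[d] / sigma) for d in range(3)])
            se = np.sqrt(p * (1 - p) / n)
            assert abs(flat[idx] - p) <= 3 * se + 1e-3

    def test_empty_selection(self, single_atom_ensemble):
        with pytest.raises(ValueError, match="empty"):
            tb.occupancy_density(single_atom_ensemble, np.array([], int))
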