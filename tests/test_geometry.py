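import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import biotite.structure as struc

from pbflex.ensemble_io import Selection, SelectionError, TopologyError, select_atoms
from pbflex.geometry import (
    backbone_dihedrals,
    center_of_mass,
    com_distance_series,
    contact_counts,
    contacts_by_partner_domain,
    dihedral_angle,
    kabsch_superpose,
    rmsd_series,
    rmsf_profile,
    wrap_angle,
)
from pbflex.synthetic_ensembles import GeneratorSpec, generate_ensemble

from conftest import make_ensemble


def quaternion_superpose_rmsd(mobile, reference):
    """Independent superposition oracle: Horn's closed-form quaternion method."""
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)
    Sxx, Sxy, Sxz = (P[:, 0] @ Q[:, 0], P[:, 0] @ Q[:, 1], P[:, 0] @ Q[:, 2])
    Syx, Syy, Syz = (P[:, 1] @ Q[:, 0], P[:, 1] @ Q[:, 1], P[:, 1] @ Q[:, 2])
    Szx, Szy, Szz = (P[:, 2] @ Q[:, 0], P[:, 2] @ Q[:, 1], P[:, 2] @ Q[:, 2])
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(P**2) + np.sum(Q**2) - 2.0 * lam) / P.shape[0]
    return np.sqrt(max(msd, 0.0))


class TestDihedralAngle:
    def test_cis_is_zero(self):
        assert dihedral_angle((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)) == pytest.approx(0.0, abs=1e-12)

    def test_trans_is_180(self):
        assert dihedral_angle((0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0)) == pytest.approx(180.0)

    def test_right_angle_sign_matches_iupac_convention(self):
        # Independent oracle: biotite implements the standard convention
        # under which alpha helices measure phi ~ -57 deg.
        pts = [np.array(p, float) for p in ((0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1))]
        expected = np.degrees(struc.dihedral(*pts))
        value = dihedral_angle(*pts)
        assert value == pytest.approx(expected, abs=1e-9)
        assert value == pytest.approx(90.0)

    def test_collinear_points_raise(self):
        with pytest.raises(ValueError):
            dihedral_angle((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-1000, 1000), st.integers(-3, 3))
    def test_wrap_into_half_open_interval(self, angle, k):
        wrapped = wrap_angle(angle)
        assert -180.0 < wrapped <= 180.0
        assert wrap_angle(angle + 360.0 * k) == pytest.approx(wrapped, abs=1e-9)


class TestBackboneDihedrals:
    def test_helical_chain_has_canonical_angles(self):
        spec = GeneratorSpec(n_residues=10, n_frames=2, recipes=(("m" * 10, 1.0),), seed=1)
        dih = backbone_dihedrals(generate_ensemble(spec))
        # PB m carries the alpha-helical centre (-65.5, -38.9)
        assert np.allclose(dih.phi_deg[:, 1:], -65.54, atol=1e-6)
        assert np.allclose(dih.psi_deg[:, :-1], -38.88, atol=1e-6)
        assert np.all(np.isnan(dih.phi_deg[:, 0]))
        assert np.all(np.isnan(dih.psi_deg[:, -1]))

    def test_two_residue_chain_boundary_rule(self):
        from pbflex.synthetic_ensembles import build_coordinates
        from pbflex.ensemble_io import Frame, StructureEnsemble

        top, coords = build_coordinates(
            np.array([np.nan, -60.0]), np.array([140.0, np.nan])
        )
        ens = StructureEnsemble(top, [Frame(coords, 100.0, "r1")])
        dih = backbone_dihedrals(ens)
        assert np.isnan(dih.phi_deg[0, 0]) and np.isfinite(dih.phi_deg[0, 1])
        assert np.isfinite(dih.psi_deg[0, 0]) and np.isnan(dih.psi_deg[0, 1])

    def test_missing_backbone_atom_names_residue(self, helix_ensemble):
        broken = select_atoms(
            helix_ensemble,
            Selection(atom_names=("N", "CA", "C", "O")),
        )
        # drop CA of residue 5
        idx = [
            i
            for i, a in enumerate(broken.topology)
            if not (a.residue_number == 5 and a.atom_name == "CA")
        ]
        from pbflex.ensemble_io import Frame, StructureEnsemble

        topo = [broken.topology[i] for i in idx]
        frames = [Frame(f.coordinates[idx], f.time_ps, f.replica_id) for f in broken.frames]
        with pytest.raises(TopologyError, match="residue 5"):
            backbone_dihedrals(StructureEnsemble(topo, frames))


class TestKabsch:
    def test_self_superposition_is_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        _, _, rmsd = kabsch_superpose(X, X)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 3))
        theta = 0.7
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        Y = X @ R.T + np.array([5.0, -2.0, 3.0])
        _, _, rmsd = kabsch_superpose(Y, X)
        assert rmsd <= 1e-6

    def test_agrees_with_quaternion_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(4, 3))
        Y = X + rng.normal(scale=0.3, size=(4, 3))
        _, _, rmsd = kabsch_superpose(Y, X)
        assert rmsd == pytest.approx(quaternion_superpose_rmsd(Y, X), abs=1e-9)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 3))
        Y = X + rng.normal(scale=0.5, size=(8, 3))
        assert kabsch_superpose(X, Y)[2] == pytest.approx(kabsch_superpose(Y, X)[2], abs=1e-9)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 3))
        Y = rng.normal(size=(6, 3))
        R, _, _ = kabsch_superpose(X, Y)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRMSDSeries:
    def test_copies_of_reference_give_zeros(self, helix_ensemble):
        ref = helix_ensemble.frames[0]
        coords = [ref.coordinates.copy() for _ in range(3)]
        ens = make_ensemble(
            coords,
            atom_names=[a.atom_name for a in helix_ensemble.topology],
            residue_numbers=[a.residue_number for a in helix_ensemble.topology],
            residue_names=[a.residue_name for a in helix_ensemble.topology],
            elements=[a.element for a in helix_ensemble.topology],
        )
        rmsd = rmsd_series(ens, ref)
        assert np.allclose(rmsd, 0.0, atol=1e-9)

    def test_rigidly_displaced_frame_is_zero(self, helix_ensemble):
        ref = helix_ensemble.frames[0]
        shifted = ref.coordinates + np.array([10.0, 0.0, 0.0])
        ens = make_ensemble(
            [ref.coordinates, shifted],
            atom_names=[a.atom_name for a in helix_ensemble.topology],
            residue_numbers=[a.residue_number for a in helix_ensemble.topology],
            residue_names=[a.residue_name for a in helix_ensemble.topology],
            elements=[a.element for a in helix_ensemble.topology],
        )
        assert np.allclose(rmsd_series(ens, ref), 0.0, atol=1e-9)

    def test_isotropic_noise_matches_closed_form(self):
        # Gaussian per-coordinate noise of scale sigma leaves an expected
        # post-fit RMSD of sigma*sqrt(3)*sqrt(1 - 6/(3N)) (6 fitted DOF).
        rng = np.random.default_rng(5)
        N, sigma, frames = 60, 0.5, 200
        ref = rng.normal(scale=10.0, size=(N, 3))
        coords = [ref + rng.normal(scale=sigma, size=(N, 3)) for _ in range(frames)]
        ens = make_ensemble(coords, atom_names=["CA"] * N,
                            residue_numbers=list(range(1, N + 1)))
        mean_rmsd = rmsd_series(ens, ref).mean()
        expected = sigma * np.sqrt(3.0) * np.sqrt(1.0 - 6.0 / (3.0 * N))
        assert mean_rmsd == pytest.approx(expected, rel=0.05)


class TestRMSF:
    def test_identical_frames_give_zero(self, helix_ensemble):
        coords = [helix_ensemble.frames[0].coordinates.copy() for _ in range(4)]
        ens = make_ensemble(
            coords,
            atom_names=[a.atom_name for a in helix_ensemble.topology],
            residue_numbers=[a.residue_number for a in helix_ensemble.topology],
        )
        _, rmsf = rmsf_profile(ens)
        assert np.allclose(rmsf, 0.0, atol=1e-9)

    def test_single_oscillating_atom_recovers_amplitude(self):
        rng = np.random.default_rng(6)
        N, d = 30, 1.5
        base = rng.normal(scale=8.0, size=(N, 3))
        up, down = base.copy(), base.copy()
        up[7, 0] += d
        down[7, 0] -= d
        ens = make_ensemble([up, down] * 10, atom_names=["CA"] * N,
                            residue_numbers=list(range(1, N + 1)))
        _, rmsf = rmsf_profile(ens)
        assert rmsf[7] == pytest.approx(d, rel=0.05)
        assert np.all(rmsf[np.arange(N) != 7] < 0.2 * d)

    def test_single_frame_raises(self, helix_ensemble):
        single = helix_ensemble.subset_frames([0])
        with pytest.raises(Exception):
            rmsf_profile(single)


class TestCenterOfMass:
    def test_single_atom_is_its_position(self):
        ens = make_ensemble([[(1.0, 2.0, 3.0)]], atom_names=["CA"], elements=["C"])
        com = center_of_mass(ens.frames[0], Selection(), ens.topology)
        assert np.allclose(com, [1.0, 2.0, 3.0])

    def test_equal_masses_give_midpoint(self):
        ens = make_ensemble([[(0, 0, 0), (2, 0, 0)]], atom_names=["C1", "C2"],
                            elements=["C", "C"])
        com = center_of_mass(ens.frames[0], Selection(), ens.topology)
        assert np.allclose(com, [1.0, 0.0, 0.0])

    def test_mass_weighting_carbon_oxygen(self):
        ens = make_ensemble([[(0, 0, 0), (1, 0, 0)]], atom_names=["C", "O"],
                            elements=["C", "O"])
        com = center_of_mass(ens.frames[0], Selection(), ens.topology)
        assert com[0] == pytest.approx(15.999 / (12.011 + 15.999), abs=1e-6)


class TestCOMDistances:
    def test_identical_selections_give_zero(self, helix_ensemble):
        sel = Selection(residue_range=(1, 6))
        series = com_distance_series(helix_ensemble, sel, sel)
        assert np.allclose(series.values_A, 0.0)

    def test_translation_invariance(self, helix_ensemble):
        sel_a = Selection(residue_range=(1, 4))
        sel_b = Selection(residue_range=(9, 12))
        base = com_distance_series(helix_ensemble, sel_a, sel_b).values_A
        shifted = make_ensemble(
            [f.coordinates + 25.0 for f in helix_ensemble.frames],
            atom_names=[a.atom_name for a in helix_ensemble.topology],
            residue_numbers=[a.residue_number for a in helix_ensemble.topology],
            residue_names=[a.residue_name for a in helix_ensemble.topology],
            elements=[a.element for a in helix_ensemble.topology],
        )
        moved = com_distance_series(shifted, sel_a, sel_b).values_A
        assert np.allclose(base, moved, atol=1e-9)

    def test_fixed_separation_is_constant(self):
        coords = [[(0, 0, 0), (10.0, 0, 0)]] * 3
        ens = make_ensemble(coords, atom_names=["CA", "CA"], residue_numbers=[1, 2],
                            elements=["C", "C"])
        series = com_distance_series(
            ens, Selection.residues([1]), Selection.residues([2])
        )
        assert np.allclose(series.values_A, 10.0)


class TestContacts:
    def test_boundary_distance_is_inclusive(self):
        coords = [[(0, 0, 0), (8.0, 0, 0), (100.0, 0, 0)]]
        ens = make_ensemble(coords, atom_names=["CA"] * 3, residue_numbers=[1, 2, 3])
        series = contact_counts(ens, cutoff_A=8.0)
        assert series.counts[0].tolist() == [1, 1, 0]

    def test_extended_chain_interior_residue_has_four_contacts(self, extended_ensemble):
        series = contact_counts(extended_ensemble)
        # brute-force all-pairs oracle
        ca = select_atoms(extended_ensemble, Selection.calpha()).coords[0]
        d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=2)
        oracle = ((d <= 8.0) & ~np.eye(len(ca), dtype=bool)).sum(axis=1)
        assert series.counts[0].tolist() == oracle.tolist()
        assert series.counts[0][5] == 4  # i+-1 at 3.8 A, i+-2 at 6.8 A

    def test_symmetry_total_is_twice_pair_count(self, helix_ensemble):
        series = contact_counts(helix_ensemble)
        ca = select_atoms(helix_ensemble, Selection.calpha()).coords
        for fi in range(helix_ensemble.n_frames):
            d = np.linalg.norm(ca[fi][:, None] - ca[fi][None, :], axis=2)
            pairs = ((d <= 8.0) & ~np.eye(d.shape[0], dtype=bool)).sum() // 2
            assert series.counts[fi].sum() == 2 * pairs

    def test_exclusion_removes_sequence_neighbours(self, extended_ensemble):
        with_neighbours = contact_counts(extended_ensemble, exclusion=0)
        without = contact_counts(extended_ensemble, exclusion=2)
        assert without.counts[0][5] == with_neighbours.counts[0][5] - 4


class TestContactsByDomain:
    def test_partition_sums_to_total_over_domains(self, helix_ensemble):
        domains = {"D1": (1, 4), "D2": (5, 8), "D3": (9, 12)}
        split = contacts_by_partner_domain(helix_ensemble, 6, domains)
        total = contact_counts(helix_ensemble)
        col = list(total.residue_numbers).index(6)
        summed = split["D1"] + split["D2"] + split["D3"]
        assert np.array_equal(summed, total.counts[:, col])

    def test_absent_partner_domain_counts_zero(self):
        coords = [[(0, 0, 0), (4.0, 0, 0), (100.0, 0, 0)]]
        ens = make_ensemble(coords, atom_names=["CA"] * 3, residue_numbers=[1, 2, 3])
        split = contacts_by_partner_domain(ens, 1, {"near": (2, 2), "far": (3, 3)})
        assert split["near"].tolist() == [1]
        assert split["far"].tolist() == [0]

    def test_overlapping_domains_rejected(self, helix_ensemble):
        with pytest.raises(ValueError, match="overlap"):
            contacts_by_partner_domain(helix_ensemble, 6, {"A": (1, 6), "B": (6, 12)})
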