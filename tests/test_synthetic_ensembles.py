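import numpy as np
import pytest
from scipy import stats

from pbflex.ensemble_io import Frame, StructureEnsemble
from pbflex.geometry import backbone_dihedrals, wrap_angle
from pbflex.pb_alphabet import assign_ensemble, neq_profile, pb_profile
from pbflex.synthetic_ensembles import (
    GeneratorSpec,
    GeometryConstants,
    build_coordinates,
    generate_ensemble,
    generate_variant_pair,
    sample_dihedrals,
    two_variant_scenario,
)


class TestSampleDihedrals:
    def test_noise_free_single_recipe_hits_prototype_centres(self, pb_table):
        spec = GeneratorSpec(n_residues=8, n_frames=3, recipes=(("m" * 8, 1.0),), seed=0)
        dih, _ = sample_dihedrals(spec)
        phi_c, psi_c = pb_table.prototype("m")[3], pb_table.prototype("m")[4]
        assert np.allclose(dih.phi_deg[:, 1:], phi_c)
        assert np.allclose(dih.psi_deg[:, :-1], psi_c)

    def test_recipe_draws_follow_mixture_weights(self):
        spec = GeneratorSpec(
            n_residues=6, n_frames=2000,
            recipes=(("m" * 6, 0.5), ("d" * 6, 0.5)), seed=1,
        )
        _, idx = sample_dihedrals(spec)
        k = int((idx == 0).sum())
        lo, hi = stats.binom.interval(0.999, 2000, 0.5)
        assert lo <= k <= hi

    def test_angular_noise_has_requested_circular_spread(self):
        spec = GeneratorSpec(
            n_residues=6, n_frames=2000, recipes=(("d" * 6, 1.0),),
            sigma_deg=10.0, seed=2,
        )
        dih, _ = sample_dihedrals(spec)
        sd = stats.circstd(np.radians(dih.phi_deg[:, 3]), high=np.pi, low=-np.pi)
        assert np.degrees(sd) == pytest.approx(10.0, abs=1.0)

    def test_invalid_recipe_letter_rejected(self):
        with pytest.raises(ValueError):
            GeneratorSpec(n_residues=5, n_frames=1, recipes=(("mmmmz", 1.0),))


class TestBuildCoordinates:
    def test_round_trip_reproduces_torsions(self):
        rng = np.random.default_rng(3)
        n = 9
        phi = wrap_angle(rng.uniform(-180, 180, n))
        psi = wrap_angle(rng.uniform(-180, 180, n))
        phi[0] = np.nan
        psi[-1] = np.nan
        top, coords = build_coordinates(phi, psi)
        ens = StructureEnsemble(top, [Frame(coords, 100.0, "r1")])
        dih = backbone_dihedrals(ens)
        assert np.nanmax(np.abs(wrap_angle(dih.phi_deg[0] - phi))) < 1e-6
        assert np.nanmax(np.abs(wrap_angle(dih.psi_deg[0] - psi))) < 1e-6

    def test_extended_chain_calpha_spacing(self, pb_table):
        n = 8
        phi = np.full(n, pb_table.prototype("d")[3])
        psi = np.full(n, pb_table.prototype("d")[4])
        phi[0] = np.nan
        psi[-1] = np.nan
        top, coords = build_coordinates(phi, psi)
        ca = np.array([coords[i] for i, a in enumerate(top) if a.atom_name == "CA"])
        gaps = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.allclose(gaps, 3.80, atol=0.05)

    def test_helix_is_more_compact_than_extended(self, pb_table):
        n = 10
        builds = {}
        for letter in ("m", "d"):
            phi = np.full(n, pb_table.prototype(letter)[3])
            psi = np.full(n, pb_table.prototype(letter)[4])
            phi[0] = np.nan
            psi[-1] = np.nan
            top, coords = build_coordinates(phi, psi)
            ca = np.array([coords[i] for i, a in enumerate(top) if a.atom_name == "CA"])
            builds[letter] = np.linalg.norm(ca[2] - ca[5])
        assert builds["m"] < builds["d"]

    def test_chirality_is_l_amino_acid(self):
        from pbflex.geometry import dihedral_angle

        phi = np.array([np.nan, -60.0, -60.0])
        psi = np.array([-40.0, -40.0, np.nan])
        top, coords = build_coordinates(phi, psi)
        idx = {(a.residue_number, a.atom_name): i for i, a in enumerate(top)}
        improper = dihedral_angle(
            coords[idx[(2, "C")]], coords[idx[(2, "N")]],
            coords[idx[(2, "CA")]], coords[idx[(2, "CB")]],
        )
        assert improper == pytest.approx(GeometryConstants().torsion_cb, abs=1e-6)


class TestGenerateEnsemble:
    def test_same_seed_is_byte_identical(self):
        spec = GeneratorSpec(n_residues=7, n_frames=10, recipes=(("m" * 7, 1.0),),
                             sigma_deg=8.0, seed=42)
        a = generate_ensemble(spec)
        b = generate_ensemble(spec)
        assert a.coords.tobytes() == b.coords.tobytes()

    def test_frame_count_and_times(self):
        spec = GeneratorSpec(n_residues=6, n_frames=100, recipes=(("d" * 6, 1.0),), seed=0)
        ens = generate_ensemble(spec)
        assert ens.n_frames == 100
        assert ens.times_ps[0] == 100.0 and ens.times_ps[-1] == 10000.0

    def test_replica_layout_is_respected(self):
        spec = GeneratorSpec(
            n_residues=6, n_frames=10, recipes=(("d" * 6, 1.0),), seed=0,
            replica_layout=(("r1", 6), ("r2", 4)),
        )
        ens = generate_ensemble(spec)
        assert ens.replica_ids.count("r1") == 6
        assert ens.replica_ids.count("r2") == 4

    def test_noise_free_single_recipe_has_unit_neq(self, pb_table):
        spec = GeneratorSpec(n_residues=10, n_frames=20, recipes=(("m" * 10, 1.0),), seed=6)
        ens = generate_ensemble(spec)
        prof = neq_profile(pb_profile(assign_ensemble(backbone_dihedrals(ens), pb_table)))
        interior = prof.values[2:-2]
        assert np.allclose(interior, 1.0)

    def test_ground_truth_table_aligns_with_frames(self):
        spec = GeneratorSpec(n_residues=6, n_frames=8, recipes=(("d" * 6, 1.0),), seed=0)
        ens, truth = generate_ensemble(spec, return_ground_truth=True)
        assert len(truth) == ens.n_frames
        assert set(truth["true_pb"]) == {"d" * 6}


class TestNoiseMonotonicity:
    def test_expected_neq_never_drops_with_noise(self, pb_table):
        means = []
        for sigma in (0.0, 5.0, 10.0, 20.0):
            spec = GeneratorSpec(
                n_residues=9, n_frames=500, recipes=(("d" * 9, 1.0),),
                sigma_deg=sigma, seed=13,
            )
            ens = generate_ensemble(spec)
            prof = neq_profile(pb_profile(assign_ensemble(backbone_dihedrals(ens), pb_table)))
            means.append(np.nanmean(prof.values[2:-2]))
        assert all(b >= a - 0.05 for a, b in zip(means, means[1:]))


class TestVariantPair:
    def test_null_contrast_has_no_flags(self, pb_table):
        from pbflex.pb_alphabet import delta_neq

        flags = 0
        for seed in range(10):
            spec = GeneratorSpec(
                n_residues=15, n_frames=150, recipes=(("d" * 15, 1.0),),
                sigma_deg=5.0, variant_position=8, seed=seed,
            )
            ea, eb = generate_variant_pair(spec, (6, 10), extra_noise_sigma=0.0)
            na = neq_profile(pb_profile(assign_ensemble(backbone_dihedrals(ea), pb_table)))
            nb = neq_profile(pb_profile(assign_ensemble(backbone_dihedrals(eb), pb_table)))
            flags += len(delta_neq(na, nb).significant_residues())
        assert flags == 0

    def test_variant_types_differ_only_at_variant_position(self):
        spec = GeneratorSpec(
            n_residues=12, n_frames=5, recipes=(("d" * 12, 1.0),),
            variant_position=6, seed=3,
        )
        ea, eb = generate_variant_pair(spec, (5, 7), extra_noise_sigma=10.0)
        na, nb = ea.residue_names(), eb.residue_names()
        assert na[6] == "LEU" and nb[6] == "PRO"
        assert all(na[r] == nb[r] for r in na if r != 6)

    def test_alt_recipe_mixture_doubles_window_neq(self, pb_table):
        spec = GeneratorSpec(
            n_residues=15, n_frames=400, recipes=(("d" * 15, 1.0),),
            sigma_deg=0.0, variant_position=8, seed=21,
        )
        ea, eb = generate_variant_pair(
            spec, (6, 10), extra_noise_sigma=0.0, alt_recipe="mmmmm", alt_weight=0.5
        )
        na = neq_profile(pb_profile(assign_ensemble(backbone_dihedrals(ea), pb_table)))
        nb = neq_profile(pb_profile(assign_ensemble(backbone_dihedrals(eb), pb_table)))
        centre = list(na.residue_numbers).index(8)
        assert na.values[centre] == pytest.approx(1.0)
        assert nb.values[centre] == pytest.approx(2.0, rel=0.1)

    def test_perturbation_stays_local(self, pb_table):
        from pbflex.pb_alphabet import delta_neq

        hits = 0
        for seed in range(10):
            ea, eb, _ = two_variant_scenario(seed=seed, n_frames=250)
            na = neq_profile(pb_profile(assign_ensemble(backbone_dihedrals(ea), pb_table)))
            nb = neq_profile(pb_profile(assign_ensemble(backbone_dihedrals(eb), pb_table)))
            rep = delta_neq(na, nb)
            sig = np.array(rep.significant_residues())
            far = sig[(sig < 3) | (sig > 17)]
            hits += len(far) == 0
        assert hits >= 9
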