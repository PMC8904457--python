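import numpy as np
import pytest

import loopscan as ls
from loopscan.geometry import contact_frequency
from loopscan.structure import select_atoms
from loopscan.synthetic import (
    BackboneChain,
    ClosureError,
    IDEAL_GEOMETRY,
    LoopGeometrySpec,
    SyntheticEnsembleSpec,
    SyntheticKineticsSpec,
    _canonical_anchor_frame,
    build_ideal_backbone,
    ccd_close,
    dihedral,
    gen_kinetics,
    plant_contact_fraction,
    sample_loop_ensemble,
)
from loopscan.variants import DeletionWindow


def _bond_lengths(arr, res_ids=None):
    """All N-CA, CA-C bond lengths of a backbone AtomArray."""
    out = {}
    for rid in np.unique(arr.res_id):
        res = arr[arr.res_id == rid]
        def coord(name):
            return res.coord[res.atom_name == name][0].astype(float)
        out[(int(rid), "n_ca")] = float(np.linalg.norm(coord("CA") - coord("N")))
        out[(int(rid), "ca_c")] = float(np.linalg.norm(coord("C") - coord("CA")))
    return out


class TestBackboneBuilder:
    def test_single_residue_has_four_atoms_with_ideal_n_ca(self):
        arr = build_ideal_backbone("A")
        assert arr.array_length() == 5  # N, CA, C, O, CB
        n = arr.coord[arr.atom_name == "N"][0]
        ca = arr.coord[arr.atom_name == "CA"][0]
        assert np.linalg.norm(ca - n) == pytest.approx(1.458, abs=1e-6)

    def test_glycine_has_no_cb(self):
        arr = build_ideal_backbone("G")
        assert arr.array_length() == 4

    def test_eleven_residue_chain_atom_count(self):
        arr = build_ideal_backbone("QSRKVGDSPAA")
        # 4 backbone atoms per residue + CB for the 10 non-Gly residues
        backbone = arr[np.isin(arr.atom_name, ("N", "CA", "C", "O"))]
        assert backbone.array_length() == 44

    def test_every_bond_matches_ideal_geometry(self):
        arr = build_ideal_backbone("QSRKV")
        bonds = _bond_lengths(arr)
        for (rid, kind), length in bonds.items():
            assert length == pytest.approx(IDEAL_GEOMETRY[kind], abs=1e-6)
        # peptide C-N bonds between consecutive residues
        for rid in range(1, 5):
            c = arr.coord[(arr.res_id == rid) & (arr.atom_name == "C")][0]
            n = arr.coord[(arr.res_id == rid + 1) & (arr.atom_name == "N")][0]
            assert np.linalg.norm(n - c) == pytest.approx(
                IDEAL_GEOMETRY["c_n"], abs=1e-6
            )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            build_ideal_backbone("")
        with pytest.raises(ValueError):
            LoopGeometrySpec(sequence="")


class TestCCD:
    def _chain(self, n=11, seed=0, sigma=0.0):
        anchor = _canonical_anchor_frame(IDEAL_GEOMETRY)
        chain = BackboneChain(n, anchor)
        rng = np.random.default_rng(seed)
        torsions = rng.uniform(-180, 180, 2 * n + 1) if sigma == 0 else None
        if torsions is None:
            torsions = rng.uniform(-180, 180, 2 * n + 1)
        chain.rebuild(torsions)
        return chain

    def test_target_equal_to_current_anchor_converges_immediately(self):
        chain = self._chain(seed=1)
        target = chain.coords[chain.anchor_atom_indices].copy()
        closed, ok = ccd_close(chain, target, tol=0.01)
        assert ok
        assert closed.anchor_rmsd(target) < 1e-12

    def test_seeded_closure_success_rate(self):
        """>= 95% of 100 seeded perturbed 11-residue loops close to 0.1 A."""
        anchor = _canonical_anchor_frame(IDEAL_GEOMETRY)
        ref = BackboneChain(11, anchor)
        rng = np.random.default_rng(42)
        base = rng.uniform(-150, 150, ref.n_torsions)
        ref.rebuild(base)
        target = ref.coords[ref.anchor_atom_indices].copy()
        successes = 0
        for seed in range(100):
            rng_i = np.random.default_rng(1000 + seed)
            chain = BackboneChain(11, anchor)
            chain.rebuild(base + rng_i.normal(0, 25.0, base.size))
            _, ok = ccd_close(chain, target, tol=0.1)
            successes += bool(ok)
        assert successes >= 95

    def test_bond_geometry_invariant_under_closure(self):
        """Torsion-only moves: bond lengths and angles preserved to 1e-9."""
        chain = self._chain(seed=3)
        before = chain.bond_vectors().copy()
        coords_before = chain.coords.copy()
        target = coords_before[chain.anchor_atom_indices] + 1.0
        ccd_close(chain, target, tol=0.05)
        after = chain.bond_vectors()
        assert np.allclose(after, before, atol=1e-9)
        # bond angles via the law of cosines on consecutive bond vectors
        def angles(coords):
            v = np.diff(coords, axis=0)
            cos = (v[:-1] * v[1:]).sum(axis=1) / (
                np.linalg.norm(v[:-1], axis=1) * np.linalg.norm(v[1:], axis=1)
            )
            return np.arccos(np.clip(cos, -1, 1))
        # the chain moved, so compare angle magnitudes, not coordinates
        assert np.allclose(
            angles(chain.coords), angles(coords_before), atol=1e-9
        )
        assert not np.allclose(chain.coords, coords_before)

    def test_torsion_bookkeeping_consistent_after_closure(self):
        """Accumulated torsion deltas match the closed coordinates."""
        chain = self._chain(n=5, seed=7)
        target = chain.coords[chain.anchor_atom_indices] + np.array([1.0, -0.5, 0.5])
        closed, _ = ccd_close(chain, target, tol=0.05)
        coords = closed.coords.copy()
        closed.rebuild()  # rebuild from the stored torsions
        assert np.allclose(closed.coords, coords, atol=1e-6)


class TestEnsembleSampler:
    def test_default_spec_produces_requested_pose_count(self, loop_def, body):
        spec = SyntheticEnsembleSpec(n_poses=25, seed=5)
        ens, truth = sample_loop_ensemble(spec, loop_def, body=body)
        assert ens.n_poses == 25
        assert truth.rmsd_to_native.shape == (25,)

    def test_zero_perturbation_collapses_to_native(self, loop_def, body):
        spec = SyntheticEnsembleSpec(n_poses=5, dihedral_sigma_deg=0.0,
                                     score_noise=0.0, seed=6)
        ens, truth = sample_loop_ensemble(spec, loop_def, body=body)
        assert np.allclose(truth.rmsd_to_native, 0.0, atol=1e-5)
        assert np.allclose(ens.scores, 0.0, atol=1e-5)

    def test_same_seed_is_byte_identical(self, loop_def, body, tmp_path):
        spec = SyntheticEnsembleSpec(n_poses=8, seed=9)
        e1, _ = sample_loop_ensemble(spec, loop_def, body=body)
        e2, _ = sample_loop_ensemble(spec, loop_def, body=body)
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        ls.write_multimodel_pdb(e1, p1)
        ls.write_multimodel_pdb(e2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_variant_ensemble_omits_deleted_residues(self, loop_def, body, library):
        v = library.by_window(DeletionWindow(size=3, start=316))
        spec = SyntheticEnsembleSpec(n_poses=3, seed=4)
        ens, _ = sample_loop_ensemble(spec, loop_def, variant=v, body=body)
        res_ids = set(ens.stack.res_id.tolist())
        assert {316, 317, 318}.isdisjoint(res_ids)
        assert {311, 315, 319, 321} <= res_ids

    def test_generated_ensembles_pass_io_validation(self, loop_def, body, tmp_path):
        spec = SyntheticEnsembleSpec(n_poses=4, seed=12)
        ens, _ = sample_loop_ensemble(spec, loop_def, body=body)
        path = tmp_path / "v.pdb"
        ls.write_multimodel_pdb(ens, path)
        back = ls.read_ensemble(path, rebuild_span=loop_def.rebuild_span)
        assert back.n_poses == 4
        sel = select_atoms(back.pose(0), residues=loop_def.rebuild_span)
        assert sel.array_length() > 0

    def test_infeasible_tolerance_raises_closure_error(self, loop_def, body):
        spec = SyntheticEnsembleSpec(n_poses=5, closure_tol=1e-8, max_iter=3,
                                     seed=2)
        with pytest.raises(ClosureError, match="tolerance"):
            sample_loop_ensemble(spec, loop_def, body=body)

    def test_funnel_spearman_of_planted_energies(self, loop_def, body):
        spec = SyntheticEnsembleSpec(n_poses=100, seed=17)
        ens, truth = sample_loop_ensemble(spec, loop_def, body=body)
        assert ls.funnel(ens).spearman >= 0.9
        # clean scores are exactly slope * rmsd-to-native
        assert np.allclose(
            truth.scores_clean, spec.score_slope * truth.rmsd_to_native
        )


@pytest.fixture(scope="module")
def base_ensemble(loop_def, body):
    spec = SyntheticEnsembleSpec(n_poses=40, seed=3)
    ens, _ = sample_loop_ensemble(spec, loop_def, body=body)
    return ens


class TestPlantedContacts:
    PAIR = ((315, "N"), (372, "O"))

    def test_fraction_one_and_zero(self, base_ensemble):
        for f, expected in ((1.0, 1.0), (0.0, 0.0)):
            planted, mask = plant_contact_fraction(
                base_ensemble, self.PAIR, f, seed=1
            )
            series = ls.atom_distance_series(planted, *self.PAIR)
            assert contact_frequency(series) == expected
            assert mask.mean() == expected

    def test_estimator_equals_realized_bernoulli_exactly(self, base_ensemble):
        planted, mask = plant_contact_fraction(
            base_ensemble, self.PAIR, 0.4, seed=7
        )
        series = ls.atom_distance_series(planted, *self.PAIR)
        assert contact_frequency(series) == mask.mean()
        d = series.distances
        assert np.all(d[mask] < 3.4)
        assert np.all(d[~mask] > 4.5)

    def test_truth_record_updated(self, base_ensemble, loop_def, body):
        spec = SyntheticEnsembleSpec(n_poses=10, seed=8)
        ens, truth = sample_loop_ensemble(spec, loop_def, body=body)
        plant_contact_fraction(ens, self.PAIR, 0.5, seed=2, truth=truth)
        key = "315.N-372.O"
        assert key in truth.planted_contacts
        rec = truth.planted_contacts[key]
        assert rec["realized_fraction"] == np.mean(rec["contact_mask"])

    def test_invalid_fraction_rejected(self, base_ensemble):
        with pytest.raises(ValueError):
            plant_contact_fraction(base_ensemble, self.PAIR, 1.5, seed=0)


class TestKineticsGenerator:
    def test_zero_noise_equals_model_predictions(self):
        spec = SyntheticKineticsSpec(noise_sigma=0.0, seed=0)
        data = gen_kinetics(spec)
        mm = data["michaelis_menten"][0]
        vmax = spec.kcat_s * spec.enzyme_conc_nm
        expected = vmax * mm.x / (spec.km_mm + mm.x)
        assert np.allclose(mm.v, expected)
        prog = data["progress_curve"][0]
        assert np.allclose(
            prog.v, spec.progress_intercept + spec.progress_slope * prog.x
        )

    def test_same_seed_identical_datasets(self):
        d1 = gen_kinetics(SyntheticKineticsSpec(seed=5))
        d2 = gen_kinetics(SyntheticKineticsSpec(seed=5))
        for key in ("michaelis_menten", "competitive_ki", "binding_kd"):
            assert np.array_equal(d1[key][0].v, d2[key][0].v)

    def test_replicates_share_design_but_not_noise(self):
        data = gen_kinetics(SyntheticKineticsSpec(seed=3))
        a, b = data["michaelis_menten"]
        assert np.array_equal(a.x, b.x)
        assert not np.array_equal(a.v, b.v)

    def test_designs_match_study_conditions(self):
        spec = SyntheticKineticsSpec()
        assert max(spec.substrate_grid_mm) == 12.5
        assert max(spec.titrant_grid_um) == 3.0
        data = gen_kinetics(spec)
        assert data["competitive_ki"][0].metadata["s_fixed_mm"] == 1.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SyntheticKineticsSpec(km_mm=-1.0)
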