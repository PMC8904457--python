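import numpy as np
import pytest
import biotite.structure as bst
from biotite.structure import AtomArray

import loopscan as ls
from loopscan.geometry import vector_angle_deg, superpose_to_body
from loopscan.structure import ConformerEnsemble, Pose
from loopscan.synthetic import gaussian_ensemble
from loopscan.variants import DeletionWindow


def _atom_array(entries):
    """entries: list of (res_id, atom_name, xyz)"""
    arr = AtomArray(len(entries))
    arr.coord = np.array([e[2] for e in entries], dtype=np.float32)
    arr.res_id = np.array([e[0] for e in entries], dtype=int)
    arr.atom_name = np.array([e[1] for e in entries])
    arr.res_name = np.array(["GLY"] * len(entries))
    arr.chain_id = np.array(["A"] * len(entries))
    arr.element = np.array([e[1][0] for e in entries])
    arr.hetero = np.zeros(len(entries), dtype=bool)
    return arr


def _ensemble_from_coords(base, coord_list, scores=None):
    stacks = []
    for coords in coord_list:
        arr = base.copy()
        arr.coord = np.asarray(coords, dtype=np.float32)
        stacks.append(arr)
    if scores is None:
        scores = np.zeros(len(coord_list))
    return ConformerEnsemble(stack=bst.stack(stacks), scores=np.asarray(scores, float))


@pytest.fixture()
def tiny_base():
    return _atom_array(
        [
            (1, "N", (0.0, 0.0, 0.0)),
            (1, "CA", (1.5, 0.0, 0.0)),
            (2, "CA", (3.0, 0.0, 0.0)),
            (2, "O", (4.0, 1.0, 0.0)),
        ]
    )


class TestMeanAndRMSF:
    def test_mean_of_identical_poses_is_the_pose(self, tiny_base):
        ens = _ensemble_from_coords(tiny_base, [tiny_base.coord] * 5)
        mean = ls.geometric_mean(ens)
        assert np.allclose(mean.coords, tiny_base.coord, atol=1e-7)
        prof = ls.rmsf(ens)
        assert np.allclose(prof.per_atom, 0.0)

    def test_mean_of_two_poses_is_midpoint(self, tiny_base):
        c1 = tiny_base.coord.copy()
        c2 = tiny_base.coord.copy()
        c2[0] += np.array([2.0, 0.0, 0.0], dtype=np.float32)
        ens = _ensemble_from_coords(tiny_base, [c1, c2])
        mean = ls.geometric_mean(ens)
        assert np.allclose(mean.coords, (c1 + c2) / 2.0, atol=1e-7)

    def test_two_point_rmsf_is_half_displacement(self, tiny_base):
        c1 = tiny_base.coord.copy()
        c2 = tiny_base.coord.copy()
        d = 1.8
        c2[2, 2] += d
        ens = _ensemble_from_coords(tiny_base, [c1, c2])
        prof = ls.rmsf(ens)
        assert prof.per_atom[ens.atom_index(2, "CA")] == pytest.approx(d / 2)

    def test_rmsf_matches_brute_force(self):
        """Oracle: per-atom loop-free recomputation in float64."""
        ens = gaussian_ensemble(n_poses=50, sigma=0.7, seed=9)
        prof = ls.rmsf(ens)
        coords = ens.coords.astype(np.float64)
        expected = np.empty(ens.n_atoms)
        for a in range(ens.n_atoms):
            xs = coords[:, a, :]
            mu = xs.mean(axis=0)
            expected[a] = np.sqrt(((xs - mu) ** 2).sum(axis=1).mean())
        assert np.allclose(prof.per_atom, expected, rtol=1e-9, atol=0)
        assert prof.average == pytest.approx(expected.mean(), rel=1e-9)

    def test_gaussian_rmsf_approaches_sigma_sqrt3(self):
        sigma = 0.5
        ens = gaussian_ensemble(n_poses=250, sigma=sigma, seed=21)
        prof = ls.rmsf(ens)
        assert prof.average == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_mean_matches_brute_force(self):
        ens = gaussian_ensemble(n_poses=50, sigma=0.5, seed=3)
        mean = ls.geometric_mean(ens)
        coords = ens.coords.astype(np.float64)
        assert np.allclose(mean.coords, coords.mean(axis=0), rtol=1e-9, atol=1e-12)


class TestRMSD:
    def test_identical_poses_zero(self, tiny_base):
        ens = _ensemble_from_coords(tiny_base, [tiny_base.coord] * 2)
        assert ls.rmsd(ens.pose(0), ens.pose(1)) == 0.0

    def test_single_displaced_atom_closed_form(self, tiny_base):
        c2 = tiny_base.coord.copy()
        c2[1] += np.array([0.0, 3.0, 0.0], dtype=np.float32)
        ens = _ensemble_from_coords(tiny_base, [tiny_base.coord, c2])
        m = tiny_base.array_length()
        assert ls.rmsd(ens.pose(0), ens.pose(1)) == pytest.approx(
            3.0 / np.sqrt(m), rel=1e-6
        )

    def test_random_pair_matches_brute_force(self):
        ens = gaussian_ensemble(n_poses=2, sigma=1.0, seed=13)
        a = ens.coords[0].astype(np.float64)
        b = ens.coords[1].astype(np.float64)
        brute = np.sqrt(((a - b) ** 2).sum(axis=1).mean())
        assert ls.rmsd(ens.pose(0), ens.pose(1)) == pytest.approx(brute, rel=1e-9)

    def test_mismatched_selection_raises(self, tiny_base):
        other = _atom_array([(1, "N", (0, 0, 0)), (1, "CA", (1, 0, 0))])
        ens1 = _ensemble_from_coords(tiny_base, [tiny_base.coord])
        ens2 = _ensemble_from_coords(other, [other.coord])
        with pytest.raises(ValueError):
            ls.rmsd(ens1.pose(0), ens2.pose(0))


class TestFunnel:
    def test_reference_row_is_zero_and_rows_complete(self, wt_ensemble):
        ens, _ = wt_ensemble
        ftab = ls.funnel(ens)
        assert len(ftab.table) == ens.n_poses
        assert ftab.reference_pose == int(np.argmin(ens.scores))
        ref_row = ftab.table.loc[ftab.table["pose"] == ftab.reference_pose]
        assert ref_row["rmsd"].iloc[0] == 0.0
        assert (ftab.table["rmsd"] >= 0).all()

    def test_planted_energy_gives_high_spearman(self, wt_ensemble):
        ens, truth = wt_ensemble
        assert ls.funnel(ens).spearman >= 0.9

    def test_all_equal_scores_reference_is_pose_one(self, tiny_base):
        ens = _ensemble_from_coords(
            tiny_base, [tiny_base.coord] * 3, scores=[2.0, 2.0, 2.0]
        )
        assert ls.funnel(ens).reference_pose == 0

    def test_pose_permutation_leaves_summaries_unchanged(self, wt_ensemble):
        ens, _ = wt_ensemble
        rng = np.random.default_rng(0)
        perm = rng.permutation(ens.n_poses)
        permuted = ConformerEnsemble(
            stack=ens.stack[perm.tolist()],
            scores=ens.scores[perm],
            rebuild_span=ens.rebuild_span,
        )
        f1, f2 = ls.funnel(ens), ls.funnel(permuted)
        assert f1.spearman == pytest.approx(f2.spearman, rel=1e-9)
        assert np.sort(f1.table["rmsd"]) == pytest.approx(
            np.sort(f2.table["rmsd"]), rel=1e-6
        )
        r1 = ls.rmsf(ens).average
        r2 = ls.rmsf(permuted).average
        assert r1 == pytest.approx(r2, rel=1e-9)


class TestSelection:
    def test_select_low_energy(self, wt_ensemble):
        ens, _ = wt_ensemble
        ids = ls.select_low_energy(ens, 10)
        assert len(ids) == 10
        assert ids[0] == int(np.argmin(ens.scores))
        cutoff = np.sort(ens.scores)[9]
        assert all(ens.scores[i] <= cutoff + 1e-12 for i in ids)
        assert sorted(ls.select_low_energy(ens, ens.n_poses)) == list(
            range(ens.n_poses)
        )
        with pytest.raises(ValueError):
            ls.select_low_energy(ens, ens.n_poses + 1)

    def test_rmsd_groups_on_trimodal_ensemble(self, tiny_base):
        # three planted RMSD modes: 0, ~4 and ~8 A from the reference
        rng = np.random.default_rng(8)
        coord_list, scores = [], []
        for mode, offset in enumerate((0.0, 4.0, 8.0)):
            for k in range(6):
                c = tiny_base.coord.astype(float).copy()
                c += offset / np.sqrt(3)  # uniform shift: RMSD == offset
                c += rng.normal(0, 0.05, c.shape)
                coord_list.append(c)
                scores.append(mode * 1.0 + 0.1 * k)
        ens = _ensemble_from_coords(tiny_base, coord_list, scores=scores)
        groups = ls.rmsd_group_representatives(ens, n_groups=3, per_group=5)
        assert len(groups) == 3
        assert [len(g) for g in groups] == [5, 5, 5]
        rmsds = ls.funnel(ens).table["rmsd"].to_numpy()
        # each group's members fall in one RMSD mode
        for g, centre in zip(groups, (0.0, 4.0, 8.0)):
            assert np.allclose(rmsds[g], centre, atol=1.0)

    def test_single_group_takes_lowest_scores(self, wt_ensemble):
        ens, _ = wt_ensemble
        groups = ls.rmsd_group_representatives(
            ens, n_groups=1, per_group=ens.n_poses
        )
        assert sorted(groups[0]) == list(range(ens.n_poses))

    def test_identical_poses_collapse_to_one_group(self, tiny_base):
        ens = _ensemble_from_coords(
            tiny_base, [tiny_base.coord] * 6, scores=np.arange(6.0)
        )
        groups = ls.rmsd_group_representatives(ens, n_groups=3, per_group=2)
        assert len(groups) == 1
        assert groups[0] == [0, 1]


class TestDistancesAndContacts:
    def test_known_distance(self, tiny_base):
        coords = tiny_base.coord.astype(float).copy()
        coords[0] = (0, 0, 0)
        coords[3] = (0, 0, 4)
        ens = _ensemble_from_coords(tiny_base, [coords])
        series = ls.atom_distance_series(ens, (1, "N"), (2, "O"))
        assert series.distances[0] == pytest.approx(4.0, abs=1e-6)

    def test_unresolvable_atom_named_in_error(self, tiny_base):
        ens = _ensemble_from_coords(tiny_base, [tiny_base.coord])
        with pytest.raises(KeyError, match="9/CA"):
            ls.atom_distance_series(ens, (9, "CA"), (2, "O"))

    def test_hbond_summary_constant_series(self):
        s = ls.hbond_summary(np.full(100, 3.0))
        assert s.mean == pytest.approx(3.0)
        assert s.sd == 0.0
        assert s.stable
        assert s.in_range_frequency == 1.0
        assert s.hist_counts.sum() == 100

    def test_hbond_summary_out_of_window(self):
        far = ls.hbond_summary(np.full(50, 5.0))
        assert not far.stable
        assert far.in_range_frequency == 0.0
        # mean just above the stable window is classified unstable
        edge = ls.hbond_summary(np.full(50, 3.9))
        assert not edge.stable
        assert edge.in_range_frequency == 1.0  # still inside 2.5-4.0
        inside = ls.hbond_summary(np.full(50, 3.8))
        assert inside.stable

    def test_contact_frequency_strict_cutoff(self):
        assert ls.contact_frequency(np.full(10, 2.0)) == 1.0
        assert ls.contact_frequency(np.full(10, 3.5)) == 0.0  # strict <
        mixed = np.array([3.0, 3.0, 4.0, 4.0])
        assert ls.contact_frequency(mixed) == 0.5

    def test_frequencies_invariant_to_unrelated_atoms(self, tiny_base):
        coords = tiny_base.coord.astype(float).copy()
        ens1 = _ensemble_from_coords(tiny_base, [coords] * 4)
        s1 = ls.atom_distance_series(ens1, (1, "N"), (2, "O"))
        bigger = _atom_array(
            [(r, n, tuple(c)) for r, n, c in
             zip(tiny_base.res_id, tiny_base.atom_name, coords)]
            + [(5, "CA", (9.0, 9.0, 9.0))]
        )
        ens2 = _ensemble_from_coords(bigger, [bigger.coord] * 4)
        s2 = ls.atom_distance_series(ens2, (1, "N"), (2, "O"))
        assert ls.contact_frequency(s1) == ls.contact_frequency(s2)
        assert ls.hbond_summary(s1).in_range_frequency == \
            ls.hbond_summary(s2).in_range_frequency


class TestSlotResolution:
    def test_wild_type_identity(self, loop_def):
        assert ls.resolve_slot_residue(None, 315, loop_def) == 315

    def test_deletion_shifts_next_residue_into_slot(self, library, loop_def):
        v = library.by_window(DeletionWindow(size=2, start=315))
        assert ls.resolve_slot_residue(v, 315, loop_def) == 317

    def test_identity_when_window_is_c_terminal_of_slot(self, library, loop_def):
        v = library.by_window(DeletionWindow(size=3, start=319))
        assert ls.resolve_slot_residue(v, 315, loop_def) == 315

    def test_deep_deletion_keeps_downstream_residue_in_slot(self, library, loop_def):
        # the size-6 window at 313 moves D319 into the slot of Q313
        v = library.by_window(DeletionWindow(size=6, start=313))
        assert ls.resolve_slot_residue(v, 313, loop_def) == 319

    def test_slot_beyond_truncated_loop_returns_c_anchor(self, library, loop_def):
        v = library.by_window(DeletionWindow(size=6, start=313))
        assert ls.resolve_slot_residue(v, 321, loop_def) == 321
        assert ls.resolve_slot_residue(v, 319, loop_def) == 321

    def test_slot_outside_loop_raises(self, loop_def):
        with pytest.raises(ValueError, match="outside loop span"):
            ls.resolve_slot_residue(None, 400, loop_def)


class TestHelixAngle:
    @staticmethod
    def _pose_with_helix(base_b_xyz):
        entries = [(i, "CA", (0.0, 0.0, 1.5 * i)) for i in range(1, 6)]
        entries += [(10, "CA", (0.0, 0.0, 0.0)), (11, "CA", base_b_xyz)]
        return Pose(array=_atom_array(entries))

    def test_parallel_vectors_zero_degrees(self):
        pose = self._pose_with_helix((0.0, 0.0, 5.0))
        res = ls.helix_angle(pose, (1, 5), ((10, 10), {"CA"}), ((11, 11), {"CA"}))
        assert res.angle_deg == pytest.approx(0.0, abs=1e-6)

    def test_orthogonal_vectors_ninety_degrees(self):
        pose = self._pose_with_helix((5.0, 0.0, 0.0))
        res = ls.helix_angle(pose, (1, 5), ((10, 10), {"CA"}), ((11, 11), {"CA"}))
        assert res.angle_deg == pytest.approx(90.0, abs=1e-6)

    def test_oblique_angle(self):
        pose = self._pose_with_helix((3.0, 0.0, 3.0))
        res = ls.helix_angle(pose, (1, 5), ((10, 10), {"CA"}), ((11, 11), {"CA"}))
        assert res.angle_deg == pytest.approx(45.0, abs=1e-6)

    def test_antiparallel_is_180(self):
        pose = self._pose_with_helix((0.0, 0.0, -5.0))
        res = ls.helix_angle(pose, (1, 5), ((10, 10), {"CA"}), ((11, 11), {"CA"}))
        assert res.angle_deg == pytest.approx(180.0, abs=1e-6)

    def test_degenerate_base_raises(self):
        pose = self._pose_with_helix((0.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="degenerate"):
            ls.helix_angle(pose, (1, 5), ((10, 10), {"CA"}), ((11, 11), {"CA"}))

    def test_too_few_helix_atoms_raises(self):
        pose = self._pose_with_helix((1.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="need >= 3"):
            ls.helix_angle(pose, (1, 2), ((10, 10), {"CA"}), ((11, 11), {"CA"}))

    def test_vector_angle_helper(self):
        assert vector_angle_deg([1, 0, 0], [0, 1, 0]) == pytest.approx(90.0)
        assert vector_angle_deg([1, 1, 0], [1, 1, 0]) == pytest.approx(0.0, abs=1e-5)


def test_superpose_to_body_removes_rigid_motion(wt_ensemble):
    ens, _ = wt_ensemble
    rng = np.random.default_rng(4)
    moved = ens.stack.copy()
    for i in range(moved.stack_depth()):
        moved.coord[i] += rng.normal(0, 5.0, 3).astype(np.float32)
    shifted = ConformerEnsemble(
        stack=moved, scores=ens.scores.copy(), rebuild_span=ens.rebuild_span
    )
    refit = superpose_to_body(shifted, body_residues=(305, 310))
    body_rmsf = ls.rmsf(refit, residues=(305, 310)).average
    assert body_rmsf < 1e-3
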