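"""Dual-filter screening: ranking, pose consistency RMSD, H-bond filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from gagtk import glycan, screening, synthetic
from gagtk.screening import (
    Pose,
    PoseAtom,
    PoseSet,
    ScreenConfig,
    SiteDefinition,
    hbond_contacts,
    pose_consistency,
    rank_top_fraction,
    rmsd_pair,
    run_screen,
    surrogate_score,
)


def make_pose(coords, score=0.0, run_id=0, charge_class="sulfate_O", label="lig"):
    atoms = tuple(
        PoseAtom(name=f"A{i}", element="O", charge_class=charge_class, xyz=tuple(c))
        for i, c in enumerate(np.atleast_2d(coords))
    )
    return Pose(ligand_label=label, atoms=atoms, score=score, run_id=run_id)


class TestRankTopFraction:
    def test_254_at_ten_percent_keeps_25(self):
        scores = [(f"s{i:03d}", float(i)) for i in range(254)]
        assert len(rank_top_fraction(scores, 0.10)) == 25

    def test_fraction_one_returns_all(self):
        scores = [(f"s{i}", float(i)) for i in range(7)]
        assert sorted(rank_top_fraction(scores, 1.0)) == sorted(l for l, _ in scores)

    def test_sort_oracle(self):
        scores = [(f"s{i}", v) for i, v in enumerate([3, 9, 1, 7, 5, 8, 2, 6, 4, 0])]
        top = rank_top_fraction(scores, 0.30)
        expected = [l for l, _ in sorted(scores, key=lambda t: -t[1])[:3]]
        assert top == expected

    def test_selected_scores_dominate_excluded(self):
        rng = np.random.default_rng(0)
        scores = [(f"s{i:02d}", float(v)) for i, v in enumerate(rng.normal(size=40))]
        top = set(rank_top_fraction(scores, 0.25))
        selected = [v for l, v in scores if l in top]
        excluded = [v for l, v in scores if l not in top]
        assert min(selected) >= max(excluded)

    def test_ties_broken_lexicographically(self):
        scores = [("b", 1.0), ("a", 1.0), ("c", 1.0), ("d", 0.0)]
        assert rank_top_fraction(scores, 0.5) == ["a", "b"]

    def test_empty_and_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            rank_top_fraction([], 0.1)
        with pytest.raises(ValueError):
            rank_top_fraction([("a", 1.0), ("a", 2.0)], 0.5)


class TestRmsdPair:
    def test_identity_is_zero(self):
        coords = np.arange(12.0).reshape(4, 3)
        assert rmsd_pair(coords, coords) == 0.0

    def test_single_displaced_atom(self):
        a = np.zeros((4, 3))
        b = a.copy()
        b[0, 0] = 6.0
        assert rmsd_pair(a, b) == pytest.approx(3.0)

    def test_uniform_translation_equals_norm(self):
        a = np.arange(15.0).reshape(5, 3)
        b = a + np.array([1.0, 2.0, 2.0])
        assert rmsd_pair(a, b) == pytest.approx(3.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmsd_pair(np.zeros((3, 3)), np.zeros((4, 3)))

    @given(
        arrays(np.float64, (5, 3), elements=st.floats(-50, 50)),
        arrays(np.float64, (5, 3), elements=st.floats(-50, 50)),
    )
    @settings(deadline=None, max_examples=60)
    def test_matches_bruteforce_and_symmetry(self, a, b):
        brute = np.sqrt(
            np.mean([np.sum((a[i] - b[i]) ** 2) for i in range(len(a))])
        )
        assert rmsd_pair(a, b) == pytest.approx(brute, abs=1e-10)
        assert rmsd_pair(b, a) == pytest.approx(rmsd_pair(a, b))
        assert rmsd_pair(a, b) >= 0.0


class TestPoseConsistency:
    def test_identical_poses_are_specific(self):
        coords = np.arange(9.0).reshape(3, 3)
        poses = [make_pose(coords, score=float(i)) for i in range(6)]
        result = pose_consistency(PoseSet("lig", poses), ScreenConfig())
        assert result["rmsd"] == 0.0
        assert result["specific"] is True
        assert result["n_pairs"] == 15

    def test_stored_rmsd_below_threshold_is_specific(self):
        """A consistency RMSD like the published 1.23 A passes the 2.5 A rule."""
        base = np.zeros((4, 3))
        # poses alternating between two sub-positions 1.739 A apart ->
        # mean pairwise rmsd = (9 pairs cross * d + 6 pairs zero)/15 ~ 1.04 d
        shift = np.array([1.739, 0.0, 0.0])
        poses = [
            make_pose(base + (shift if i % 2 else 0.0), score=float(i))
            for i in range(6)
        ]
        result = pose_consistency(PoseSet("lig", poses), ScreenConfig())
        assert 0 < result["rmsd"] < 2.5
        assert result["specific"] is True

    def test_two_distant_clusters_not_specific(self):
        """Two tight 3-pose clusters 10 A apart fail the 2.5 A consistency rule."""
        base = np.zeros((4, 3))
        far = base + np.array([10.0, 0.0, 0.0])
        poses = [make_pose(base, score=float(i)) for i in range(3)] + [
            make_pose(far, score=float(3 + i)) for i in range(3)
        ]
        # brute-force all-pairs oracle: 9 cross pairs at 10 A, 6 at 0
        expected = 9 * 10.0 / 15
        result = pose_consistency(PoseSet("lig", poses), ScreenConfig())
        assert result["rmsd"] == pytest.approx(expected)
        assert result["specific"] is False

    def test_order_invariance(self, rng):
        poses = [
            make_pose(rng.normal(size=(5, 3)), score=float(i)) for i in range(8)
        ]
        cfg = ScreenConfig()
        ref = pose_consistency(PoseSet("lig", poses), cfg)
        perm = [poses[i] for i in rng.permutation(len(poses))]
        assert pose_consistency(PoseSet("lig", perm), cfg) == ref

    def test_rmsd_monotone_in_spread(self):
        template = np.zeros((6, 3))
        rmsds = []
        for sigma in (0.1, 1.0, 5.0):
            pose_set = synthetic.gen_pose_cloud(
                template, sigma, n_runs=3, poses_per_run=6, seed=42
            )
            rmsds.append(pose_consistency(pose_set, ScreenConfig())["rmsd"])
        assert rmsds[0] < rmsds[1] < rmsds[2]

    def test_too_few_poses_rejected(self):
        poses = [make_pose(np.zeros((3, 3)), score=float(i)) for i in range(4)]
        with pytest.raises(ValueError, match="at least 6"):
            pose_consistency(PoseSet("lig", poses), ScreenConfig())

    def test_atom_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="atom count"):
            PoseSet("lig", [make_pose(np.zeros((3, 3))), make_pose(np.zeros((4, 3)))])


class TestHbondContacts:
    def test_close_sulfate_counts(self, cluster1_site):
        pose = make_pose([[0.0, 0.0, 0.0]])
        contacts = hbond_contacts(
            pose, cluster1_site, [("R64", (2.9, 0.0, 0.0))], distance_cutoff=3.5
        )
        assert contacts == [("R64", 1)]

    def test_no_anionic_atoms_no_contacts(self, cluster1_site):
        pose = make_pose([[0.0, 0.0, 0.0]], charge_class="ring")
        assert hbond_contacts(pose, cluster1_site, [("R64", (0.5, 0, 0))]) == []

    def test_beyond_cutoff_excluded(self, cluster1_site):
        pose = make_pose([[0.0, 0.0, 0.0]])
        assert (
            hbond_contacts(
                pose, cluster1_site, [("R64", (5.0, 0, 0))], distance_cutoff=3.5
            )
            == []
        )

    def test_empty_protein_list_rejected(self, cluster1_site):
        with pytest.raises(ValueError, match="empty"):
            hbond_contacts(make_pose([[0, 0, 0]]), cluster1_site, [])


class TestSurrogateScore:
    def test_no_anionic_atoms_scores_zero(self, cluster1_site, cluster1_basic_atoms):
        pose = make_pose([[0, 0, 0]], charge_class="ring")
        assert surrogate_score(pose, cluster1_site, cluster1_basic_atoms) == 0.0

    def test_single_pair_closed_form(self, cluster1_site):
        pose = make_pose([[1.0, 0.0, 0.0]])
        assert surrogate_score(pose, cluster1_site, [("R64", (2.0, 0, 0))]) == 0.5

    def test_translation_away_lowers_score(self, cluster1_site, cluster1_basic_atoms):
        near = make_pose([[0.5, 0.0, 0.0]])
        far = make_pose([[2.5, 0.0, 0.0]])
        s_near = surrogate_score(near, cluster1_site, cluster1_basic_atoms)
        s_far = surrogate_score(far, cluster1_site, cluster1_basic_atoms)
        assert s_far < s_near


class TestRunScreen:
    def test_top_fraction_reaches_consistency_stage(
        self, toy_library, cluster1_site, cluster1_basic_atoms
    ):
        lib = toy_library[:20]
        backend = synthetic.SurrogateDockingBackend(cluster1_basic_atoms, 0.3)
        report = run_screen(
            lib, backend, cluster1_site, ScreenConfig(top_fraction=0.10),
            protein_polar_atoms=cluster1_basic_atoms, seed=3,
        )
        assert sum(r.ranked for r in report.records) == 2  # round(20*0.1)

    def test_tight_backend_all_specific(
        self, toy_library, cluster1_site, cluster1_basic_atoms
    ):
        backend = synthetic.SurrogateDockingBackend(cluster1_basic_atoms, 0.0)
        report = run_screen(
            toy_library[:10], backend, cluster1_site, ScreenConfig(),
            protein_polar_atoms=cluster1_basic_atoms, seed=0,
        )
        ranked = [r for r in report.records if r.ranked]
        assert ranked and all(r.specific for r in ranked)
        assert all(r.rmsd == pytest.approx(0.0) for r in ranked)

    def test_wide_spread_yields_no_specific(
        self, toy_library, cluster1_site, cluster1_basic_atoms
    ):
        backend = synthetic.SurrogateDockingBackend(cluster1_basic_atoms, 5.0)
        report = run_screen(
            toy_library[:10], backend, cluster1_site, ScreenConfig(),
            protein_polar_atoms=cluster1_basic_atoms, seed=0,
        )
        ranked = [r for r in report.records if r.ranked]
        assert ranked and not any(r.specific for r in ranked)

    def test_report_byte_identical_across_runs(
        self, toy_library, cluster1_site, cluster1_basic_atoms
    ):
        backend = synthetic.SurrogateDockingBackend(cluster1_basic_atoms, 0.5)
        kwargs = dict(
            backend=backend, site=cluster1_site, config=ScreenConfig(),
            protein_polar_atoms=cluster1_basic_atoms, seed=11,
        )
        a = run_screen(toy_library[:12], **kwargs).to_json()
        b = run_screen(toy_library[:12], **kwargs).to_json()
        assert a == b

    def test_backend_failure_recorded_not_fatal(
        self, toy_library, cluster1_site, cluster1_basic_atoms
    ):
        lib = toy_library[:10]
        bad = lib[0].label
        backend = synthetic.SurrogateDockingBackend(
            cluster1_basic_atoms, 0.3, fail_labels=[bad]
        )
        report = run_screen(
            lib, backend, cluster1_site, ScreenConfig(),
            protein_polar_atoms=cluster1_basic_atoms, seed=0,
        )
        rec = next(r for r in report.records if r.label == bad)
        assert rec.error is not None and not rec.shortlisted
        assert sum(r.error is None for r in report.records) == 9


class TestPoseIO:
    def test_csv_roundtrip(self, tmp_path, rng):
        poses = [
            make_pose(rng.normal(size=(4, 3)), score=float(i), run_id=i % 2)
            for i in range(6)
        ]
        pose_set = PoseSet("lig", poses)
        path = tmp_path / "poses.csv"
        screening.poses_to_csv(pose_set, path)
        back = screening.poses_from_csv(path)
        assert len(back.poses) == 6
        orig_coords = sorted(
            (p.run_id, p.score, tuple(map(tuple, np.round(p.coords, 6))))
            for p in poses
        )
        back_coords = sorted(
            (p.run_id, p.score, tuple(map(tuple, np.round(p.coords, 6))))
            for p in back.poses
        )
        assert orig_coords == back_coords
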