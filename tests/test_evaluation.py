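"""CAPRI metrics, superposition, pose clustering and ranking."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import footprintdock as fd
from footprintdock.evaluation import (
    DockPose,
    EvaluationResult,
    PoseCluster,
    pairwise_pose_rmsd,
    read_scores,
)
from footprintdock.patchup import Patch
from footprintdock.structure import Atom, Chain, Residue, Structure
from footprintdock.synthetic import _copy_chain, _transform_chain


def rigid(structure, R, t):
    return Structure(
        structure.id, [_transform_chain(c, R, np.asarray(t, float)) for c in structure.chains]
    )


def translate_ligand(complex_structure, shift):
    return Structure(
        "moved",
        [
            _copy_chain(complex_structure.chains[0]),
            _transform_chain(
                complex_structure.chains[1], np.eye(3), np.asarray(shift, float)
            ),
        ],
    )


class TestKabsch:
    def test_identity_on_identical_coordinates(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        R, t, rmsd = fd.kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_random_rigid_transform(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(15, 3))
        R_true = Rotation.random(rng=rng).as_matrix()
        moved = pts @ R_true.T + rng.normal(size=3)
        R, t, rmsd = fd.kabsch_superpose(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_quarter_turn_about_z(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        Rz = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], float)
        _, _, rmsd = fd.kabsch_superpose(pts, pts @ Rz.T)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_agrees_with_scipy_align_vectors(self):
        """Independent optimal-rotation route gives the same residual."""
        rng = np.random.default_rng(7)
        P = rng.normal(size=(20, 3))
        Q = rng.normal(size=(20, 3))
        _, _, ours = fd.kabsch_superpose(P, Q)
        rot, ssd = Rotation.align_vectors(
            Q - Q.mean(0), P - P.mean(0), return_sensitivity=False
        )
        aligned = rot.apply(P - P.mean(0))
        scipy_rmsd = np.sqrt(np.mean(np.sum((aligned - (Q - Q.mean(0))) ** 2, axis=1)))
        assert ours == pytest.approx(scipy_rmsd, abs=1e-8)

    def test_degenerate_inputs_error(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError, match="degenerate|collinear"):
            fd.kabsch_superpose(line, line)
        with pytest.raises(ValueError, match="3"):
            fd.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


def two_residue_complex(separation):
    """One-residue chains A and B, CB atoms ``separation`` Å apart."""
    a = Chain("A", [Residue(1, "ALA", [Atom("CB", "C", np.zeros(3))])])
    b = Chain("B", [Residue(1, "ALA", [Atom("CB", "C", np.array([separation, 0.0, 0.0]))])])
    return Structure("pair", [a, b])


class TestInterfaceResidues:
    def test_close_pair_both_in_interface(self):
        iface = fd.interface_residues(two_residue_complex(5.0))
        assert iface == {"A": {1}, "B": {1}}

    def test_distant_pair_empty(self):
        iface = fd.interface_residues(two_residue_complex(12.0))
        assert iface == {"A": set(), "B": set()}

    def test_cutoff_monotonicity(self, toy):
        small = fd.interface_residues(toy.complex, cutoff=5.0)
        large = fd.interface_residues(toy.complex, cutoff=10.0)
        for chain in ("A", "B"):
            assert small[chain] <= large[chain]

    def test_single_chain_errors(self, toy):
        with pytest.raises(ValueError):
            fd.interface_residues(toy.receptor)


class TestMetrics:
    def test_model_equals_reference(self, toy):
        r = fd.evaluate_model(toy.complex, toy.complex)
        assert r.irmsd == pytest.approx(0.0, abs=1e-9)
        assert r.lrmsd == pytest.approx(0.0, abs=1e-9)
        assert r.fnat == 1.0

    def test_lrmsd_of_uniform_ligand_translation(self, toy):
        moved = translate_ligand(toy.complex, [5.0, 0.0, 0.0])
        assert fd.lrmsd(moved, toy.complex) == pytest.approx(5.0, abs=1e-3)

    def test_irmsd_of_translated_ligand_matches_oracle(self, toy):
        """Brute-force oracle: build interface atom sets directly and
        superpose with scipy, independent of the irmsd code path."""
        moved = translate_ligand(toy.complex, [0.0, 2.0, 0.0])
        got = fd.irmsd(moved, toy.complex)

        iface = fd.interface_residues(toy.complex, 10.0)
        ref = np.vstack(
            [toy.complex.chain(c).backbone_coords(sorted(iface[c])) for c in sorted(iface)]
        )
        mod = np.vstack(
            [moved.chain(c).backbone_coords(sorted(iface[c])) for c in sorted(iface)]
        )
        rot, _ = Rotation.align_vectors(ref - ref.mean(0), mod - mod.mean(0))
        oracle = np.sqrt(
            np.mean(np.sum((rot.apply(mod - mod.mean(0)) - (ref - ref.mean(0))) ** 2, axis=1))
        )
        assert got == pytest.approx(oracle, abs=1e-6)
        assert 0 < got < 2.0  # superposition absorbs part of the 2 Å shift

    def test_lrmsd_rotation_matches_oracle(self, toy):
        """Ligand rotated about its centroid: receptor fit is identity, so
        the lRMSD equals the direct RMSD of the rotated ligand backbone."""
        lig = toy.complex.chains[1]
        centroid = lig.heavy_coords().mean(axis=0)
        R = Rotation.from_euler("z", 25, degrees=True).as_matrix()
        moved = Structure(
            "rot",
            [
                _copy_chain(toy.complex.chains[0]),
                _transform_chain(lig, R, centroid - R @ centroid),
            ],
        )
        bb = lig.backbone_coords()
        oracle = np.sqrt(
            np.mean(np.sum(((bb - centroid) @ R.T + centroid - bb) ** 2, axis=1))
        )
        assert fd.lrmsd(moved, toy.complex) == pytest.approx(oracle, abs=1e-6)

    def test_fnat_counts_preserved_contacts(self):
        """Four reference contacts, model preserves two -> fnat = 0.5."""
        def cplx(b_positions):
            a = Chain(
                "A",
                [
                    Residue(i + 1, "ALA", [Atom("CB", "C", np.array([0.0, 8.0 * i, 0.0]))])
                    for i in range(4)
                ],
            )
            b = Chain(
                "B",
                [
                    Residue(i + 1, "ALA", [Atom("CB", "C", np.array(p))])
                    for i, p in enumerate(b_positions)
                ],
            )
            return Structure("c", [a, b])

        reference = cplx([[4.0, 8.0 * i, 0.0] for i in range(4)])
        model = cplx(
            [[4.0, 0.0, 0.0], [4.0, 8.0, 0.0], [50.0, 16.0, 0.0], [50.0, 24.0, 0.0]]
        )
        assert fd.fnat(reference, reference) == 1.0
        assert fd.fnat(model, reference) == 0.5

    def test_fnat_zero_on_opposite_face(self, toy):
        moved = translate_ligand(toy.complex, [-18.0, 0.0, 0.0])
        assert fd.fnat(moved, toy.complex) == 0.0

    def test_metrics_invariant_under_common_rigid_transform(self, toy):
        moved = translate_ligand(toy.complex, [1.0, 2.0, 0.5])
        base = fd.evaluate_model(moved, toy.complex)
        R = Rotation.from_euler("xyz", [10, 70, -30], degrees=True).as_matrix()
        t = np.array([3.0, -8.0, 12.0])
        got = fd.evaluate_model(rigid(moved, R, t), rigid(toy.complex, R, t))
        assert got.irmsd == pytest.approx(base.irmsd, abs=1e-6)
        assert got.lrmsd == pytest.approx(base.lrmsd, abs=1e-6)
        assert got.fnat == pytest.approx(base.fnat)


class TestCapriClass:
    @pytest.mark.parametrize(
        "metrics,expected",
        [
            ((2.85, 7.76, 0.124), "acceptable"),
            ((5.0, 7.0, 0.2), "not_acceptable"),
            ((4.0, 9.0, 0.2), "not_acceptable"),  # strict 'below'
            ((2.0, 10.0, 0.2), "not_acceptable"),
            ((2.0, 9.0, 0.1), "not_acceptable"),  # strict 'larger than'
            ((3.99, 9.99, 0.101), "acceptable"),
        ],
    )
    def test_strict_thresholds(self, metrics, expected):
        assert fd.capri_class(EvaluationResult(*metrics)) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fd.capri_class(EvaluationResult(np.nan, 1.0, 0.5))


def scored_pose(score, i=0):
    return DockPose(Structure(f"s{i}", []), score=score, id=f"s{i}")


def daura_oracle(D, cutoff):
    """All partitions reachable by greedy largest-neighbourhood clustering
    when every tie in the centre choice is explored (exhaustive)."""
    D = np.asarray(D)

    def step(remaining):
        if not remaining:
            return [[]]
        idx = list(remaining)
        counts = {i: sum(D[i, j] <= cutoff for j in idx) for i in idx}
        best = max(counts.values())
        results = []
        for center in [i for i in idx if counts[i] == best]:
            members = frozenset(j for j in idx if D[center, j] <= cutoff)
            rest = remaining - members
            for tail in step(rest):
                results.append([members] + tail)
        return results

    return {frozenset(p) for p in step(frozenset(range(len(D))))}


class TestClusterPoses:
    def _poses(self, n):
        return [scored_pose(-50.0 + i, i) for i in range(n)]

    def test_identical_poses_form_one_cluster(self):
        D = np.zeros((5, 5))
        clusters = fd.cluster_poses(self._poses(5), rmsd_matrix=D)
        assert len(clusters) == 1 and clusters[0].size == 5

    def test_min_size_discards_small_groups(self):
        """Three identical poses among mutually distant ones: no cluster."""
        n = 13
        D = np.full((n, n), 50.0)
        np.fill_diagonal(D, 0.0)
        D[np.ix_([0, 1, 2], [0, 1, 2])] = 0.0
        assert fd.cluster_poses(self._poses(n), rmsd_matrix=D) == []

    def test_two_tight_groups(self):
        n = 8
        D = np.full((n, n), 40.0)
        for group in ([0, 1, 2, 3], [4, 5, 6, 7]):
            D[np.ix_(group, group)] = 1.0
        np.fill_diagonal(D, 0.0)
        clusters = fd.cluster_poses(self._poses(n), rmsd_matrix=D)
        assert sorted(c.size for c in clusters) == [4, 4]

    def test_clusters_are_disjoint(self):
        rng = np.random.default_rng(5)
        n = 12
        X = rng.normal(scale=6.0, size=(n, 2))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        clusters = fd.cluster_poses(self._poses(n), cutoff=7.5, min_size=2, rmsd_matrix=D)
        ids = [p.id for c in clusters for p in c.members]
        assert len(ids) == len(set(ids))

    def test_members_within_cutoff_of_center(self):
        rng = np.random.default_rng(9)
        n = 10
        X = rng.normal(scale=5.0, size=(n, 2))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        poses = self._poses(n)
        for c in fd.cluster_poses(poses, cutoff=6.0, min_size=2, rmsd_matrix=D):
            center_i = int(c.center.id[1:])
            for m in c.members:
                assert D[center_i, int(m.id[1:])] <= 6.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_daura_oracle(self, seed):
        """On ≤6-pose sets the greedy result is one of the exhaustive
        tie-exploration outcomes."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        X = rng.normal(scale=5.0, size=(n, 2))
        D = np.round(np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1)), 3)
        clusters = fd.cluster_poses(
            self._poses(n), cutoff=6.0, min_size=1, rmsd_matrix=D
        )
        got = frozenset(
            frozenset(int(p.id[1:]) for p in c.members) for c in clusters
        )
        assert got in daura_oracle(D, 6.0)

    def test_pairwise_metric_zero_for_identical_poses(self, toy):
        assert pairwise_pose_rmsd(toy.complex, toy.complex) == pytest.approx(0.0, abs=1e-9)

    def test_no_poses_errors(self):
        with pytest.raises(ValueError):
            fd.cluster_poses([])


class TestRankClusters:
    def _cluster(self, member_scores, start=0):
        return PoseCluster([scored_pose(s, start + i) for i, s in enumerate(member_scores)])

    def test_score_is_mean_of_four_lowest(self):
        c = self._cluster([-100, -90, -80, -70, -10])
        assert c.score == pytest.approx(-85.0)

    def test_orders_by_score_ascending(self):
        clusters = [
            self._cluster([-73.6] * 4, 0),
            self._cluster([-80.0] * 4, 10),
            self._cluster([-73.4] * 4, 20),
        ]
        ranked = fd.rank_clusters(clusters)
        assert [round(c.score, 1) for c in ranked] == [-80.0, -73.6, -73.4]
        assert [c.rank for c in ranked] == [1, 2, 3]

    def test_tie_broken_by_larger_size(self):
        small = self._cluster([-50.0] * 5, 0)
        large = self._cluster([-50.0] * 44, 100)
        ranked = fd.rank_clusters([small, large])
        assert ranked[0].size == 44

    def test_stable_under_permutation(self):
        clusters = [self._cluster([s] * 4, 10 * i) for i, s in enumerate((-10, -40, -20, -30))]
        a = [c.score for c in fd.rank_clusters(clusters)]
        b = [c.score for c in fd.rank_clusters(clusters[::-1])]
        assert a == b

    def test_missing_score_disables_ranking(self):
        c = PoseCluster([scored_pose(-1.0, 0), DockPose(Structure("x", []), None, "x")])
        with pytest.raises(ValueError, match="score"):
            fd.rank_clusters([c])


class TestPatchDistance:
    def test_constructed_distance(self, toy):
        patch = Patch(1, frozenset({5}), (0, 0, 0), 5)
        pose = DockPose(toy.complex, score=0.0)
        got = fd.patch_distance(pose, patch, "B")
        rec = toy.complex.chain("A").residue(5).heavy_coords()
        lig = toy.complex.chain("B").heavy_coords()
        oracle = np.min(np.linalg.norm(rec[:, None] - lig[None], axis=2))
        assert got == pytest.approx(oracle, abs=1e-9)

    def test_opposite_face_is_far(self, toy):
        moved = translate_ligand(toy.complex, [-32.0, 0.0, 0.0])
        patch = Patch(1, frozenset({14, 15, 16}), (0, 0, 0), 15)
        assert fd.patch_distance(DockPose(moved, 0.0), patch, "B") > 10.0

    def test_empty_patch_unconstructible(self):
        with pytest.raises(ValueError):
            Patch(1, frozenset(), (0, 0, 0), 0)

    def test_missing_chain_errors(self, toy):
        patch = Patch(1, frozenset({5}), (0, 0, 0), 5)
        with pytest.raises(KeyError):
            fd.patch_distance(DockPose(toy.complex, 0.0), patch, "Z")


def test_score_sidecar_reader(tmp_path):
    f = tmp_path / "scores.tsv"
    f.write_text("# model score\nmodel_1\t-80.0\nmodel_2 -73.6\n")
    assert read_scores(f) == {"model_1": -80.0, "model_2": -73.6}
    f.write_text("model_1\n")
    with pytest.raises(ValueError):
        read_scores(f)
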