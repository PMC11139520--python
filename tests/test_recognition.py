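"""Point matching and identity assignment."""

import itertools

import numpy as np
import numpy.testing as npt
import pytest
from scipy.spatial import cKDTree

from cellasr.recognition import (
    RecognitionConfig,
    extract_centroids,
    hard_assignment,
    map_subject,
    pca_align,
    recognize,
    refine_bipartite,
    rpm_match,
    spv_similarity,
    tsv_similarity,
    _prior_matrices,
)
from cellasr.atlas import shape_contexts_all
from cellasr.synthetic import PointSet, WormConfig, make_synthetic_worm


class TestCentroids:
    def test_cube_centroid(self):
        mask = np.zeros((11, 11, 11), int)
        mask[4:7, 4:7, 4:7] = 1
        ps, labels = extract_centroids(mask)
        npt.assert_allclose(ps.points[0], [5, 5, 5])  # (x, y, z)
        assert labels == [1]

    def test_two_instances_two_centroids_ordered_by_label(self):
        mask = np.zeros((8, 8, 8), int)
        mask[1, 1, 1] = 2
        mask[5, 5, 5] = 1
        ps, labels = extract_centroids(mask)
        assert labels == [1, 2]
        npt.assert_allclose(ps.points[0], [5, 5, 5])
        npt.assert_allclose(ps.points[1], [1, 1, 1])

    def test_matches_brute_force_mean(self, rng):
        mask = (rng.random((6, 6, 6)) > 0.7).astype(int) * 3
        if not mask.any():
            mask[0, 0, 0] = 3
        ps, labels = extract_centroids(mask)
        zyx = np.argwhere(mask == 3).mean(axis=0)
        npt.assert_allclose(ps.points[0], zyx[::-1])

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            extract_centroids(np.zeros((3, 3, 3), int))


class TestPcaAlign:
    def test_self_alignment_near_identity_chamfer(self, worm_template):
        tf = pca_align(worm_template, worm_template)
        npt.assert_allclose(tf.apply(worm_template.points), worm_template.points, atol=1e-6)

    def test_rotated_scaled_recovery(self, worm_template, rng):
        theta = 0.7
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1.0],
        ])
        subject = PointSet(worm_template.points @ rot.T * 1.4 + 5.0)
        tf = pca_align(subject, worm_template)
        npt.assert_allclose(tf.apply(subject.points), worm_template.points, atol=1e-6)

    def test_proper_rotations_only(self, worm_template):
        mirrored = worm_template.points * np.array([1, 1, -1.0])
        tf = pca_align(PointSet(mirrored), worm_template)
        assert np.linalg.det(tf.matrix) > 0


class TestHardAssignment:
    @pytest.mark.parametrize("n", [3, 5, 7])
    def test_equals_exhaustive_minimum_cost(self, n, rng):
        for _ in range(20):
            f = rng.random((n, n)) + 1e-6
            pairs = hard_assignment(f)
            cost = -np.log(f)
            best = min(
                (sum(cost[i, p] for i, p in enumerate(perm)), perm)
                for perm in itertools.permutations(range(n))
            )[1]
            assert pairs == [(i, best[i]) for i in range(n)]

    def test_rectangular_leaves_extras_unmatched(self, rng):
        f = rng.random((3, 5)) + 1e-6
        pairs = hard_assignment(f)
        assert len(pairs) == 3
        assert len({m for _, m in pairs}) == 3


class TestSimilarities:
    def test_spv_identity_is_one(self):
        assert spv_similarity(np.zeros(3), np.zeros(3), np.ones(3)) == 1.0

    def test_spv_one_sigma_offset(self):
        s = np.array([1.0, 2.0, 3.0])
        assert spv_similarity(s, np.zeros(3), s, omega=1.0) == pytest.approx(np.exp(-1.5))

    def test_tsv_zero_distance_is_one(self):
        assert tsv_similarity(0.0, 0.5) == 1.0
        assert 0 < tsv_similarity(0.3, 0.5) < 1


class TestRpm:
    def test_identical_sets_identity_permutation(self, worm_template, worm_atlas):
        ps = worm_atlas.pointset
        state = rpm_match(ps, ps, worm_atlas.sc_ref, RecognitionConfig())
        assert state.correspondences == [(n, n) for n in range(len(ps))]

    def test_beta_infinite_reduces_to_pure_spatial_rpm(self, rng):
        pts = rng.uniform(0, 60, (10, 3))
        target = PointSet(pts)
        subject = PointSet(pts + rng.normal(0, 0.3, pts.shape))
        sc = shape_contexts_all(target.points)
        cfg_spatial = RecognitionConfig(beta0=np.inf)
        a = rpm_match(subject, target, sc, cfg_spatial)
        b = rpm_match(subject, target, None, RecognitionConfig())
        assert a.correspondences == b.correspondences

    def test_permuted_noisy_target_matches_assignment_oracle(self, rng):
        pts = rng.uniform(0, 80, (8, 3))
        perm = rng.permutation(8)
        subject = PointSet(pts[perm] + rng.normal(0, 0.05, (8, 3)))
        state = rpm_match(subject, PointSet(pts), None, RecognitionConfig())
        # the final hard matching must equal the brute-force minimum-cost
        # assignment over -log f of the final similarity matrix
        cost = -np.log(np.maximum(state.soft, 1e-300))
        best_cost = min(
            sum(cost[i, p] for i, p in enumerate(perm2))
            for perm2 in itertools.permutations(range(8))
        )
        got = sum(cost[i, m] for i, m in state.correspondences)
        assert got == pytest.approx(best_cost, rel=1e-12)


class TestMapSubject:
    def test_affine_related_sets_mapped_exactly(self, worm_template, rng):
        a = np.eye(3) * 1.2
        subject = PointSet(worm_template.points @ a.T + 4.0)
        corr = [(n, n) for n in range(len(subject))]
        mapped = map_subject(subject, corr, worm_template)
        npt.assert_allclose(mapped, worm_template.points, atol=1e-6)

    def test_empty_correspondences_raise(self, worm_template):
        with pytest.raises(ValueError):
            map_subject(worm_template, [], worm_template)


class TestRefineBipartite:
    def test_identical_informative_matrices_full_consensus(self, worm_atlas):
        mapped = worm_atlas.asp.copy()
        sc = shape_contexts_all(mapped, worm_atlas.sc_params)
        pairs = refine_bipartite(mapped, sc, worm_atlas, RecognitionConfig())
        assert pairs == [(n, n) for n in range(len(worm_atlas.ids))]

    def test_consensus_is_intersection_of_solutions(self, worm_atlas):
        mapped = worm_atlas.asp.copy()
        sc = shape_contexts_all(mapped, worm_atlas.sc_params)
        cfg = RecognitionConfig()
        from cellasr.recognition import hard_assignment as ha

        f_spv, f_tsv = _prior_matrices(mapped, sc, worm_atlas, cfg)
        expected = sorted(set(ha(f_spv)) & set(ha(f_tsv)))
        assert refine_bipartite(mapped, sc, worm_atlas, cfg) == expected


class TestRecognize:
    def test_self_recognition_is_exact(self, worm_atlas):
        res = recognize(worm_atlas.pointset, worm_atlas, RecognitionConfig())
        assert all(
            res.assignment[n] == worm_atlas.ids[n] for n in range(len(worm_atlas.ids))
        )

    def test_jittered_affine_worm_high_accuracy(self, worm_template, worm_atlas):
        nn = np.median(cKDTree(worm_template.points).query(worm_template.points, k=2)[0][:, 1])
        cfg = WormConfig(n_cells=60, jitter_sigma=(0.1 * nn,) * 3, seed=21)
        accs = []
        for seed in (1, 2, 3):
            worm = make_synthetic_worm(worm_template, cfg, seed=seed)
            res = recognize(PointSet(worm.points), worm_atlas, RecognitionConfig())
            accs.append(np.mean([res.assignment[n] == worm.ids[n] for n in range(len(worm))]))
        assert np.mean(accs) >= 0.95

    def test_small_subject_rejected(self, worm_atlas):
        with pytest.raises(ValueError):
            recognize(PointSet(np.zeros((3, 3))), worm_atlas)

    def test_assignments_are_one_to_one(self, worm_template, worm_atlas):
        worm = make_synthetic_worm(
            worm_template, WormConfig(n_cells=60, jitter_sigma=(1, 1, 1), seed=30), seed=3
        )
        res = recognize(PointSet(worm.points), worm_atlas, RecognitionConfig())
        assigned = [v for v in res.assignment.values() if v is not None]
        assert len(assigned) == len(set(assigned))
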