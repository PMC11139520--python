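"""Statistical atlas: transforms, shape contexts, ASP/SPV/TSV construction."""

import numpy as np
import numpy.testing as npt
import pytest

from cellasr.atlas import (
    AffineTransform,
    AtlasConfig,
    ShapeContextParams,
    build_asp,
    build_atlas,
    build_spv,
    build_tsv,
    chi_square,
    fit_affine,
    fit_pwa,
    pca_frame,
    shape_context,
    shape_contexts_all,
)
from cellasr.synthetic import PointSet, WormConfig, make_synthetic_atlas, make_synthetic_worm


@pytest.fixture()
def cloud(rng):
    return rng.uniform(-20, 20, (30, 3))


class TestAffine:
    def test_identity_recovery(self, cloud):
        tf = fit_affine(cloud, cloud)
        npt.assert_allclose(tf.matrix, np.eye(3), atol=1e-10)
        npt.assert_allclose(tf.translation, 0, atol=1e-9)

    def test_exact_recovery_of_known_affine(self, cloud, rng):
        a = np.eye(3) + 0.2 * rng.normal(size=(3, 3))
        t = rng.normal(size=3)
        tf = fit_affine(cloud, cloud @ a.T + t)
        npt.assert_allclose(tf.matrix, a, atol=1e-8)
        npt.assert_allclose(tf.translation, t, atol=1e-7)

    def test_noisy_fit_matches_normal_equations(self, cloud, rng):
        dst = cloud @ (np.eye(3) * 1.1).T + rng.normal(0, 0.5, cloud.shape)
        tf = fit_affine(cloud, dst)
        design = np.hstack([cloud, np.ones((len(cloud), 1))])
        sol = np.linalg.solve(design.T @ design, design.T @ dst)
        npt.assert_allclose(tf.matrix, sol[:3].T, atol=1e-8)

    def test_degenerate_raises(self):
        flat = np.zeros((5, 3))
        flat[:, 0] = np.arange(5)
        with pytest.raises(ValueError):
            fit_affine(flat, flat)


class TestPwa:
    def test_single_segment_equals_global_affine(self, cloud):
        dst = cloud * 1.3 + 2.0
        pwa = fit_pwa(cloud, dst, n_segments=1)
        npt.assert_allclose(pwa.apply(cloud), dst, atol=1e-8)

    def test_globally_affine_data_recovered_by_every_segment(self, rng):
        src = rng.uniform(0, 100, (120, 3))
        src[:, 0] *= 4  # elongate
        a = np.eye(3) + 0.1 * rng.normal(size=(3, 3))
        dst = src @ a.T + 3.0
        pwa = fit_pwa(src, dst, n_segments=4)
        npt.assert_allclose(pwa.apply(src), dst, atol=1e-6)

    def test_bent_worm_pwa_beats_global_affine(self, rng):
        src = rng.uniform(0, 300, (150, 3))
        src[:, 1:] = rng.uniform(-15, 15, (150, 2))
        dst = src.copy()
        dst[:, 1] += 20 * np.sin(np.pi * src[:, 0] / 300)  # smooth bend
        aff = fit_affine(src, dst)
        pwa = fit_pwa(src, dst, n_segments=6)
        res_aff = np.linalg.norm(aff.apply(src) - dst, axis=1).mean()
        res_pwa = np.linalg.norm(pwa.apply(src) - dst, axis=1).mean()
        assert res_pwa < res_aff


class TestShapeContext:
    def test_single_neighbor_one_bin(self):
        p = ShapeContextParams(n_shells=5, n_azimuth=6, n_polar=2, r_min=2, r_max=100)
        r = 2.0 * (100 / 2) ** (0.5 / 5)  # mid first shell
        pts = np.array([[0.0, 0, 0], [r, 0, 0], [-100.0, 0, 0], [100.0, 0, 0]])
        # fixed identity frame to make the bin analytic
        h = shape_context(pts, 0, p, frame=np.eye(3))
        assert h.sum() == pytest.approx(1.0)
        assert (h > 0).sum() == 3  # one bin per neighbor
        # the close neighbor lands in shell 0
        shell0 = h[: p.n_sectors]
        assert shell0.sum() == pytest.approx(1 / 3)

    def test_translation_invariance(self, rng):
        pts = rng.uniform(0, 50, (20, 3))
        p = ShapeContextParams()
        h1 = shape_context(pts, 3, p)
        h2 = shape_context(pts + 17.0, 3, p)
        npt.assert_allclose(h1, h2)

    def test_duplicate_points_leave_normalized_histogram_unchanged(self, rng):
        pts = rng.uniform(0, 50, (15, 3))
        p = ShapeContextParams()
        frame = pca_frame(pts)
        h1 = shape_context(pts, 0, p, frame=frame)
        doubled = np.vstack([pts, pts[1:] + 1e-9])
        h2 = shape_context(doubled, 0, p, frame=frame)
        npt.assert_allclose(h1, h2, atol=1e-12)

    def test_out_of_range_neighbors_warn_zero(self):
        pts = np.array([[0.0, 0, 0], [500.0, 0, 0]])
        with pytest.warns(UserWarning):
            h = shape_context(pts, 0, ShapeContextParams())
        assert not h.any()


class TestChiSquare:
    def test_identical_zero_and_symmetry(self, rng):
        h1 = rng.random(10)
        h1 /= h1.sum()
        h2 = rng.random(10)
        h2 /= h2.sum()
        assert chi_square(h1, h1) == pytest.approx(0.0)
        assert chi_square(h1, h2) == pytest.approx(chi_square(h2, h1))

    def test_disjoint_unit_mass(self):
        h1 = np.array([1.0, 0.0])
        h2 = np.array([0.0, 1.0])
        assert chi_square(h1, h2) == pytest.approx(1.0, abs=1e-6)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            chi_square(np.ones(3), np.ones(4))


class TestAspConstruction:
    def test_identical_samples_converge_to_sample(self, worm_template):
        samples = [PointSet(worm_template.points.copy(), list(worm_template.ids))
                   for _ in range(3)]
        asp, ids, aligned = build_asp(samples)
        npt.assert_allclose(asp, worm_template.points, atol=1e-6)

    def test_affine_perturbed_copies_recover_template_up_to_affine(self, worm_template, rng):
        samples = []
        for _ in range(8):
            a = np.eye(3) + rng.uniform(-0.08, 0.08, (3, 3))
            t = rng.uniform(-5, 5, 3)
            samples.append(PointSet(worm_template.points @ a.T + t, list(worm_template.ids)))
        asp, ids, _ = build_asp(samples)
        # Procrustes-style residual after the best affine asp->template
        from cellasr.atlas import fit_affine as fa

        tf = fa(asp, worm_template.points)
        resid = np.linalg.norm(tf.apply(asp) - worm_template.points, axis=1)
        assert resid.max() < 0.5  # zero noise: residual far below point spacing

    def test_sample_order_invariance(self, worm_template, rng):
        samples = []
        for _ in range(6):
            a = np.eye(3) + rng.uniform(-0.05, 0.05, (3, 3))
            samples.append(PointSet(worm_template.points @ a.T, list(worm_template.ids)))
        asp1, _, _ = build_asp(samples)
        asp2, _, _ = build_asp(samples[::-1])
        body = np.linalg.norm(asp1.max(axis=0) - asp1.min(axis=0))
        assert np.linalg.norm(asp1 - asp2, axis=1).max() < 2e-2 * body


class TestSpvTsv:
    def test_identical_samples_zero_spv_and_tsv(self, worm_template):
        samples = [PointSet(worm_template.points.copy(), list(worm_template.ids))
                   for _ in range(3)]
        atlas = build_atlas(samples)
        npt.assert_allclose(atlas.spv, 0, atol=1e-6)
        npt.assert_allclose(atlas.tsv, 0, atol=1e-9)

    def test_spv_recovers_injected_anisotropic_jitter(self, worm_template):
        cfg = WormConfig(n_cells=60, affine_magnitude=0.0, bend_amplitude=0.0,
                         jitter_sigma=(1.0, 2.0, 3.0), seed=11)
        samples = [make_synthetic_worm(worm_template, cfg, seed=100 + s) for s in range(50)]
        atlas = build_atlas(samples, AtlasConfig(pwa_segments=1))
        recovered = atlas.spv.mean(axis=0)
        npt.assert_allclose(recovered, [1.0, 2.0, 3.0], rtol=0.15)

    def test_tsv_increases_with_jitter_amplitude(self, worm_template):
        means = []
        for amp in (0.5, 2.0):
            cfg = WormConfig(n_cells=60, affine_magnitude=0.0, bend_amplitude=0.0,
                             jitter_sigma=(amp,) * 3, seed=12)
            samples = [make_synthetic_worm(worm_template, cfg, seed=200 + s) for s in range(12)]
            atlas = build_atlas(samples, AtlasConfig(pwa_segments=1))
            means.append(atlas.tsv.mean())
        assert means[0] < means[1]
        assert (np.array(means) >= 0).all()


def test_atlas_needs_two_samples(worm_template):
    with pytest.raises(ValueError):
        build_asp([worm_template])
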