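"""Displacement-field construction and loss identities."""

import numpy as np
import numpy.testing as npt
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi

from cellasr.dvf import (
    LossWeights,
    compute_dvf,
    direction_loss,
    direction_loss_grad,
    displacement_loss,
    displacement_loss_grad,
    dvf_to_distance,
    total_loss,
)


def brute_force_dvf(mask):
    """Independent oracle: exhaustive nearest-background search with the
    z-major lowest-linear-index tie-break."""
    bg = np.argwhere(mask == 0)
    nz, ny, nx = mask.shape
    lin = (bg[:, 0] * ny + bg[:, 1]) * nx + bg[:, 2]
    field = np.zeros((3,) + mask.shape)
    for z, y, x in np.argwhere(mask > 0):
        d2 = ((bg - [z, y, x]) ** 2).sum(axis=1)
        best = d2.min()
        cands = np.nonzero(d2 == best)[0]
        pick = bg[cands[np.argmin(lin[cands])]]
        field[:, z, y, x] = [x - pick[2], y - pick[1], z - pick[0]]
    return field


class TestComputeDvf:
    def test_all_background_is_zero_field(self):
        assert not compute_dvf(np.zeros((3, 3, 3), int)).any()

    def test_single_voxel_points_down_z_by_tiebreak(self):
        mask = np.zeros((5, 5, 5), int)
        mask[2, 2, 2] = 1
        f = compute_dvf(mask)
        npt.assert_array_equal(f[:, 2, 2, 2], [0, 0, 1])
        assert np.linalg.norm(f[:, 2, 2, 2]) == 1.0

    def test_line_mask_matches_exhaustive_search(self):
        mask = np.zeros((1, 1, 7), int)
        mask[0, 0, 1:6] = 1
        npt.assert_array_equal(compute_dvf(mask), brute_force_dvf(mask))
        # center voxel ties to the lower linear index (the left end)
        assert compute_dvf(mask)[0, 0, 0, 3] == 3

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        mask = (rng.random((6, 7, 8)) > 0.55).astype(int)
        npt.assert_array_equal(compute_dvf(mask), brute_force_dvf(mask))

    def test_pointer_validity_and_edt_equivalence(self):
        rng = np.random.default_rng(3)
        mask = (rng.random((10, 12, 14)) > 0.6).astype(int)
        f = compute_dvf(mask)
        dist = dvf_to_distance(f)
        npt.assert_allclose(dist, ndi.distance_transform_edt(mask > 0))
        zz, yy, xx = np.nonzero(mask)
        tz = (zz - f[2, zz, yy, xx]).astype(int)
        ty = (yy - f[1, zz, yy, xx]).astype(int)
        tx = (xx - f[0, zz, yy, xx]).astype(int)
        assert (mask[tz, ty, tx] == 0).all()

    def test_translation_equivariance(self):
        mask = np.zeros((9, 9, 9), int)
        mask[2:4, 2:4, 2:4] = 1
        shifted = np.roll(mask, (1, 2, 1), axis=(0, 1, 2))
        f = compute_dvf(mask)
        fs = compute_dvf(shifted)
        npt.assert_array_equal(np.roll(f, (1, 2, 1), axis=(1, 2, 3)), fs)

    def test_anisotropic_spacing_matches_weighted_edt(self):
        rng = np.random.default_rng(4)
        mask = (rng.random((6, 8, 8)) > 0.5).astype(int)
        f = compute_dvf(mask, spacing=(2.0, 1.0, 1.0))
        sp = np.array([1.0, 1.0, 2.0])  # (dx, dy, dz) channel spacing
        dist = np.sqrt(((f * sp[:, None, None, None]) ** 2).sum(axis=0))
        npt.assert_allclose(dist, ndi.distance_transform_edt(mask > 0, sampling=(2, 1, 1)))

    def test_errors(self):
        with pytest.raises(ValueError):
            compute_dvf(np.ones((3, 3, 3), int))
        with pytest.raises(ValueError):
            compute_dvf(-np.ones((3, 3, 3), int))


class TestLosses:
    def test_distance_map_identities(self):
        f = np.zeros((3, 2, 2, 2))
        assert not dvf_to_distance(f).any()
        f[:, 0, 0, 0] = [3, 4, 0]
        assert dvf_to_distance(f)[0, 0, 0] == 5.0

    def test_displacement_loss_identities(self, rng):
        gt = rng.normal(size=(3, 4, 4, 4))
        assert displacement_loss(gt, gt) == 0.0
        assert displacement_loss(gt + 1.0, gt) == pytest.approx(1.0)
        pred = gt + rng.normal(size=gt.shape)
        naive = sum(
            ((pred[:, i, j, k] - gt[:, i, j, k]) ** 2).sum()
            for i in range(4)
            for j in range(4)
            for k in range(4)
        ) / (3 * 64)
        assert displacement_loss(pred, gt) == pytest.approx(naive)

    def test_direction_loss_parallel_orthogonal_antiparallel(self):
        gt = np.zeros((3, 2, 2, 2))
        gt[0] = 1.0  # all +x
        assert direction_loss(gt, gt) == pytest.approx(0.0)
        assert direction_loss(-gt, gt) == pytest.approx(2.0)
        ortho = np.zeros_like(gt)
        ortho[1] = 1.0
        assert direction_loss(ortho, gt) == pytest.approx(1.0)

    def test_direction_loss_excludes_zero_vectors(self):
        gt = np.zeros((3, 2, 2, 2))
        gt[0, 0, 0, 0] = 1.0
        pred = np.zeros_like(gt)
        pred[0, 0, 0, 0] = 1.0
        pred[1, 1, 1, 1] = 5.0  # gt zero there -> excluded
        assert direction_loss(pred, gt) == pytest.approx(0.0)

    def test_direction_loss_all_zero_warns_and_returns_zero(self):
        z = np.zeros((3, 2, 2, 2))
        with pytest.warns(UserWarning):
            assert direction_loss(z, z) == 0.0

    def test_total_loss_linearity_and_default_weights(self, rng):
        w = LossWeights()
        assert (w.omega1, w.omega2) == (7.0, 1.0)
        gt = rng.normal(size=(3, 3, 3, 3)) + 2.0
        pred = gt + 0.3 * rng.normal(size=gt.shape)
        ld = displacement_loss(pred, gt)
        lr = direction_loss(pred, gt)
        assert total_loss(pred, gt, w) == pytest.approx(7 * ld + lr)
        assert total_loss(pred, gt, LossWeights(2, 5)) == pytest.approx(2 * ld + 5 * lr)

    @pytest.mark.parametrize("grad_fn,loss_fn", [
        (displacement_loss_grad, displacement_loss),
        (direction_loss_grad, direction_loss),
    ])
    def test_loss_gradients_match_finite_differences(self, grad_fn, loss_fn, rng):
        gt = rng.normal(size=(3, 2, 2, 2)) + 1.0
        pred = gt + 0.2 * rng.normal(size=gt.shape)
        g = grad_fn(pred, gt)
        eps = 1e-6
        for idx in [(0, 0, 0, 0), (1, 1, 0, 1), (2, 1, 1, 1)]:
            p = pred.copy()
            p[idx] += eps
            up = loss_fn(p, gt)
            p[idx] -= 2 * eps
            dn = loss_fn(p, gt)
            assert g[idx] == pytest.approx((up - dn) / (2 * eps), abs=1e-5)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 10_000))
def test_losses_nonnegative_property(seed):
    rng = np.random.default_rng(seed)
    gt = rng.normal(size=(3, 3, 3, 3))
    pred = rng.normal(size=(3, 3, 3, 3))
    assert displacement_loss(pred, gt) >= 0
    assert 0 <= direction_loss(pred, gt) <= 2
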