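"""Preprocessing contracts on phantoms with known ground truth."""

import numpy as np
import pytest

from habitatmri.grid import Mask3D, Volume3D
from habitatmri.preprocess import (
    correct_bias,
    dice,
    learn_landmarks,
    register,
    resample_isotropic,
    standardize_histogram,
)


def _bias_phantom(amplitude: float, seed: int = 0, shape=(32, 32, 32)):
    """Homogeneous tissue + small noise, multiplied by a quadratic field."""
    rng = np.random.default_rng(seed)
    base = 100.0 + rng.normal(0, 1.0, shape)
    coords = [np.linspace(-1, 1, n) for n in shape]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    field = 1.0 + amplitude * (X**2 - 0.5 * Y**2 + 0.3 * X * Z)
    vol = Volume3D(base * field)
    mask = np.zeros(shape, dtype=np.int16)
    mask[6:26, 6:26, 6:26] = 1
    return vol, Volume3D(base), Mask3D(mask)


class TestBiasCorrection:
    def test_bias_free_volume_unchanged_within_tolerance(self):
        _, clean, mask = _bias_phantom(0.0)
        out = correct_bias(clean, order=3)
        np.testing.assert_allclose(out.data, clean.data, rtol=0.02)

    def test_constant_volume_returned_unchanged(self):
        vol = Volume3D(np.full((10, 10, 10), 7.0))
        out = correct_bias(vol)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_planted_quadratic_bias_cv_reduction(self):
        vol, _, mask = _bias_phantom(0.3)
        out = correct_bias(vol, order=3)
        m = mask.voi
        cv_before = vol.data[m].std() / vol.data[m].mean()
        cv_after = out.data[m].std() / out.data[m].mean()
        assert cv_after <= 0.5 * cv_before

    def test_mean_preserved_inside_mask(self):
        vol, _, mask = _bias_phantom(0.3)
        out = correct_bias(vol, mask, order=3)
        m = mask.voi
        assert out.data[m].mean() == pytest.approx(vol.data[m].mean(), rel=0.01)

    def test_nonpositive_intensity_rejected(self):
        vol = Volume3D(np.zeros((8, 8, 8)))
        with pytest.raises(ValueError):
            correct_bias(vol)


class TestResample:
    def test_already_isotropic_grid_unchanged(self):
        vol = Volume3D(np.random.default_rng(0).random((12, 12, 12)), spacing=(1, 1, 1))
        out = resample_isotropic(vol, 1.0)
        assert out.shape == vol.shape
        np.testing.assert_allclose(out.data, vol.data, atol=1e-9)

    def test_volume_bookkeeping_2mm_to_1mm(self):
        mask = np.zeros((30, 30, 30), dtype=np.int16)
        mask[5:25, 5:25, 5:25] = 1  # 20-voxel cube at 2 mm = 8000 voxels = 64000 mm^3
        m = Mask3D(mask, spacing=(2, 2, 2))
        out = resample_isotropic(m, 1.0, mode="nearest")
        assert all(abs(n - 60) <= 1 for n in out.shape)
        vol_mm3_before = m.n_voxels * 8.0
        vol_mm3_after = out.n_voxels * 1.0
        assert vol_mm3_after == pytest.approx(vol_mm3_before, rel=0.05)

    def test_nearest_mode_keeps_masks_binary(self):
        m = Mask3D((np.random.default_rng(1).random((10, 12, 14)) > 0.5).astype(np.int16),
                   spacing=(1.5, 1.0, 2.0))
        out = resample_isotropic(m, 1.0, mode="nearest")
        assert set(np.unique(out.data)) <= {0, 1}

    def test_degenerate_volume_rejected(self):
        with pytest.raises(ValueError):
            resample_isotropic(Volume3D(np.zeros((1, 5, 5))), 1.0)


class TestHistogramStandardization:
    def _volumes(self):
        rng = np.random.default_rng(3)
        a = Volume3D(rng.gamma(4.0, 25.0, (16, 16, 16)))
        b = Volume3D(rng.gamma(6.0, 20.0, (16, 16, 16)))
        return a, b

    def test_affine_shifted_volumes_align_deciles(self):
        a, _ = self._volumes()
        shifted = Volume3D(2.5 * a.data + 40.0)
        model = learn_landmarks([a, shifted])
        sa = standardize_histogram(a, model)
        sb = standardize_histogram(shifted, model)
        pct = np.percentile(sa.data, [10, 30, 50, 70, 90])
        pct2 = np.percentile(sb.data, [10, 30, 50, 70, 90])
        np.testing.assert_allclose(pct, pct2, atol=1e-8)

    def test_idempotent(self):
        a, b = self._volumes()
        model = learn_landmarks([a, b])
        once = standardize_histogram(a, model)
        twice = standardize_histogram(once, model)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-6)

    def test_monotone(self):
        a, b = self._volumes()
        model = learn_landmarks([a, b])
        out = standardize_histogram(a, model)
        x, y = a.data.ravel(), out.data.ravel()
        order = np.argsort(x)
        assert np.all(np.diff(y[order]) >= -1e-9)

    def test_constant_volume_rejected(self):
        a, b = self._volumes()
        model = learn_landmarks([a, b])
        with pytest.raises(ValueError):
            standardize_histogram(Volume3D(np.ones((8, 8, 8))), model)

    def test_single_volume_training_rejected(self):
        a, _ = self._volumes()
        with pytest.raises(ValueError):
            learn_landmarks([a])


def test_chain_is_idempotent_without_registration():
    from habitatmri.grid import Mask3D
    from habitatmri.preprocess import preprocess_patient

    rng = np.random.default_rng(6)
    shape = (48, 48, 48)  # the chain's operating volume size
    # tissue-like contrast (mean ~200, sd ~30, no long tails): the
    # invariant concerns realistic volumes, where the second-pass
    # polynomial fit has essentially nothing left to remove
    mk = lambda m, s: Volume3D(np.clip(rng.normal(m, s, shape), 50, None))
    t2w, dwi, other = mk(200, 30), mk(180, 28), mk(200, 30)
    t2w.sequence, dwi.sequence = "T2WI", "DWI"
    voi = Mask3D((rng.random(shape) > 0.7).astype(np.int16))
    lm = {
        "T2WI": __import__("habitatmri.preprocess", fromlist=["learn_landmarks"]).learn_landmarks([t2w, other]),
        "DWI": __import__("habitatmri.preprocess", fromlist=["learn_landmarks"]).learn_landmarks([dwi, other]),
    }
    once = preprocess_patient(t2w, dwi, voi, lm, do_register=False)
    twice = preprocess_patient(once[0], once[1], once[2], lm, do_register=False)
    for a, b in zip(once[:2], twice[:2]):
        rel = np.linalg.norm(b.data - a.data) / np.linalg.norm(a.data)
        assert rel < 1e-3


def _registration_phantom(shift_vox=(0, 0, 0), seed=0):
    """Blurred ellipsoid with texture; moving = fixed translated by shift."""
    rng = np.random.default_rng(seed)
    shape = (36, 36, 36)
    grids = np.meshgrid(*[np.arange(n) - n / 2 for n in shape], indexing="ij")
    r = np.sqrt(grids[0] ** 2 / 1.3 + grids[1] ** 2 + grids[2] ** 2 / 0.8)
    base = 100.0 * np.exp(-((r / 10.0) ** 2)) + 20.0
    from scipy import ndimage

    base += ndimage.gaussian_filter(rng.normal(0, 6.0, shape), 2.0)
    moved = ndimage.shift(base, shift_vox, order=3, mode="nearest")
    return Volume3D(base), Volume3D(moved)


class TestRegistration:
    def test_identity_recovered(self):
        fixed, _ = _registration_phantom()
        tx, res = register(fixed, fixed, deformable=False)
        assert tx.converged
        assert np.all(np.abs(tx.translation_mm) < 0.1)
        # off-diagonal linear terms stay near identity
        np.testing.assert_allclose(tx.affine[:, :3], np.eye(3), atol=0.01)

    def test_planted_3mm_shift_recovered(self):
        fixed, moving = _registration_phantom(shift_vox=(3.0, 0.0, 0.0))
        tx, res = register(moving, fixed, deformable=False)
        # moving(x) = fixed(x - 3): the resampling transform maps the fixed
        # frame into the moving frame, so the recovered translation is +3
        assert abs(tx.translation_mm[0] - 3.0) < 0.5
        assert np.all(np.abs(tx.translation_mm[1:]) < 0.5)
        err = np.abs(res.data - fixed.data)[4:-4, 4:-4, 4:-4]
        assert np.median(err) < 2.0

    def test_shift_plus_warp_voi_overlap_recovered(self):
        from habitatmri.grid import Mask3D
        from habitatmri.preprocess import apply_transform

        rng = np.random.default_rng(0)
        shape = (40, 40, 40)
        grids = np.meshgrid(*[np.arange(n) - n / 2 for n in shape], indexing="ij")
        r = np.sqrt(grids[0] ** 2 / 1.2 + grids[1] ** 2 + grids[2] ** 2 / 0.9)
        from scipy import ndimage

        base = 100.0 * np.exp(-((r / 12.0) ** 2)) + 30.0
        base += ndimage.gaussian_filter(rng.normal(0, 15.0, shape), 1.5)
        mask = (r < 11).astype(np.int16)
        disp = []
        for ax in range(3):
            d = np.full(shape, (3.0, 1.5, 0.0)[ax])
            w = ndimage.gaussian_filter(rng.normal(size=shape), 10.0)
            disp.append(d + w / w.std() * 1.0)
        g = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
        sample = [gr - dd for gr, dd in zip(g, disp)]
        moved = ndimage.map_coordinates(base, sample, order=3, mode="nearest")
        mask_moved = ndimage.map_coordinates(mask, sample, order=0, mode="constant").astype(np.int16)
        assert dice(mask_moved, mask) <= 0.8  # misaligned before registration
        tx, _ = register(Volume3D(moved), Volume3D(base), deformable=True)
        voi_reg = apply_transform(tx, Mask3D(mask_moved), Volume3D(base))
        assert dice(voi_reg.data, mask) >= 0.95
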