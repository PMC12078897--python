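"""Feature engine: budgets, filter bank, first-order/shape closed forms."""

import numpy as np
import pytest

from habitatmri.features import (
    FeatureConfig,
    build_image_types,
    discretize,
    extract_feature_vector,
    first_order_features,
    shape_features,
)
from habitatmri.grid import Mask3D, Volume3D


class TestConfig:
    def test_default_budget_matches_fixed_class_counts(self):
        cfg = FeatureConfig.default()
        assert cfg.total_features == 1904
        assert cfg.class_counts == {
            "firstorder": 378, "shape": 14, "glcm": 441, "glrlm": 336,
            "glszm": 336, "gldm": 294, "ngtdm": 105,
        }
        assert len(cfg.image_types) == 21
        assert len(cfg.directions) == 13

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            FeatureConfig(bin_width=0)
        with pytest.raises(ValueError):
            FeatureConfig(image_types=("original", "nope"))


class TestImageTypes:
    def test_exactly_21_named_outputs(self, one_patient):
        bank = build_image_types(one_patient.t2w)
        assert len(bank) == 21
        assert set(bank) == set(FeatureConfig.default().image_types)
        for vol in bank.values():
            assert vol.shape == one_patient.t2w.shape

    def test_constant_volume_derivative_filters_vanish(self):
        vol = Volume3D(np.full((16, 16, 16), 5.0))
        bank = build_image_types(vol)
        assert np.allclose(bank["gradient"].data, 0.0)
        for s in (1, 2, 3):
            # zero up to the truncated-kernel residual of the discrete filter
            assert np.abs(bank[f"log-sigma-{s}mm"].data).max() < 0.01
        # lowpass wavelet band reproduces the constant up to normalisation
        lll = bank["wavelet-LLL"].data
        assert np.allclose(lll, lll.flat[0])

    def test_log_sigma_exceeding_extent_rejected(self):
        vol = Volume3D(np.ones((3, 3, 3)))
        with pytest.raises(ValueError):
            build_image_types(vol, config=FeatureConfig(image_types=("original", "log-sigma-4mm")))


class TestDiscretize:
    def test_bin_arithmetic(self):
        data = np.arange(100, dtype=float).reshape(1, 10, 10)
        q, n = discretize(data, np.ones_like(data), 25.0)
        assert n == 4
        assert q.min() == 1 and q.max() == 4

    def test_constant_region_single_level(self):
        data = np.full((2, 2, 2), 3.0)
        q, n = discretize(data, np.ones_like(data), 25.0)
        assert n == 1 and set(q.ravel()) == {1}

    def test_planted_two_level_phantom(self):
        data = np.where(np.arange(64).reshape(4, 4, 4) < 32, 10.0, 60.0)
        q, n = discretize(data, np.ones_like(data), 25.0)
        assert n == 3  # range 50 / width 25 -> levels 1..3, two occupied
        assert set(q.ravel()) == {1, 3}

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            discretize(np.ones((2, 2, 2)), np.zeros((2, 2, 2)), 25.0)


class TestFirstOrder:
    def test_constant_region_closed_forms(self):
        c, n = 7.0, 3 * 3 * 3
        data = np.full((3, 3, 3), c)
        f = first_order_features(data, np.ones_like(data), voxel_volume=2.0)
        assert f["Mean"] == c and f["Variance"] == 0.0
        assert f["Energy"] == pytest.approx(n * c * c)
        assert f["TotalEnergy"] == pytest.approx(2.0 * n * c * c)
        assert f["Entropy"] == 0.0 and f["Uniformity"] == 1.0

    def test_symmetric_distribution_has_zero_skewness(self, rng):
        x = rng.normal(50.0, 5.0, 40_000)
        data = x.reshape(40, 40, 25)
        f = first_order_features(data, np.ones_like(data))
        assert abs(f["Skewness"]) < 0.05

    def test_affine_equivariance(self, rng):
        data = rng.gamma(3.0, 10.0, (8, 8, 8))
        mask = np.ones_like(data)
        f0 = first_order_features(data, mask)
        f1 = first_order_features(2.0 * data + 5.0, mask)
        assert f1["Mean"] == pytest.approx(2.0 * f0["Mean"] + 5.0, rel=1e-9)
        assert f1["Skewness"] == pytest.approx(f0["Skewness"], rel=1e-6)
        assert f1["Variance"] == pytest.approx(4.0 * f0["Variance"], rel=1e-9)


class TestShape:
    def test_cube_oracle(self):
        mask = np.zeros((14, 14, 14), dtype=np.int16)
        mask[2:12, 2:12, 2:12] = 1
        f = shape_features(Mask3D(mask, spacing=(1, 1, 1)))
        assert f["VoxelVolume"] == pytest.approx(1000.0)
        assert f["MeshVolume"] == pytest.approx(1000.0, rel=0.05)
        assert f["SurfaceArea"] == pytest.approx(600.0, rel=0.10)
        expected_sph = np.pi ** (1 / 3) * (6.0 * f["MeshVolume"]) ** (2 / 3) / f["SurfaceArea"]
        assert f["Sphericity"] == pytest.approx(expected_sph, rel=1e-9)
        # cube diagonal ~ 10 sqrt(3); mesh runs half a voxel outside the centres
        assert f["Maximum3DDiameter"] == pytest.approx(10 * np.sqrt(3), rel=0.12)
        assert f["Elongation"] == pytest.approx(1.0, rel=1e-6)
        assert f["Flatness"] == pytest.approx(1.0, rel=1e-6)

    def test_single_voxel_mask_flagged_undefined(self):
        mask = np.zeros((5, 5, 5), dtype=np.int16)
        mask[2, 2, 2] = 1
        f = shape_features(Mask3D(mask))
        assert f["VoxelVolume"] == 1.0
        assert np.isnan(f["MeshVolume"]) and np.isnan(f["Sphericity"])


class TestExtraction:
    def test_full_bank_vector_length_and_class_counts(self, one_patient):
        cfg = FeatureConfig.default()
        vec = extract_feature_vector(
            one_patient.t2w, one_patient.dwi, {"whole_T2WI": one_patient.voi}, cfg
        )
        assert vec.size == 1904
        counts = {}
        for name in vec.index:
            cls = name.split("|")[2]
            counts[cls] = counts.get(cls, 0) + 1
        assert counts == cfg.class_counts

    def test_deterministic_and_mean_consistency(self, one_patient, fast_config):
        masks = {"whole_DWI": one_patient.voi}
        v1 = extract_feature_vector(one_patient.t2w, one_patient.dwi, masks, fast_config)
        v2 = extract_feature_vector(one_patient.t2w, one_patient.dwi, masks, fast_config)
        assert v1.equals(v2)
        plain_mean = one_patient.dwi.data[one_patient.voi.voi].mean()
        assert v1["whole_DWI|original|firstorder|Mean"] == pytest.approx(plain_mean, rel=1e-12)

    def test_empty_region_reported_missing(self, one_patient, fast_config):
        empty = Mask3D(np.zeros(one_patient.voi.shape, dtype=np.int16),
                       one_patient.voi.spacing, one_patient.voi.origin)
        vec = extract_feature_vector(
            one_patient.t2w, one_patient.dwi,
            {"whole_T2WI": one_patient.voi, "DWI_habitat2": empty}, fast_config,
        )
        assert vec.size == 2 * fast_config.total_features
        sub = vec[[n for n in vec.index if n.startswith("DWI_habitat2|")]]
        assert sub.isna().all()
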