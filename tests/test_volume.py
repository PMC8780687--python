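import numpy as np
import pytest

from valvemorph.volume import (AugmentParams, PhysBox, Volume, augment_volume,
                               bounding_box_scaled, landmark_augmentation,
                               read_volume, resample_to_grid, write_volume,
                               zscore_normalize)


def ball_volume(radius=6.0, spacing=1.0, n=24, center=None):
    c = (np.arange(n) - (n - 1) / 2.0) * spacing
    x, y, z = np.meshgrid(c, c, c, indexing="ij")
    if center is None:
        center = (0, 0, 0)
    m = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2 <= radius**2
    return Volume(m.astype(np.float32), spacing=spacing, origin=np.full(3, c[0]))


class TestVolumeGeometry:
    def test_index_physical_roundtrip(self):
        vol = Volume(np.zeros((4, 5, 6)), spacing=(1, 2, 3), origin=(-1, 0, 5))
        idx = np.array([[0, 0, 0], [3, 4, 5], [1.5, 2.0, 0.5]])
        assert np.allclose(vol.physical_to_index(vol.index_to_physical(idx)), idx)

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ValueError):
            Volume(np.zeros((2, 2, 2)), spacing=(0, 1, 1))

    def test_non_orthonormal_direction_rejected(self):
        with pytest.raises(ValueError):
            Volume(np.zeros((2, 2, 2)), direction=np.eye(3) * 2)


class TestIO:
    @pytest.mark.parametrize("ext", [".nii.gz", ".mha"])
    def test_geometry_roundtrip(self, tmp_path, ext):
        rng = np.random.default_rng(0)
        vol = Volume(rng.normal(size=(7, 8, 9)).astype(np.float32),
                     spacing=(0.4, 0.5, 0.6), origin=(-3.2, 1.1, 7.5))
        path = tmp_path / f"vol{ext}"
        write_volume(vol, path)
        back = read_volume(path)
        assert np.allclose(back.values, vol.values)
        assert np.allclose(back.spacing, vol.spacing)
        assert np.allclose(back.origin, vol.origin)
        assert np.allclose(back.direction, vol.direction)


class TestResample:
    def test_identity_on_own_grid(self):
        vol = ball_volume()
        out = resample_to_grid(vol, vol.center, float(vol.spacing[0]),
                               vol.shape[0], pad_value=0.0)
        assert np.allclose(out.values, vol.values)

    def test_linear_midpoint(self):
        vol = Volume(np.array([0.0, 100.0]).reshape(2, 1, 1), spacing=1.0)
        out = resample_to_grid(vol, center=(0.5, 0, 0), spacing=1.0,
                               matrix_size=1, pad_value=-1, interpolation="linear")
        assert out.values.item() == pytest.approx(50.0)

    def test_outside_padded(self):
        vol = ball_volume(n=10)
        out = resample_to_grid(vol, center=(1000.0, 0, 0), spacing=1.0,
                               matrix_size=8, pad_value=-3024)
        assert np.all(out.values == -3024)

    def test_constant_volume_preserved(self):
        vol = Volume(np.full((9, 9, 9), 7.0), spacing=0.8)
        for interp in ("linear", "nearest"):
            out = resample_to_grid(vol, vol.center + 0.3, 0.5, 12,
                                   pad_value=7.0, interpolation=interp)
            assert np.allclose(out.values, 7.0)

    def test_centroid_preserved(self):
        """Physical positions survive resampling within one output voxel."""
        vol = ball_volume(radius=5, spacing=1.0, n=24, center=(2.0, -1.0, 3.0))
        out = resample_to_grid(vol, vol.center, 0.7, 40, pad_value=0.0,
                               interpolation="nearest")
        c_src = vol.foreground_points().mean(axis=0)
        c_out = out.foreground_points().mean(axis=0)
        assert np.linalg.norm(c_src - c_out) < 0.7

    def test_crop_idempotent(self):
        vol = ball_volume()
        a = resample_to_grid(vol, (1.0, 2.0, 0.0), 1.5, 16, pad_value=0.0)
        b = resample_to_grid(a, (1.0, 2.0, 0.0), 1.5, 16, pad_value=0.0)
        assert np.allclose(a.values, b.values)


class TestNormalize:
    @pytest.mark.parametrize("values,mean,std,expected", [
        (np.full((2, 2, 2), 5.0), 5.0, 1.0, 0.0),
        (np.array([-1.0, 1.0]).reshape(2, 1, 1), 0.0, 1.0, None),
        (np.array([0.0, 10.0]).reshape(2, 1, 1), 5.0, 5.0, None),
    ])
    def test_values(self, values, mean, std, expected):
        out = zscore_normalize(Volume(values), mean, std)
        if expected is not None:
            assert np.allclose(out.values, expected)
        else:
            assert np.allclose(out.values, (values - mean) / std)

    def test_nonpositive_std_rejected(self):
        with pytest.raises(ValueError):
            zscore_normalize(Volume(np.zeros((2, 2, 2))), 0.0, 0.0)


class TestBoundingBox:
    def test_box_scaling(self):
        box = PhysBox((0, 0, 0), (10, 10, 10)).scaled(1.5)
        assert np.allclose(box.lo, -2.5) and np.allclose(box.hi, 12.5)

    def test_factor_one_identity(self):
        box = PhysBox((1, 2, 3), (4, 5, 6))
        out = box.scaled(1.0)
        assert np.allclose(out.lo, box.lo) and np.allclose(out.hi, box.hi)

    def test_single_point_degenerate(self):
        box = bounding_box_scaled(np.array([[1.0, 2.0, 3.0]]), 1.5)
        assert np.allclose(box.lo, box.hi) and np.allclose(box.lo, (1, 2, 3))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bounding_box_scaled(np.zeros((0, 3)), 1.5)
        with pytest.raises(ValueError):
            bounding_box_scaled(Volume(np.zeros((3, 3, 3))), 1.5)


class TestAugment:
    def test_identity_params(self):
        vol = ball_volume()
        out = augment_volume(vol, AugmentParams(), np.random.default_rng(0))
        assert np.allclose(out.values, vol.values)

    def test_same_seed_bit_identical(self):
        vol = ball_volume()
        params = landmark_augmentation()
        a = augment_volume(vol, params, np.random.default_rng(42))
        b = augment_volume(vol, params, np.random.default_rng(42))
        assert np.array_equal(a.values, b.values)

    def test_rotation_90_maps_bar_to_bar(self):
        """90-degree rotations map an axis-aligned bar onto another axis."""
        n = 21
        vals = np.zeros((n, n, n), dtype=np.float32)
        vals[4:17, 10, 10] = 1.0
        vol = Volume(vals, spacing=1.0, origin=np.full(3, -(n - 1) / 2))
        params = AugmentParams(rotation_deg_range=(90.0, 90.0),
                               interpolation="nearest", pad_value=0.0)
        out = augment_volume(vol, params, np.random.default_rng(1))
        idx = np.argwhere(out.values > 0.5)
        assert len(idx) == 13  # bar length preserved
        spans = idx.max(axis=0) - idx.min(axis=0)
        assert sorted(spans) == [0, 0, 12]  # still a single-axis bar

    def test_intensity_only(self):
        vol = ball_volume()
        params = AugmentParams(intensity_scale_range=(2.0, 2.0),
                               intensity_shift_range=(0.5, 0.5))
        out = augment_volume(vol, params, np.random.default_rng(0))
        assert np.allclose(out.values, vol.values * 2.0 + 0.5)
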