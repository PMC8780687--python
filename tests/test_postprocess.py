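import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial import cKDTree

from valvemorph.metrics import surface_points
from valvemorph.postprocess import (extend_insertion_line, fill_holes,
                                    keep_largest_component, postprocess_cusps)
from valvemorph.volume import Volume

from conftest import cusp_mask


def vol(arr):
    return Volume(np.asarray(arr, dtype=np.uint8))


class TestKeepLargestComponent:
    def test_larger_component_survives(self):
        a = np.zeros((12, 12, 12))
        a[1:3, 1:6, 1:2] = 1   # 10 voxels
        a[8:9, 8:13, 8:9] = 1  # 4-5 voxels (clipped)
        out = keep_largest_component(vol(a))
        assert out.values[1, 1, 1] == 1 and out.values[8, 8, 8] == 0

    def test_single_component_identity(self):
        a = np.zeros((6, 6, 6)); a[2:4, 2:4, 2:4] = 1
        out = keep_largest_component(vol(a))
        assert np.array_equal(out.values, a.astype(np.uint8))

    def test_equal_components_tiebreak_smallest_flat_index(self):
        a = np.zeros((10, 10, 10))
        a[6, 6, 6] = 1  # later in C order
        a[1, 1, 1] = 1  # earlier
        out = keep_largest_component(vol(a))
        assert out.values[1, 1, 1] == 1 and out.values[6, 6, 6] == 0

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning):
            out = keep_largest_component(vol(np.zeros((4, 4, 4))))
        assert out.values.sum() == 0

    def test_output_subset_and_idempotent(self):
        rng = np.random.default_rng(0)
        a = (rng.random((15, 15, 15)) < 0.2).astype(np.uint8)
        m = vol(a)
        out = keep_largest_component(m)
        assert np.all(out.values <= m.values)
        again = keep_largest_component(out)
        assert np.array_equal(again.values, out.values)

    def test_connectivity_6_vs_26(self):
        # two voxels touching only diagonally
        a = np.zeros((5, 5, 5)); a[1, 1, 1] = 1; a[2, 2, 2] = 1
        assert keep_largest_component(vol(a), connectivity=26).values.sum() == 2
        assert keep_largest_component(vol(a), connectivity=6).values.sum() == 1


class TestFillHoles:
    def test_hollow_sphere_becomes_ball(self):
        n = 21
        c = np.arange(n) - (n - 1) / 2
        x, y, z = np.meshgrid(c, c, c, indexing="ij")
        r = np.sqrt(x**2 + y**2 + z**2)
        shell = (r <= 7) & (r >= 5)
        out = fill_holes(vol(shell))
        ball = r <= 7
        # filled output covers the solid ball interior
        assert np.all(out.values[ball & (r <= 5)] == 1)

    def test_solid_mask_unchanged(self):
        a = np.zeros((8, 8, 8)); a[2:6, 2:6, 2:6] = 1
        out = fill_holes(vol(a))
        assert np.array_equal(out.values, a.astype(np.uint8))

    def test_torus_tunnel_preserved_matches_flood_fill_oracle(self):
        """Through-tunnels are not cavities: output equals a border flood."""
        n = 25
        c = np.arange(n) - (n - 1) / 2
        x, y, z = np.meshgrid(c, c, c, indexing="ij")
        torus = (np.sqrt(x**2 + y**2) - 7) ** 2 + z**2 <= 3**2
        out = fill_holes(vol(torus))
        # oracle: background flood fill from the border with 6-connectivity
        bg = ~torus
        lab, _ = ndimage.label(bg, structure=ndimage.generate_binary_structure(3, 1))
        border_labels = set(np.unique(lab[0])) | set(np.unique(lab[-1])) \
            | set(np.unique(lab[:, 0])) | set(np.unique(lab[:, -1])) \
            | set(np.unique(lab[:, :, 0])) | set(np.unique(lab[:, :, -1]))
        cavity = bg & ~np.isin(lab, sorted(border_labels))
        expected = torus | cavity
        assert np.array_equal(out.values > 0, expected)
        # the central tunnel is still open
        assert out.values[n // 2, n // 2, n // 2] == 0

    def test_superset_and_idempotent(self):
        rng = np.random.default_rng(1)
        a = (rng.random((12, 12, 12)) < 0.4).astype(np.uint8)
        m = vol(a)
        out = fill_holes(m)
        assert np.all(out.values >= m.values)
        assert np.array_equal(fill_holes(out).values, out.values)


class TestExtendInsertionLine:
    @pytest.fixture(scope="class")
    def detached_cusp(self, default_phantom, root_mask):
        """Phantom RCC with its insertion rim stripped off the wall."""
        spec, labels, _ = default_phantom
        cusp = cusp_mask(labels, 2)
        tree = cKDTree(surface_points(root_mask))
        idx = np.argwhere(cusp.values)
        d = tree.query(cusp.foreground_points())[0]
        kept = idx[d > 1.0 * spec.voxel_spacing]
        vals = np.zeros_like(cusp.values)
        vals[kept[:, 0], kept[:, 1], kept[:, 2]] = 1
        return cusp, cusp.with_values(vals)

    def test_intact_cusp_unchanged(self, default_phantom, root_mask):
        _, labels, _ = default_phantom
        cusp = cusp_mask(labels, 2)
        out, rep = extend_insertion_line(cusp, root_mask)
        assert np.array_equal(out.values, cusp.values)
        assert rep.n_bridged == 0

    def test_detached_rim_recontacts_wall(self, detached_cusp, root_mask,
                                          default_phantom):
        spec, _, _ = default_phantom
        intact, defect = detached_cusp
        out, rep = extend_insertion_line(defect, root_mask)
        assert rep.n_bridged > 0 and rep.added_voxels > 0
        # superset of the input, additions confined to the root region
        assert np.all(out.values >= defect.values)
        added = (out.values > 0) & (defect.values == 0)
        assert np.all(root_mask.values[added] > 0)
        # repaired mask reaches as close to the wall as the intact cusp
        tree = cKDTree(surface_points(root_mask))
        d_out = tree.query(out.foreground_points())[0].min()
        assert d_out <= 1.0 * spec.voxel_spacing

    def test_idempotent(self, detached_cusp, root_mask):
        _, defect = detached_cusp
        out, _ = extend_insertion_line(defect, root_mask)
        out2, rep2 = extend_insertion_line(out, root_mask)
        assert np.array_equal(out2.values, out.values)
        assert rep2.added_voxels == 0

    def test_cusp_outside_root_rejected(self, default_phantom, root_mask):
        _, labels, _ = default_phantom
        stray = np.zeros_like(labels.values)
        stray[0:3, 0:3, 0:3] = 1  # far corner, outside the lumen
        with pytest.raises(ValueError):
            extend_insertion_line(labels.with_values(stray), root_mask)


class TestFullPostprocess:
    def test_single_component_no_cavity_per_cusp(self, default_phantom,
                                                 root_mask):
        _, labels, _ = default_phantom
        cusps = labels.with_values(
            np.where(labels.values >= 2, labels.values, 0).astype(np.uint8))
        # add debris and a hole to one cusp
        vals = cusps.values.copy()
        vals[2, 2, 2] = 2  # disconnected speck
        cleaned, reports = postprocess_cusps(cusps.with_values(vals), root_mask)
        struct = ndimage.generate_binary_structure(3, 3)
        for code in (2, 3, 4):
            m = cleaned.values == code
            _, n = ndimage.label(m, structure=struct)
            assert n == 1
            filled = ndimage.binary_fill_holes(
                m, structure=ndimage.generate_binary_structure(3, 1))
            assert np.array_equal(filled, m)  # no internal cavity
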