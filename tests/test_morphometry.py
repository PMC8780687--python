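import numpy as np
import pytest

from valvemorph.morphometry import (MEASUREMENT_KEYS, MeasurementReport, Plane,
                                    arc_midpoint, cross_section_perimeter,
                                    fit_plane, hinge_point, measure_all,
                                    point_plane_distance, polyline_arclength,
                                    split_cusp_boundary, surface_geodesic)
from valvemorph.phantom import PhantomSpec, build_phantom
from valvemorph.volume import Volume

from conftest import cusp_mask


def length_tol(key):
    return "perimeter" in key or "geometric" in key


class TestPlanes:
    def test_plane_contains_inputs_and_orients_up(self):
        p1, p2, p3 = np.array([0., 0, 1]), np.array([1., 0, 1]), np.array([0., 1, 1])
        pl = fit_plane(p1, p2, p3)
        assert abs(pl.signed_distance(p1)) < 1e-12
        assert np.allclose(pl.normal, (0, 0, 1))

    def test_permutation_invariance(self):
        pts = [np.array([0., 0, 0]), np.array([2., 1, 0.5]), np.array([-1., 3, 1])]
        ref = fit_plane(*pts)
        for perm in ((1, 0, 2), (2, 1, 0), (1, 2, 0)):
            pl = fit_plane(*(pts[i] for i in perm))
            assert np.allclose(pl.normal, ref.normal)
            assert abs(pl.signed_distance(ref.point)) < 1e-9

    def test_toward_orientation(self):
        pl = fit_plane((0, 0, 0), (1, 0, 0), (0, 1, 0), toward=(0, 0, -5))
        assert np.allclose(pl.normal, (0, 0, -1))

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            fit_plane((0, 0, 0), (1, 1, 1), (2, 2, 2))

    @pytest.mark.parametrize("p,mode,expected", [
        ((0, 0, 0), "absolute", 0.0),
        ((0, 0, 5), "absolute", 5.0),
        ((0, 0, -5), "signed", -5.0),
    ])
    def test_point_plane_distance(self, p, mode, expected):
        pl = Plane((0, 0, 0), (0, 0, 1))
        assert point_plane_distance(p, pl, mode) == pytest.approx(expected)


class TestPolylines:
    def test_two_point_segment(self):
        path = np.array([[0., 0, 0], [5., 0, 0]])
        assert polyline_arclength(path) == 5.0
        assert np.allclose(arc_midpoint(path), (2.5, 0, 0))

    def test_closed_square_perimeter(self):
        a = 3.0
        sq = np.array([[0, 0, 0], [a, 0, 0], [a, a, 0], [0, a, 0], [0, 0, 0]],
                      dtype=float)
        assert polyline_arclength(sq) == pytest.approx(4 * a)

    def test_reversal_invariance(self):
        rng = np.random.default_rng(0)
        path = rng.normal(size=(10, 3))
        assert polyline_arclength(path[::-1]) == pytest.approx(
            polyline_arclength(path))
        assert np.allclose(arc_midpoint(path[::-1]), arc_midpoint(path), atol=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            polyline_arclength(np.zeros((1, 3)))

    def test_hinge_tie_breaks_to_first(self):
        pl = Plane((0, 0, 0), (0, 0, 1))
        flat = np.array([[0., 0, 0], [1., 0, 0], [2., 0, 0]])
        assert np.allclose(hinge_point(flat, pl), (0, 0, 0))

    def test_hinge_of_descending_path_is_last(self):
        pl = Plane((0, 0, 0), (0, 0, 1))
        desc = np.array([[0., 0, 3], [0., 0, 2], [0., 0, 1]])
        assert np.allclose(hinge_point(desc, pl), (0, 0, 1))


class TestCuspBoundary:
    def test_split_arcs_anchor_commissures_and_pass_landmarks(
            self, default_phantom, root_mask):
        spec, labels, truth = default_phantom
        cusp = cusp_mask(labels, 2)
        c1 = truth.landmarks["commissure_rl"]
        c2 = truth.landmarks["commissure_rn"]
        cb = split_cusp_boundary(cusp, root_mask, (c1, c2))
        for path in (cb.attached, cb.free):
            ends = {tuple(np.round(path[0], 6)), tuple(np.round(path[-1], 6))}
            assert ends == {tuple(np.round(c1, 6)), tuple(np.round(c2, 6))}
        # attached passes through the nadir, free through the Arantius spot
        nadir = truth.landmarks["nadir_rcc"]
        arantius = (c1 + c2) / 2.0
        d_att = np.linalg.norm(cb.attached - nadir, axis=1).min()
        d_free = np.linalg.norm(cb.free - arantius, axis=1).min()
        assert d_att <= 2 * spec.voxel_spacing
        assert d_free <= 2 * spec.voxel_spacing

    def test_attached_length_matches_analytic(self, default_phantom, root_mask):
        spec, labels, truth = default_phantom
        cusp = cusp_mask(labels, 3)
        cb = split_cusp_boundary(cusp, root_mask,
                                 (truth.landmarks["commissure_rl"],
                                  truth.landmarks["commissure_ln"]))
        assert polyline_arclength(cb.attached) == pytest.approx(
            truth.measurements["cusp_insertion_length_lcc"],
            abs=2 * spec.voxel_spacing)


class TestSurfaceGeodesic:
    def test_same_point_zero(self, default_phantom):
        _, labels, truth = default_phantom
        cusp = cusp_mask(labels, 2)
        p = truth.landmarks["nadir_rcc"]
        assert surface_geodesic(cusp, p, p) == 0.0

    def test_flat_sheet_matches_straight_line(self, default_phantom):
        """On the planar closed cusp, geodesics are straight lines (~3%)."""
        _, labels, truth = default_phantom
        cusp = cusp_mask(labels, 2)
        a = truth.landmarks["nadir_rcc"]
        b = (truth.landmarks["commissure_rl"] + truth.landmarks["commissure_rn"]) / 2
        g = surface_geodesic(cusp, a, b)
        straight = np.linalg.norm(a - b)
        assert g == pytest.approx(straight, rel=0.03)

    def test_geodesic_dominates_euclidean(self, default_phantom):
        _, labels, truth = default_phantom
        cusp = cusp_mask(labels, 4)
        a = truth.landmarks["nadir_ncc"]
        b = truth.landmarks["commissure_ln"]
        assert surface_geodesic(cusp, a, b) >= np.linalg.norm(a - b) - 1e-9

    def test_far_point_rejected(self, default_phantom):
        _, labels, truth = default_phantom
        cusp = cusp_mask(labels, 2)
        with pytest.raises(ValueError):
            surface_geodesic(cusp, truth.landmarks["nadir_rcc"], (50., 50., 50.))


class TestCrossSectionPerimeter:
    def _cylinder(self, radius, spacing=0.4, height=8.0, margin=3.0):
        n_xy = int(2 * (radius + margin) / spacing) + 1
        n_z = int(height / spacing) + 1
        c = (np.arange(n_xy) - (n_xy - 1) / 2) * spacing
        cz = (np.arange(n_z) - (n_z - 1) / 2) * spacing
        x, y, z = np.meshgrid(c, c, cz, indexing="ij")
        m = x**2 + y**2 <= radius**2
        return Volume(m.astype(np.uint8), spacing=spacing,
                      origin=(c[0], c[0], cz[0]))

    def test_cylinder_perimeter(self):
        vol = self._cylinder(12.0)
        pl = Plane((0, 0, 0), (0, 0, 1))
        p = cross_section_perimeter(vol, pl)
        assert p == pytest.approx(2 * np.pi * 12.0, rel=0.05)

    def test_square_prism_perimeter(self):
        a = 14.0
        n = 50
        vals = np.zeros((n, n, 20), dtype=np.uint8)
        vals[8:8 + 28, 8:8 + 28, :] = 1  # 28 voxels * 0.5 mm = 14 mm side
        vol = Volume(vals, spacing=0.5, origin=(0, 0, 0))
        pl = Plane((12.0, 12.0, 5.0), (0, 0, 1))
        p = cross_section_perimeter(vol, pl)
        assert p == pytest.approx(4 * a, rel=0.05)

    def test_in_plane_basis_invariance(self):
        """Perimeter is stable (~2%) under rotation of the plane's 2D basis."""
        vol = self._cylinder(10.0, spacing=0.5)
        base = cross_section_perimeter(vol, Plane((0, 0, 0), (0, 0, 1)))
        tilted = cross_section_perimeter(
            vol, Plane((0, 0, 0), (1e-3, 2e-3, 1.0)))
        assert tilted == pytest.approx(base, rel=0.02)

    def test_no_intersection_rejected(self):
        vol = self._cylinder(8.0)
        with pytest.raises(ValueError):
            cross_section_perimeter(vol, Plane((0, 0, 100.0), (0, 0, 1)))


class TestMeasureAll:
    def test_phantom_recovery_within_tolerances(self, default_phantom):
        """All 19 values match the analytic truth: lengths within 2 voxels,
        perimeters and geodesics within 5%."""
        spec, labels, truth = default_phantom
        rep = measure_all(labels, truth.landmarks)
        for key in MEASUREMENT_KEYS:
            got, want = rep[key], truth.measurements[key]
            if length_tol(key):
                assert got == pytest.approx(want, rel=0.05), key
            else:
                assert got == pytest.approx(want, abs=2 * spec.voxel_spacing), key

    def test_commissure_example_three_four_five(self):
        assert np.linalg.norm(np.array([3.0, 4.0, 0.0])) == pytest.approx(5.0)

    def test_rigid_motion_invariance(self, default_phantom):
        """Rotating labels + landmarks leaves all 19 values within 2%."""
        from scipy.spatial.transform import Rotation

        from valvemorph.volume import resample_to_grid
        spec, labels, truth = default_phantom
        rot = Rotation.from_euler("xyz", [12, -9, 25], degrees=True)
        R = rot.as_matrix()
        shift = np.array([3.0, -2.0, 1.5])
        rotated = Volume(labels.values, spacing=labels.spacing,
                         origin=R @ labels.origin + shift,
                         direction=R @ labels.direction)
        # resample onto a finer axis-aligned grid: nearest interpolation at
        # the source spacing would erode the thin cusps a second time
        resampled = resample_to_grid(rotated, rotated.center, 0.4, 150,
                                     pad_value=0, interpolation="nearest")
        lm_rot = truth.landmarks.transformed(lambda p: R @ p + shift)
        base = measure_all(labels, truth.landmarks)
        moved = measure_all(resampled, lm_rot)
        for key in MEASUREMENT_KEYS:
            assert moved[key] == pytest.approx(base[key], rel=0.02), key

    def test_phantom_scaling_scales_measurements(self):
        """Scaling the phantom geometry by k scales every value by k (2%)."""
        k = 1.25
        base_spec = PhantomSpec(grid_size=96)
        scaled_spec = PhantomSpec(
            lvot_radius=12.0 * k, nadir_ring_radius=14.0 * k,
            commissure_ring_radius=13.0 * k, nadir_height=-5.0 * k,
            commissure_height=5.0 * k, stj_height=10.0 * k,
            sinus_bulge=2.5 * k, ostium_heights=(8.0 * k, 7.0 * k),
            grid_size=128)
        _, t_base = build_phantom(base_spec)
        _, t_scaled = build_phantom(scaled_spec)
        base = t_base.measurements.as_array()
        scaled = t_scaled.measurements.as_array()
        # LVOT stub depth is fixed, not scaled, so insertion geometry is exact
        assert np.allclose(scaled, k * base, rtol=0.02)

    def test_eh_not_exceeding_gh_on_planar_phantom(self, default_phantom):
        _, labels, truth = default_phantom
        rep = measure_all(labels, truth.landmarks)
        for c in ("rcc", "lcc", "ncc"):
            assert rep[f"effective_height_{c}"] <= rep[f"geometric_height_{c}"] + 1e-6

    def test_report_requires_all_items(self):
        with pytest.raises(ValueError):
            MeasurementReport({"effective_height_rcc": 1.0})
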