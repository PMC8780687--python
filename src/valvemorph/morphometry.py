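"""The eight aortic-valve measurement items (19 values) from labels + landmarks.

Given a post-processed multi-label volume (0 background, 1 aortic root,
2 RCC, 3 LCC, 4 NCC) and the eight landmarks, this module computes, all in
mm:

* effective height eH  — straight distance from the Arantius body (midpoint
  of the free margin) to the nadir plane, per cusp;
* geometric height gH  — shortest path along the cusp surface from the
  Arantius body to the hinge point, per cusp;
* cusp insertion length ciL — arc length of the cusp rim in contact with
  the sinus wall, commissure to commissure, per cusp;
* free margin length FML — arc length of the non-contacting rim arc;
* commissural distances comD — straight distances between commissure pairs;
* nadir / commissure ring perimeters NRP, CRP — perimeter of the root
  cross-section on the nadir plane and the commissure plane;
* coronary heights corH — straight distance from each coronary ostium to
  the nadir plane.

Orientation convention: all planes carry a unit normal pointing toward the
sinotubular junction (+aorta) side; "most LVOT-ward" therefore means
minimal signed plane distance.  Heights are reported as absolute values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure as skmeasure

from .landmarks import CUSP_COMMISSURES, CUSP_LABELS, LandmarkSet
from .metrics import surface_points
from .sheet import SheetModel, _smooth_closed, fit_sheet
from .volume import Volume

__all__ = [
    "Plane",
    "CuspBoundary",
    "MeasurementReport",
    "MEASUREMENT_KEYS",
    "fit_plane",
    "point_plane_distance",
    "polyline_arclength",
    "arc_midpoint",
    "hinge_point",
    "split_cusp_boundary",
    "surface_geodesic",
    "cross_section_perimeter",
    "measure_all",
    "combine_labels",
]


# ---------------------------------------------------------------------------
# Planes and polylines
# ---------------------------------------------------------------------------

@dataclass
class Plane:
    """Oriented plane: a point on it and a unit normal (toward the STJ side)."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("plane normal must be nonzero")
        self.normal = n / norm

    def signed_distance(self, pts) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - self.point) @ self.normal

    def to_dict(self) -> dict:
        return {"point": self.point.tolist(), "normal": self.normal.tolist()}

    @classmethod
    def from_dict(cls, d) -> "Plane":
        return cls(np.asarray(d["point"]), np.asarray(d["normal"]))


def fit_plane(p1, p2, p3, toward=None) -> Plane:
    """Plane through three points.

    If ``toward`` is given the normal is oriented so that point lies on the
    positive side (measure_all passes the commissure centroid, putting the
    STJ side up).  Otherwise a deterministic sign convention (+z, then +y,
    then +x) is applied, so permuting the inputs leaves the oriented plane
    unchanged.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float).reshape(3) for p in (p1, p2, p3))
    n = np.cross(p2 - p1, p3 - p1)
    scale = max(np.linalg.norm(p2 - p1), np.linalg.norm(p3 - p1), 1.0)
    if np.linalg.norm(n) < 1e-9 * scale**2:
        raise ValueError("points are collinear; no unique plane")
    n = n / np.linalg.norm(n)
    centroid = (p1 + p2 + p3) / 3.0
    if toward is not None:
        s = float((np.asarray(toward, dtype=float) - centroid) @ n)
        if s < 0:
            n = -n
    else:
        for c in (2, 1, 0):
            if abs(n[c]) > 1e-12:
                if n[c] < 0:
                    n = -n
                break
    return Plane(centroid, n)


def point_plane_distance(p, plane: Plane, mode: str = "absolute") -> float:
    """Distance from a point to a plane; ``signed`` keeps the normal's sign."""
    d = float(plane.signed_distance(np.asarray(p, dtype=float).reshape(3)))
    if mode == "absolute":
        return abs(d)
    if mode == "signed":
        return d
    raise ValueError(f"unknown mode {mode!r}; use 'absolute' or 'signed'")


def polyline_arclength(path) -> float:
    """Sum of segment lengths of an ordered mm polyline."""
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or len(path) < 2:
        raise ValueError("polyline needs at least 2 points")
    return float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)))


def arc_midpoint(path) -> np.ndarray:
    """Point at half arc length, interpolated on the containing segment."""
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or len(path) < 2:
        raise ValueError("polyline needs at least 2 points")
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    half = cum[-1] / 2.0
    k = int(np.searchsorted(cum, half, side="right") - 1)
    k = min(k, len(seg) - 1)
    t = 0.0 if seg[k] == 0 else (half - cum[k]) / seg[k]
    return path[k] + t * (path[k + 1] - path[k])


def hinge_point(attached_path, nadir_plane: Plane) -> np.ndarray:
    """Most LVOT-ward point of the insertion polyline (minimal signed
    distance to the nadir plane); ties go to the first point along the path.
    Typically this coincides with the cusp's nadir landmark."""
    path = np.asarray(attached_path, dtype=float)
    if path.ndim != 2 or len(path) == 0:
        raise ValueError("attached path must be a nonempty polyline")
    s = nadir_plane.signed_distance(path)
    return path[int(np.argmin(s))]


# ---------------------------------------------------------------------------
# Measurement report
# ---------------------------------------------------------------------------

MEASUREMENT_KEYS = (
    "effective_height_rcc", "effective_height_lcc", "effective_height_ncc",
    "geometric_height_rcc", "geometric_height_lcc", "geometric_height_ncc",
    "cusp_insertion_length_rcc", "cusp_insertion_length_lcc", "cusp_insertion_length_ncc",
    "free_margin_length_rcc", "free_margin_length_lcc", "free_margin_length_ncc",
    "commissural_distance_rl_rn", "commissural_distance_rl_ln", "commissural_distance_ln_rn",
    "nadir_ring_perimeter", "commissure_ring_perimeter",
    "coronary_height_right", "coronary_height_left",
)


@dataclass
class MeasurementReport:
    """The 19 valve-morphology values, all in mm."""

    values: dict

    def __post_init__(self):
        missing = [k for k in MEASUREMENT_KEYS if k not in self.values]
        if missing:
            raise ValueError(f"missing measurement items: {missing}")
        self.values = {k: float(self.values[k]) for k in MEASUREMENT_KEYS}

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in MEASUREMENT_KEYS])

    def to_dict(self) -> dict:
        return dict(self.values)

    @classmethod
    def from_dict(cls, d: dict) -> "MeasurementReport":
        return cls({k: d[k] for k in MEASUREMENT_KEYS})

    def save(self, path) -> None:
        path = str(path)
        if path.endswith(".csv"):
            with open(path, "w") as fh:
                fh.write(",".join(MEASUREMENT_KEYS) + "\n")
                fh.write(",".join(f"{self.values[k]:.6g}" for k in MEASUREMENT_KEYS) + "\n")
        else:
            with open(path, "w") as fh:
                json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# Cusp boundary
# ---------------------------------------------------------------------------

@dataclass
class CuspBoundary:
    """The cusp rim split at the commissures.

    ``attached`` runs commissure -> commissure along the wall contact (the
    insertion line, through the hinge/nadir); ``free`` is the complementary
    arc through the Arantius position.  Both polylines share the exact
    commissure endpoints.
    """

    attached: np.ndarray
    free: np.ndarray

    def __post_init__(self):
        self.attached = np.asarray(self.attached, dtype=float)
        self.free = np.asarray(self.free, dtype=float)


def _split_rim(sheet: SheetModel, wall_tree: cKDTree, c1, c2,
               contact_tol: float):
    """Split the sheet rim at the two commissure-nearest vertices.

    Returns (attached, free) mm polylines anchored on the exact commissure
    coordinates.  Voxelizing a thin slab dilates its in-plane support by
    half the slab thickness in every rim direction, so the whole rim
    contour is first offset inward by half the estimated thickness to
    recover the mid-surface boundary.
    """
    rim_ij = sheet.rim_ij()
    inward = sheet.inward_normals_ij(rim_ij)
    rim_ij = rim_ij + inward * ((sheet.thickness / 2.0) / sheet.bin_size)
    rim_xyz = sheet.ij_to_xyz(rim_ij)
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    i1 = int(np.argmin(np.linalg.norm(rim_xyz - c1, axis=1)))
    i2 = int(np.argmin(np.linalg.norm(rim_xyz - c2, axis=1)))
    if i1 == i2:
        raise ValueError(
            "rim cannot be split into exactly two arcs: both commissures "
            "snap to the same rim vertex")
    swap = i1 > i2
    if swap:
        i1, i2 = i2, i1
        c1, c2 = c2, c1
    arc_a = rim_ij[i1:i2 + 1]
    arc_b = np.vstack([rim_ij[i2:], rim_ij[:i1 + 1]])

    def _mean_wall_distance(ij):
        xyz = sheet.ij_to_xyz(ij)
        return float(np.mean(wall_tree.query(xyz)[0]))

    if _mean_wall_distance(arc_a) <= _mean_wall_distance(arc_b):
        att_ij, free_ij = arc_a, arc_b
        att_ends, free_ends = (c1, c2), (c2, c1)
    else:
        att_ij, free_ij = arc_b, arc_a
        att_ends, free_ends = (c2, c1), (c1, c2)

    attached = np.vstack([att_ends[0], sheet.ij_to_xyz(att_ij), att_ends[1]])
    free = np.vstack([free_ends[0], sheet.ij_to_xyz(free_ij), free_ends[1]])
    contact = wall_tree.query(sheet.ij_to_xyz(att_ij))[0]
    meta = {
        "attached_contact_fraction": float(np.mean(contact <= contact_tol)),
        "thickness_mm": sheet.thickness,
    }
    return attached, free, meta


def split_cusp_boundary(cusp: Volume, root: Volume, commissures,
                        contact_tol: float | None = None) -> CuspBoundary:
    """Split a post-processed cusp's rim into insertion and free-margin arcs.

    ``commissures`` is the pair of mm commissure points flanking this cusp;
    ``root`` is the (label >= 1) aortic-root region on the same grid, whose
    surface defines wall contact (a rim point counts as contacting within
    ``contact_tol``, default 1.5x the voxel spacing).
    """
    if not cusp.same_grid(root):
        raise ValueError("cusp and root masks must share one grid")
    if contact_tol is None:
        contact_tol = 1.5 * float(np.max(cusp.spacing))
    sheet = fit_sheet(cusp)
    wall_tree = cKDTree(surface_points(root))
    c1, c2 = commissures
    attached, free, _ = _split_rim(sheet, wall_tree, c1, c2, contact_tol)
    return CuspBoundary(attached=attached, free=free)


def surface_geodesic(cusp: Volume, a, b, snap_tol: float | None = None) -> float:
    """Shortest on-surface path length (mm) between two points near the cusp.

    Both endpoints must lie within ``snap_tol`` (default 2x voxel spacing)
    of the cusp's mid-surface; they are snapped to the nearest surface node
    and connected by a Dijkstra path on the mid-surface grid graph.
    """
    if snap_tol is None:
        snap_tol = 2.0 * float(np.max(cusp.spacing))
    sheet = fit_sheet(cusp)
    return sheet.geodesic(a, b, snap_tol)


# ---------------------------------------------------------------------------
# Cross-section perimeter
# ---------------------------------------------------------------------------

def _plane_basis(normal: np.ndarray) -> tuple:
    axis = np.argmin(np.abs(normal))
    e = np.zeros(3)
    e[axis] = 1.0
    u = np.cross(normal, e)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return u, v


def cross_section_perimeter(root: Volume, plane: Plane,
                            resolution: float | None = None) -> float:
    """Perimeter (mm) of the root's cross-section contour on a plane.

    The mask is resliced onto an in-plane 2D grid (half the finest voxel
    spacing by default, which recovers the sub-voxel boundary position the
    trilinear field carries) with linear interpolation, the largest 2D
    component kept, and its outer contour extracted at the 0.5 level with
    sub-pixel precision.  Smoothing scales are fixed in mm (0.3 mm on the
    resliced field, 0.5 mm along the contour polyline) so the estimate is
    resolution-consistent: enough to suppress voxelization wiggle, which
    otherwise inflates arc length, without eroding anatomical lobes.
    """
    if resolution is None:
        resolution = float(np.min(root.spacing)) / 2.0
    u, v = _plane_basis(plane.normal)
    idx = np.argwhere(root.values > 0)
    if len(idx) == 0:
        raise ValueError("root mask is empty")
    corners_idx = np.array(np.meshgrid(*[(lo, hi) for lo, hi in
                                         zip(idx.min(0), idx.max(0))],
                                       indexing="ij")).reshape(3, -1).T
    corners = root.index_to_physical(corners_idx.astype(float)) - plane.point
    margin = 3 * resolution
    uu = np.arange(float((corners @ u).min()) - margin,
                   float((corners @ u).max()) + margin, resolution)
    vv = np.arange(float((corners @ v).min()) - margin,
                   float((corners @ v).max()) + margin, resolution)
    U, V = np.meshgrid(uu, vv, indexing="ij")
    pts = plane.point + U[..., None] * u + V[..., None] * v
    ijk = root.physical_to_index(pts.reshape(-1, 3)).T
    field = ndimage.map_coordinates(root.values.astype(np.float32), ijk,
                                    order=1, cval=0.0).reshape(U.shape)
    field = ndimage.gaussian_filter(field, 0.3 / resolution)
    binary = field >= 0.5
    if not binary.any():
        raise ValueError("plane does not intersect the root region")
    lab, n = ndimage.label(binary, structure=np.ones((3, 3)))
    if n > 1:
        counts = np.bincount(lab.ravel())[1:]
        keep = int(np.argmax(counts)) + 1
        field = np.where((lab == keep) | ~binary, field, 0.0)
    contours = skmeasure.find_contours(field, 0.5)
    if not contours:
        raise ValueError("no cross-section contour found")

    def _area(c):
        x, y = c[:, 0], c[:, 1]
        return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    outer = contours[int(np.argmax([_area(c) for c in contours]))]
    if np.allclose(outer[0], outer[-1]):
        outer = outer[:-1]
    vertex_mm = float(np.linalg.norm(
        np.diff(np.vstack([outer, outer[:1]]), axis=0), axis=1).mean()) * resolution
    outer = _smooth_closed(outer, sigma=0.5 / max(vertex_mm, 1e-6))
    closed = np.vstack([outer, outer[:1]])
    return polyline_arclength(closed) * resolution


# ---------------------------------------------------------------------------
# measure_all
# ---------------------------------------------------------------------------

def combine_labels(root: Volume, cusps: Volume) -> Volume:
    """Merge a {0,1} root mask and a {0,2,3,4} cusp volume into 5 classes."""
    if not root.same_grid(cusps):
        raise ValueError("root and cusp volumes must share one grid")
    merged = np.where(cusps.values > 0, cusps.values,
                      (root.values > 0).astype(cusps.values.dtype))
    return root.with_values(merged.astype(np.uint8))


def measure_all(labels: Volume, landmarks: LandmarkSet,
                contact_tol: float | None = None,
                resolution: float | None = None) -> MeasurementReport:
    """All 19 morphology values from a 5-class label volume + landmarks.

    The root region for ring perimeters and wall contact is the union of
    labels >= 1 (the cusps lie inside the annotated root).  Raised errors
    name the measurement item that failed.
    """
    vals = {}
    root_region = labels.with_values((labels.values >= 1).astype(np.uint8))
    if contact_tol is None:
        contact_tol = 1.5 * float(np.max(labels.spacing))

    nadirs = [landmarks[f"nadir_{c}"] for c in ("rcc", "lcc", "ncc")]
    comm_names = ("commissure_rl", "commissure_rn", "commissure_ln")
    comms = {n: landmarks[n] for n in comm_names}
    comm_centroid = np.mean(list(comms.values()), axis=0)
    nadir_plane = fit_plane(*nadirs, toward=comm_centroid)
    nadir_centroid = np.mean(nadirs, axis=0)
    stj_side = comm_centroid + (comm_centroid - nadir_centroid)
    commissure_plane = fit_plane(*comms.values(), toward=stj_side)

    wall_tree = cKDTree(surface_points(root_region))

    for cusp_name, label in CUSP_LABELS.items():
        mask = labels.with_values((labels.values == label).astype(np.uint8))
        c1n, c2n = CUSP_COMMISSURES[cusp_name]
        try:
            sheet = fit_sheet(mask)
            attached, free, _ = _split_rim(sheet, wall_tree,
                                           landmarks[c1n], landmarks[c2n],
                                           contact_tol)
        except ValueError as exc:
            raise ValueError(
                f"boundary split failed for cusp {cusp_name} "
                f"(ciL/FML/eH/gH): {exc}") from exc
        vals[f"cusp_insertion_length_{cusp_name}"] = polyline_arclength(attached)
        vals[f"free_margin_length_{cusp_name}"] = polyline_arclength(free)
        arantius = arc_midpoint(free)
        hinge = hinge_point(attached, nadir_plane)
        vals[f"effective_height_{cusp_name}"] = point_plane_distance(
            arantius, nadir_plane, "absolute")
        try:
            snap_tol = 2.0 * float(np.max(labels.spacing))
            vals[f"geometric_height_{cusp_name}"] = sheet.geodesic(
                arantius, hinge, snap_tol)
        except ValueError as exc:
            raise ValueError(
                f"geometric height failed for cusp {cusp_name}: {exc}") from exc

    vals["commissural_distance_rl_rn"] = float(
        np.linalg.norm(comms["commissure_rl"] - comms["commissure_rn"]))
    vals["commissural_distance_rl_ln"] = float(
        np.linalg.norm(comms["commissure_rl"] - comms["commissure_ln"]))
    vals["commissural_distance_ln_rn"] = float(
        np.linalg.norm(comms["commissure_ln"] - comms["commissure_rn"]))

    try:
        vals["nadir_ring_perimeter"] = cross_section_perimeter(
            root_region, nadir_plane, resolution)
    except ValueError as exc:
        raise ValueError(f"nadir ring perimeter failed: {exc}") from exc
    try:
        vals["commissure_ring_perimeter"] = cross_section_perimeter(
            root_region, commissure_plane, resolution)
    except ValueError as exc:
        raise ValueError(f"commissure ring perimeter failed: {exc}") from exc

    vals["coronary_height_right"] = point_plane_distance(
        landmarks["ostium_r"], nadir_plane, "absolute")
    vals["coronary_height_left"] = point_plane_distance(
        landmarks["ostium_l"], nadir_plane, "absolute")
    return MeasurementReport(vals)
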