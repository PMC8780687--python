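"""Mid-surface model of a thin voxelized sheet (a valve cusp).

A segmented cusp is a slab one-to-few voxels thick.  Measurements need its
*mid-surface*: we fit a PCA plane to the foreground voxel centers, bin the
in-plane coordinates at the voxel pitch, and store the mean out-of-plane
offset per bin as a height field.  This yields

* a 2D support raster whose sub-pixel 0.5-level contour is the sheet rim,
* a lifted 3D position for any (fractional) bin coordinate,
* a geodesic metric: Dijkstra on the support grid with neighbor offsets up
  to Chebyshev radius 3, so the graph metric overestimates true in-surface
  distances by at most ~1.5% (radius-1 grids err by up to ~8%).

The height-field representation assumes the sheet is a (possibly curved)
graph over its PCA plane — true for closed leaflets and moderately folded
open ones, not for sheets folded back on themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from skimage import measure as skmeasure

from .volume import Volume

__all__ = ["SheetModel", "fit_sheet", "grid_graph_geodesic"]


def _smooth_closed(polyline: np.ndarray, sigma: float) -> np.ndarray:
    """Circular Gaussian smoothing of a closed polyline's coordinates."""
    if len(polyline) < 8:
        return polyline
    return np.column_stack([
        ndimage.gaussian_filter1d(polyline[:, k], sigma, mode="wrap")
        for k in range(polyline.shape[1])
    ])


def _neighbor_offsets(radius: int):
    """Half-set of 2D integer offsets within a Chebyshev radius."""
    offs = []
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            if (di, dj) == (0, 0):
                continue
            if di > 0 or (di == 0 and dj > 0):
                offs.append((di, dj))
    return offs


def grid_graph_geodesic(xyz: np.ndarray, support: np.ndarray,
                        src_ij, dst_ij, radius: int = 3) -> float:
    """Shortest-path length between two grid nodes of a surface mesh.

    ``xyz`` has shape (ni, nj, 3); ``support`` marks valid nodes.  Edges
    connect support nodes whose offsets lie within the given Chebyshev
    radius; weights are straight 3D distances.
    """
    ni, nj = support.shape
    node_id = -np.ones((ni, nj), dtype=np.int64)
    node_id[support] = np.arange(int(support.sum()))
    rows, cols, wts = [], [], []
    for di, dj in _neighbor_offsets(radius):
        a = support[max(0, -di):ni - max(0, di), max(0, -dj):nj - max(0, dj)]
        b = support[max(0, di):ni - max(0, -di), max(0, dj):nj - max(0, -dj)]
        both = a & b
        if not both.any():
            continue
        ia, ja = np.nonzero(both)
        ia0, ja0 = ia + max(0, -di), ja + max(0, -dj)
        ib0, jb0 = ia0 + di, ja0 + dj
        d = np.linalg.norm(xyz[ia0, ja0] - xyz[ib0, jb0], axis=1)
        rows.append(node_id[ia0, ja0])
        cols.append(node_id[ib0, jb0])
        wts.append(d)
    n = int(support.sum())
    graph = coo_matrix(
        (np.concatenate(wts), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    i_src = int(node_id[tuple(src_ij)])
    i_dst = int(node_id[tuple(dst_ij)])
    if i_src < 0 or i_dst < 0:
        raise ValueError("endpoints must be support nodes")
    dist = dijkstra(graph, directed=False, indices=i_src)
    d = float(dist[i_dst])
    if not np.isfinite(d):
        raise ValueError("surface is disconnected between the endpoints")
    return d


@dataclass
class SheetModel:
    """Fitted mid-surface of a thin sheet mask."""

    basis: np.ndarray        # rows e1, e2, n (orthonormal)
    center: np.ndarray       # mm
    bin_size: float          # mm per support bin
    uv0: np.ndarray          # uv (mm) of support bin (0, 0) center
    support: np.ndarray      # 2D bool
    height: np.ndarray       # 2D float, out-of-plane offset (mm), gap-filled
    thickness: float         # estimated slab thickness (mm)
    voxel_spacing: np.ndarray

    # -- coordinate transforms ---------------------------------------------
    def ij_to_uv(self, ij) -> np.ndarray:
        return self.uv0 + np.asarray(ij, dtype=float) * self.bin_size

    def ij_to_xyz(self, ij) -> np.ndarray:
        """Lift fractional bin coordinates (..., 2) onto the mid-surface."""
        ij = np.asarray(ij, dtype=float)
        flat = ij.reshape(-1, 2)
        h = ndimage.map_coordinates(self.height, flat.T, order=1, mode="nearest")
        uv = self.uv0 + flat * self.bin_size
        e1, e2, n = self.basis
        xyz = self.center + uv[:, :1] * e1 + uv[:, 1:2] * e2 + h[:, None] * n
        return xyz.reshape(ij.shape[:-1] + (3,))

    def xyz_to_ij(self, pts) -> np.ndarray:
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        uv = (pts - self.center) @ self.basis[:2].T
        return (uv - self.uv0) / self.bin_size

    # -- rim ---------------------------------------------------------------
    def rim_ij(self) -> np.ndarray:
        """Closed sub-pixel rim polyline in fractional bin coordinates.

        The contour is taken at the 0.5 level of a Gaussian-smoothed support
        field rather than the raw binary raster, and the resulting polyline
        is itself smoothed with a circular Gaussian window: the staircase
        contour of a binary raster overestimates arc length by up to ~15%,
        while the smoothed isoline tracks the true boundary position (the
        level-set shift of the smoothing is ~sigma^2 * curvature / 2, well
        below a bin for sheet-scale curvatures).
        """
        f = ndimage.gaussian_filter(self.support.astype(float), 1.0)
        contours = skmeasure.find_contours(f, 0.5)
        if not contours:
            contours = skmeasure.find_contours(self.support.astype(float), 0.5)
        if not contours:
            raise ValueError("sheet support has no rim contour")
        lengths = [np.sum(np.linalg.norm(np.diff(c, axis=0), axis=1)) for c in contours]
        rim = contours[int(np.argmax(lengths))]
        if np.allclose(rim[0], rim[-1]):
            rim = rim[:-1]
        return _smooth_closed(rim, sigma=1.5)

    def rim_xyz(self) -> np.ndarray:
        return self.ij_to_xyz(self.rim_ij())

    def inward_normals_ij(self, ij) -> np.ndarray:
        """Unit 2D directions at contour points, pointing into the support."""
        f = ndimage.gaussian_filter(self.support.astype(float), 1.5)
        gi, gj = np.gradient(f)
        ij = np.asarray(ij, dtype=float).reshape(-1, 2)
        vi = ndimage.map_coordinates(gi, ij.T, order=1, mode="nearest")
        vj = ndimage.map_coordinates(gj, ij.T, order=1, mode="nearest")
        v = np.stack([vi, vj], axis=1)
        norm = np.linalg.norm(v, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return v / norm

    # -- geodesics ----------------------------------------------------------
    @cached_property
    def _node_grid(self):
        ii, jj = np.meshgrid(np.arange(self.support.shape[0]),
                             np.arange(self.support.shape[1]), indexing="ij")
        xyz = self.ij_to_xyz(np.stack([ii, jj], axis=-1).astype(float))
        node_xyz = xyz[self.support]
        tree = cKDTree(node_xyz)
        return xyz, node_xyz, tree

    @cached_property
    def _graph_edges(self):
        """Radius-3 grid-graph edges over the support nodes."""
        support = self.support
        ni, nj = support.shape
        node_id = -np.ones((ni, nj), dtype=np.int64)
        node_id[support] = np.arange(int(support.sum()))
        xyz = self._node_grid[0]
        rows, cols, wts = [], [], []
        for di, dj in _neighbor_offsets(3):
            a = support[max(0, -di):ni - max(0, di), max(0, -dj):nj - max(0, dj)]
            b = support[max(0, di):ni - max(0, -di), max(0, dj):nj - max(0, -dj)]
            both = a & b
            if not both.any():
                continue
            ia, ja = np.nonzero(both)
            ia0, ja0 = ia + max(0, -di), ja + max(0, -dj)
            ib0, jb0 = ia0 + di, ja0 + dj
            rows.append(node_id[ia0, ja0])
            cols.append(node_id[ib0, jb0])
            wts.append(np.linalg.norm(xyz[ia0, ja0] - xyz[ib0, jb0], axis=1))
        return (np.concatenate(rows), np.concatenate(cols), np.concatenate(wts))

    def snap(self, point, snap_tol: float) -> np.ndarray:
        """Nearest mid-surface node to a mm point; error beyond ``snap_tol``."""
        _, node_xyz, tree = self._node_grid
        d, k = tree.query(np.asarray(point, dtype=float))
        if d > snap_tol:
            raise ValueError(
                f"point {np.asarray(point)} is {d:.2f} mm from the sheet "
                f"(snap tolerance {snap_tol:.2f} mm)")
        return node_xyz[k]

    def geodesic(self, a, b, snap_tol: float) -> float:
        """Graph-geodesic distance (mm) between two points near the sheet.

        The endpoints themselves join the grid graph (edges to all support
        nodes within the neighbor radius), so the result carries no
        snap-to-node quantization beyond the graph's ~1.5% metric error.
        """
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        _, node_xyz, tree = self._node_grid
        for p in (a, b):
            self.snap(p, snap_tol)
        if np.linalg.norm(a - b) < 1e-12:
            return 0.0
        rows, cols, wts = self._graph_edges
        n = len(node_xyz)
        reach = 3.5 * self.bin_size + snap_tol
        er, ec, ew = [rows], [cols], [wts]
        for extra_id, p in ((n, a), (n + 1, b)):
            nb = tree.query_ball_point(p, reach)
            if not nb:
                nb = [int(tree.query(p)[1])]
            nb = np.asarray(nb, dtype=np.int64)
            er.append(np.full(len(nb), extra_id, dtype=np.int64))
            ec.append(nb)
            ew.append(np.linalg.norm(node_xyz[nb] - p, axis=1))
        graph = coo_matrix(
            (np.concatenate(ew), (np.concatenate(er), np.concatenate(ec))),
            shape=(n + 2, n + 2)).tocsr()
        dist = dijkstra(graph, directed=False, indices=n)
        d = float(dist[n + 1])
        if not np.isfinite(d):
            raise ValueError("surface is disconnected between the endpoints")
        return d


def fit_sheet(mask: Volume, bin_size: float | None = None) -> SheetModel:
    """Fit the mid-surface model to a thin binary sheet mask."""
    pts = mask.foreground_points()
    if len(pts) < 8:
        raise ValueError("sheet mask has too few voxels to fit a mid-surface")
    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center, full_matrices=False)
    basis = vt.copy()
    # deterministic sign convention
    for k in range(3):
        m = np.argmax(np.abs(basis[k]))
        if basis[k][m] < 0:
            basis[k] = -basis[k]
    if bin_size is None:
        bin_size = float(np.min(mask.spacing))

    uvw = (pts - center) @ basis.T
    uv, w = uvw[:, :2], uvw[:, 2]
    uv0 = uv.min(axis=0) - 2 * bin_size
    dims = np.floor((uv.max(axis=0) - uv0) / bin_size).astype(int) + 3
    ij = np.floor((uv - uv0) / bin_size + 0.5).astype(int)

    count = np.zeros(dims)
    hsum = np.zeros(dims)
    np.add.at(count, (ij[:, 0], ij[:, 1]), 1.0)
    np.add.at(hsum, (ij[:, 0], ij[:, 1]), w)
    sampled = count > 0
    support = ndimage.binary_closing(sampled, structure=np.ones((3, 3)))
    support |= sampled
    support = ndimage.binary_fill_holes(support)

    height = np.zeros(dims)
    height[sampled] = hsum[sampled] / count[sampled]
    # nearest-sample fill outside the sampled bins, then mild smoothing
    ind = ndimage.distance_transform_edt(~sampled, return_distances=False,
                                         return_indices=True)
    height = height[tuple(ind)]
    height = ndimage.uniform_filter(height, size=3)

    # slab thickness from the out-of-plane residual spread: a uniform slab
    # of thickness t has residual variance t^2/12 about its mid-surface
    resid = w - height[ij[:, 0], ij[:, 1]]
    t_var = float(np.sqrt(12.0) * np.std(resid))
    if t_var <= 0:  # degenerate (single voxel layer): fall back to volume/area
        voxel_vol = float(np.prod(mask.spacing))
        t_var = len(pts) * voxel_vol / (float(support.sum()) * bin_size**2)
    return SheetModel(basis=basis, center=center, bin_size=float(bin_size),
                      uv0=uv0, support=support, height=height,
                      thickness=t_var, voxel_spacing=np.asarray(mask.spacing))
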