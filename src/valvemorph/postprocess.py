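"""Label clean-up operators applied after segmentation.

Three operators, each idempotent:

* ``keep_largest_component`` — a single anatomical structure should be one
  connected region; everything but the largest component is removed.
* ``fill_holes`` — interior cavities (background pockets not connected to
  the volume border) become foreground.  This is a border-connected
  background flood fill: it closes cavities, the named failure mode, and
  deliberately leaves through-tunnels intact (exact topological hole
  closing is an optional extension, not implemented).
* ``extend_insertion_line`` — a cusp's insertion line must connect with the
  vessel wall inside the sinus of Valsalva; rim stretches that stop short
  of the wall (by at most ``max_gap``) are bridged outward along the sheet
  plane, adding voxels only inside the root region.

Connectivity pairing: 26-connectivity for foreground components,
6-connectivity for the background flood fill (the standard complementary
pair that avoids topological paradoxes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .metrics import surface_points
from .sheet import fit_sheet
from .volume import Volume

__all__ = [
    "keep_largest_component",
    "fill_holes",
    "extend_insertion_line",
    "ExtendReport",
    "postprocess_cusps",
]

_CONN = {6: ndimage.generate_binary_structure(3, 1),
         26: ndimage.generate_binary_structure(3, 3)}


def keep_largest_component(mask: Volume, connectivity: int = 26) -> Volume:
    """Keep only the largest connected component of a binary mask.

    Ties between equal-size components break toward the component
    containing the smallest flat (C-order) voxel index.  An empty mask is
    returned unchanged with a warning.
    """
    if connectivity not in _CONN:
        raise ValueError("connectivity must be 6 or 26")
    m = mask.values > 0
    if not m.any():
        warnings.warn("keep_largest_component: mask is empty")
        return mask.with_values(m.astype(np.uint8))
    lab, n = ndimage.label(m, structure=_CONN[connectivity])
    if n == 1:
        return mask.with_values(m.astype(np.uint8))
    flat = lab.ravel()
    ids, first_idx = np.unique(flat, return_index=True)
    counts = np.bincount(flat)
    sel = ids != 0
    ids, first_idx, counts = ids[sel], first_idx[sel], counts[ids[sel]]
    best = counts == counts.max()
    keep = ids[best][np.argmin(first_idx[best])]
    return mask.with_values((lab == keep).astype(np.uint8))


def fill_holes(mask: Volume) -> Volume:
    """Fill interior cavities (6-connected background flood from the border)."""
    filled = ndimage.binary_fill_holes(mask.values > 0, structure=_CONN[6])
    return mask.with_values(filled.astype(np.uint8))


@dataclass
class ExtendReport:
    """Outcome of :func:`extend_insertion_line`."""

    n_bridged: int = 0
    n_unbridged: int = 0
    added_voxels: int = 0
    unbridged_points: list = field(default_factory=list)

    @property
    def fully_connected(self) -> bool:
        return self.n_unbridged == 0


def extend_insertion_line(cusp: Volume, root: Volume,
                          max_gap: float = 2.0) -> tuple:
    """Bridge gaps between a cusp's rim and the root wall.

    For every rim point of the cusp's mid-surface that is not already in
    wall contact, the sheet is extended outward along its in-plane normal
    until it meets the root-region boundary; gaps larger than ``max_gap``
    (mm) are reported in the :class:`ExtendReport` rather than bridged
    (the free margin is legitimately off the wall).  Added voxels always
    lie inside the root region, so the output is a superset of the input
    confined to the lumen.

    The extension runs to a fixpoint internally (a bridged stretch can
    expose further rim to bridge), which makes the operator idempotent.

    Returns ``(extended_mask, report)``.
    """
    if not cusp.same_grid(root):
        raise ValueError("cusp and root masks must share one grid")
    cv = cusp.values > 0
    rv = root.values > 0
    if cv.any() and not (cv & rv).any():
        raise ValueError("cusp lies entirely outside the root region")
    wall_pts = surface_points(root)
    wall_tree = cKDTree(wall_pts)

    report = ExtendReport()
    total_before = int(cv.sum())
    for _ in range(8):
        cur = cusp.with_values(cv.astype(np.uint8))
        cv_new, n_bridged, unbridged = _extend_once(cur, rv, wall_tree, max_gap)
        report.n_bridged += n_bridged
        report.n_unbridged = len(unbridged)
        report.unbridged_points = unbridged
        if cv_new.sum() == cv.sum():
            break
        cv = cv_new
    report.added_voxels = int(cv.sum()) - total_before
    return cusp.with_values(cv.astype(np.uint8)), report


def _extend_once(cusp: Volume, rv: np.ndarray, wall_tree: cKDTree,
                 max_gap: float):
    """One outward-bridging sweep; returns (mask, n_bridged, unbridged pts)."""
    cv = cusp.values > 0
    spacing = float(np.max(cusp.spacing))
    contact_tol = 1.5 * spacing

    sheet = fit_sheet(cusp)
    rim_ij = sheet.rim_ij()
    outward = -sheet.inward_normals_ij(rim_ij)
    rim_xyz = sheet.ij_to_xyz(rim_ij)
    e1, e2, _ = sheet.basis
    out_xyz = outward[:, :1] * e1 + outward[:, 1:2] * e2
    norms = np.linalg.norm(out_xyz, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    out_xyz /= norms

    n_bridged = 0
    unbridged = []
    new = cv.copy()
    half_t = sheet.thickness / 2.0
    step = spacing / 2.0
    n_steps = int(np.ceil(max_gap / step))
    stamp_r = max(half_t, float(np.min(cusp.spacing)) * 0.75)

    d0 = wall_tree.query(rim_xyz)[0]
    for p, u, d_init in zip(rim_xyz, out_xyz, d0):
        if d_init <= contact_tol:
            continue  # already contacting the wall
        bridged = False
        trail = []
        for k in range(1, n_steps + 1):
            q = p + u * (k * step)
            idx = np.round(cusp.physical_to_index(q)).astype(int)
            if np.any(idx < 0) or np.any(idx >= np.array(cusp.shape)):
                break
            if not rv[tuple(idx)]:
                # reached the lumen boundary: that *is* the wall at voxel scale
                bridged = len(trail) > 0
                break
            trail.append(q)
            if wall_tree.query(q)[0] <= contact_tol:
                bridged = True
                break
        if bridged and trail:
            n_bridged += 1
            for q in trail:
                lo = np.maximum(np.floor(cusp.physical_to_index(q - stamp_r)).astype(int), 0)
                hi = np.minimum(np.ceil(cusp.physical_to_index(q + stamp_r)).astype(int),
                                np.array(cusp.shape) - 1)
                grids = np.mgrid[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
                sub_idx = grids.reshape(3, -1).T
                pts = cusp.index_to_physical(sub_idx.astype(float))
                near = np.linalg.norm(pts - q, axis=1) <= stamp_r
                inside = rv[sub_idx[near, 0], sub_idx[near, 1], sub_idx[near, 2]]
                tgt = sub_idx[near][inside]
                new[tgt[:, 0], tgt[:, 1], tgt[:, 2]] = True
        elif not bridged:
            unbridged.append(p.tolist())
    return new, n_bridged, unbridged


def postprocess_cusps(cusps: Volume, root: Volume,
                      max_gap: float = 2.0) -> tuple:
    """Full cusp clean-up: per label, largest component, hole filling, and
    insertion-line extension against the root region.

    ``cusps`` carries the cusp label codes (e.g. {0, 2, 3, 4}); returns the
    cleaned volume and a dict of :class:`ExtendReport` per label.
    """
    out = np.zeros_like(cusps.values)
    reports = {}
    for code in sorted(int(c) for c in np.unique(cusps.values) if c != 0):
        m = cusps.with_values((cusps.values == code).astype(np.uint8))
        m = keep_largest_component(m)
        m = fill_holes(m)
        if m.values.any():
            m, rep = extend_insertion_line(m, root, max_gap=max_gap)
            reports[code] = rep
        out[m.values > 0] = code
    return cusps.with_values(out), reports
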