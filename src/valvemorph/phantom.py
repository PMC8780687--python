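"""Synthetic aortic-root phantom with analytic ground truth.

The phantom makes every downstream stage testable without clinical data:
it voxelizes a contrast-filled aortic root (LVOT stub, a conical frustum
between the nadir ring and the commissure ring, and a tube up to the
sinotubular junction with three outward sinus bulges), three thin
non-overlapping cusps meeting at three commissures, and produces the eight
landmarks and all 19 morphology values in closed/analytic form.

Geometry (all mm, world origin at the volume center, LVOT along -z):

* Commissures sit at azimuths 90, 210, 330 degrees on the commissure ring
  (radius ``commissure_ring_radius`` at z = ``commissure_height``); nadirs
  at azimuths 30, 150, 270 on the nadir ring.
* Each *closed* cusp is exactly the intersection of its plane (through the
  two flanking commissures and the nadir) with the frustum solid — a
  convex planar sector whose curved edge (the insertion line) lies exactly
  on the wall and whose straight edge is the free margin.  Geodesics on it
  are therefore straight lines and ciL/FML/eH/gH have closed or
  analytically-integrable forms.
* Sinus bulges scale with height above the local insertion line
  (amplitude sinus_bulge * sin(pi*u), u the normalized height between the
  insertion curve and the STJ), so they vanish exactly on the insertion
  line: the nadir-plane cross-section stays the circle of the nadir ring
  while the commissure-level contour carries the three sinuses.
* The *open* state folds each free margin radially outward toward the
  wall; the cusp becomes a ruled surface and its geometric height is
  computed with a fine-mesh Dijkstra oracle instead of a closed form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .landmarks import CUSP_LABELS, LandmarkSet
from .morphometry import MeasurementReport, Plane
from .sheet import grid_graph_geodesic
from .volume import PAD_HU, Volume, write_volume

__all__ = ["PhantomSpec", "PhantomTruth", "build_phantom", "phantom_intensity",
           "write_phantom"]

#: depth of the LVOT stub below the nadir ring (mm)
LVOT_STUB = 4.0
#: wall (myocardium) shell thickness for the intensity phantom (mm)
WALL_THICKNESS = 2.0
#: radial opening fraction of the free margin in the open state
OPEN_FRACTION = 0.65

_DEG = np.pi / 180.0
COMMISSURE_AZIMUTHS = {"commissure_rl": 90 * _DEG,
                       "commissure_ln": 210 * _DEG,
                       "commissure_rn": 330 * _DEG}
NADIR_AZIMUTHS = {"rcc": 30 * _DEG, "lcc": 150 * _DEG, "ncc": 270 * _DEG}
#: azimuth span of each cusp: (start commissure, end commissure), end = start + 120 deg
CUSP_SPANS = {"rcc": ("commissure_rn", "commissure_rl"),
              "lcc": ("commissure_rl", "commissure_ln"),
              "ncc": ("commissure_ln", "commissure_rn")}
OSTIUM_AZIMUTHS = {"ostium_r": NADIR_AZIMUTHS["rcc"],
                   "ostium_l": NADIR_AZIMUTHS["lcc"]}


@dataclass
class PhantomSpec:
    """Parameters of the synthetic aortic root (mm / HU)."""

    lvot_radius: float = 12.0
    nadir_ring_radius: float = 14.0
    commissure_ring_radius: float = 13.0
    nadir_height: float = -5.0
    commissure_height: float = 5.0
    stj_height: float = 10.0
    sinus_bulge: float = 2.5
    cusp_thickness: float = 1.2
    ostium_heights: tuple = (8.0, 7.0)   # (right, left) z coordinates
    voxel_spacing: float = 0.5
    grid_size: int = 112
    valve_state: str = "closed"
    calcium_blobs: list = field(default_factory=list)  # (center, radius, HU)
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("lvot_radius", "nadir_ring_radius", "commissure_ring_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (self.nadir_height < self.commissure_height < self.stj_height):
            raise ValueError(
                "nadir_height < commissure_height < stj_height is required, got "
                f"nadir_height={self.nadir_height}, commissure_height="
                f"{self.commissure_height}, stj_height={self.stj_height}")
        if self.sinus_bulge < 0:
            raise ValueError("sinus_bulge must be non-negative")
        if self.voxel_spacing <= 0:
            raise ValueError("voxel_spacing must be positive")
        if self.cusp_thickness < 2 * self.voxel_spacing:
            raise ValueError(
                f"cusp_thickness must be >= 2*voxel_spacing so cusps survive "
                f"voxelization; got cusp_thickness={self.cusp_thickness} at "
                f"voxel_spacing={self.voxel_spacing}")
        if self.grid_size < 16:
            raise ValueError("grid_size must be at least 16 voxels")
        if self.valve_state not in ("closed", "open"):
            raise ValueError(f"valve_state must be 'closed' or 'open', got "
                             f"{self.valve_state!r}")
        for z in self.ostium_heights:
            if not (self.nadir_height < z <= self.stj_height):
                raise ValueError(
                    "ostium_heights must lie between nadir_height and stj_height")
        for blob in self.calcium_blobs:
            _, _, hu = blob
            if hu <= 800:
                raise ValueError("calcium_blobs must specify HU > 800")
        half_extent = (self.grid_size - 1) / 2.0 * self.voxel_spacing
        r_needed = max(self.nadir_ring_radius, self.commissure_ring_radius,
                       self.lvot_radius) + self.sinus_bulge + WALL_THICKNESS
        z_needed = max(abs(self.nadir_height - LVOT_STUB), abs(self.stj_height)) \
            + WALL_THICKNESS
        if half_extent < max(r_needed, z_needed):
            raise ValueError(
                f"grid_size={self.grid_size} at voxel_spacing="
                f"{self.voxel_spacing} does not contain the root geometry "
                f"(needs half-extent {max(r_needed, z_needed):.1f} mm)")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["ostium_heights"] = list(self.ostium_heights)
        d["calcium_blobs"] = [[list(c), float(r), float(h)]
                              for c, r, h in self.calcium_blobs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "ostium_heights" in d:
            d["ostium_heights"] = tuple(d["ostium_heights"])
        if "calcium_blobs" in d:
            d["calcium_blobs"] = [(tuple(c), float(r), float(h))
                                  for c, r, h in d["calcium_blobs"]]
        return cls(**d)


@dataclass
class PhantomTruth:
    """Analytic ground truth of a phantom: landmarks, measurements, planes."""

    landmarks: LandmarkSet
    measurements: MeasurementReport
    nadir_plane: Plane
    stj_plane: Plane

    def to_dict(self) -> dict:
        return {
            "landmarks": self.landmarks.to_dict(),
            "measurements": self.measurements.to_dict(),
            "nadir_plane": self.nadir_plane.to_dict(),
            "stj_plane": self.stj_plane.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomTruth":
        return cls(
            landmarks=LandmarkSet.from_dict(d["landmarks"]),
            measurements=MeasurementReport.from_dict(d["measurements"]),
            nadir_plane=Plane.from_dict(d["nadir_plane"]),
            stj_plane=Plane.from_dict(d["stj_plane"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "PhantomTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Continuous geometry
# ---------------------------------------------------------------------------

class _RootGeometry:
    """Closed-form description of the continuous phantom."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        self.Hn, self.Hc, self.Hstj = (spec.nadir_height, spec.commissure_height,
                                       spec.stj_height)
        self.Rn, self.Rc = spec.nadir_ring_radius, spec.commissure_ring_radius
        self.z_bot = self.Hn - LVOT_STUB
        # frustum radius a + b*z between the nadir and commissure rings
        self.b = (self.Rc - self.Rn) / (self.Hc - self.Hn)
        self.a = self.Rn - self.b * self.Hn

        self.commissures = {
            name: np.array([self.Rc * np.cos(az), self.Rc * np.sin(az), self.Hc])
            for name, az in COMMISSURE_AZIMUTHS.items()}
        self.nadirs = {
            c: np.array([self.Rn * np.cos(az), self.Rn * np.sin(az), self.Hn])
            for c, az in NADIR_AZIMUTHS.items()}
        # cusp planes through (C1, C2, nadir)
        self.planes = {}
        for cusp, (c1n, c2n) in CUSP_SPANS.items():
            p1, p2 = self.commissures[c1n], self.commissures[c2n]
            nd = self.nadirs[cusp]
            n = np.cross(p2 - p1, nd - p1)
            n /= np.linalg.norm(n)
            self.planes[cusp] = (n, float(n @ p1))

    # -- insertion curve ----------------------------------------------------
    def attachment_z(self, cusp: str, theta) -> np.ndarray:
        """z of the cusp plane / frustum-wall intersection at azimuth theta."""
        n, d = self.planes[cusp]
        c = n[0] * np.cos(theta) + n[1] * np.sin(theta)
        return (d - self.a * c) / (self.b * c + n[2])

    def attachment_z_any(self, theta) -> np.ndarray:
        """Insertion-line height for arbitrary azimuths (piecewise per cusp)."""
        theta = np.asarray(theta, dtype=float)
        out = np.full(theta.shape, self.Hc)
        for cusp, az_n in NADIR_AZIMUTHS.items():
            delta = np.mod(theta - az_n + np.pi, 2 * np.pi) - np.pi
            sel = np.abs(delta) <= np.pi / 3 + 1e-12
            if np.any(sel):
                out[sel] = self.attachment_z(cusp, theta[sel])
        return out

    def wall_radius(self, z, theta) -> np.ndarray:
        """Lumen radius at (z, azimuth); -inf outside the root's z range."""
        z = np.asarray(z, dtype=float)
        theta = np.asarray(theta, dtype=float)
        z_b, Hn, Hc, Hstj = self.z_bot, self.Hn, self.Hc, self.Hstj
        base = np.where(
            z < Hn,
            self.spec.lvot_radius + (self.Rn - self.spec.lvot_radius)
            * (z - z_b) / (Hn - z_b),
            np.where(z < Hc, self.a + self.b * z, self.Rc))
        z_att = self.attachment_z_any(theta)
        z_att = np.broadcast_to(z_att, np.broadcast_shapes(z.shape, theta.shape))
        zb = np.broadcast_to(z, z_att.shape)
        u = np.clip((zb - z_att) / np.maximum(Hstj - z_att, 1e-9), 0.0, 1.0)
        # azimuthal window: each sinus pocket peaks behind its cusp and dies
        # off smoothly (zero slope) at the commissures, so the lumen has no
        # sub-voxel-scale notches that voxelization could not represent
        delta = np.mod(theta - np.pi / 6, 2 * np.pi / 3) - np.pi / 3
        w = np.cos(1.5 * delta) ** 2
        r = base + self.spec.sinus_bulge * np.sin(np.pi * u) * w
        return np.where((zb >= z_b) & (zb <= Hstj), r, -np.inf)

    def attachment_curve(self, cusp: str, n_samples: int = 4001) -> np.ndarray:
        """Dense insertion polyline from C1 through the nadir to C2 (mm)."""
        c1n, c2n = CUSP_SPANS[cusp]
        az1 = COMMISSURE_AZIMUTHS[c1n]
        theta = az1 + np.linspace(0.0, 2 * np.pi / 3, n_samples)
        z = self.attachment_z(cusp, theta)
        r = self.a + self.b * z
        return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])

    def chord_point(self, cusp: str, theta) -> np.ndarray:
        """Free-margin chord point at a given azimuth (closed state)."""
        az_n = NADIR_AZIMUTHS[cusp]
        rho = (self.Rc * np.cos(np.pi / 3)) / np.cos(np.asarray(theta) - az_n)
        return np.stack([rho * np.cos(theta), rho * np.sin(theta),
                         np.full_like(rho, self.Hc)], axis=-1)

    def free_margin_curve(self, cusp: str, n_samples: int = 2001) -> np.ndarray:
        """Free-margin polyline: the chord (closed) or the folded arc (open)."""
        c1n, _ = CUSP_SPANS[cusp]
        az1 = COMMISSURE_AZIMUTHS[c1n]
        theta = az1 + np.linspace(0.0, 2 * np.pi / 3, n_samples)
        chord = self.chord_point(cusp, theta)
        if self.spec.valve_state == "closed":
            return chord
        rho_chord = np.linalg.norm(chord[:, :2], axis=1)
        rho_wall = self.wall_radius(np.full_like(theta, self.Hc), theta)
        rho = (1 - OPEN_FRACTION) * rho_chord + OPEN_FRACTION * rho_wall
        return np.column_stack([rho * np.cos(theta), rho * np.sin(theta),
                                np.full_like(theta, self.Hc)])

    def cusp_surface(self, cusp: str, n_theta: int = 400,
                     n_t: int = 80) -> np.ndarray:
        """(n_theta, n_t, 3) ruled-surface samples between insertion and
        free margin (identical to the planar sector in the closed state)."""
        w = self.attachment_curve(cusp, n_theta)
        f = self.free_margin_curve(cusp, n_theta)
        t = np.linspace(0.0, 1.0, n_t)
        return w[:, None, :] * (1 - t)[None, :, None] + f[:, None, :] * t[None, :, None]

    def check(self) -> None:
        """Sanity checks on the analytic construction."""
        for cusp in CUSP_LABELS:
            z = self.attachment_curve(cusp)[:, 2]
            if z.min() < self.Hn - 1e-6 or z.max() > self.Hc + 1e-6:
                raise ValueError(
                    f"insertion line of {cusp} leaves the [nadir, commissure] "
                    "band; the ring radii/heights are geometrically inconsistent")
            k = int(np.argmin(z))
            if abs(z[k] - self.Hn) > 1e-6:
                raise ValueError(f"insertion line of {cusp} does not reach the "
                                 "nadir ring")


def _truth(geom: _RootGeometry) -> PhantomTruth:
    spec = geom.spec
    pts = {}
    for c in ("rcc", "lcc", "ncc"):
        pts[f"nadir_{c}"] = geom.nadirs[c]
    pts.update(geom.commissures)
    for name, az in OSTIUM_AZIMUTHS.items():
        h = spec.ostium_heights[0] if name == "ostium_r" else spec.ostium_heights[1]
        r = float(geom.wall_radius(np.array(h), np.array(az)))
        pts[name] = np.array([r * np.cos(az), r * np.sin(az), h])
    landmarks = LandmarkSet(pts)

    vals = {}
    for cusp in ("rcc", "lcc", "ncc"):
        att = geom.attachment_curve(cusp)
        free = geom.free_margin_curve(cusp)
        vals[f"cusp_insertion_length_{cusp}"] = float(
            np.sum(np.linalg.norm(np.diff(att, axis=0), axis=1)))
        vals[f"free_margin_length_{cusp}"] = float(
            np.sum(np.linalg.norm(np.diff(free, axis=0), axis=1)))
        vals[f"effective_height_{cusp}"] = geom.Hc - geom.Hn
        nd = geom.nadirs[cusp]
        if spec.valve_state == "closed":
            c1n, c2n = CUSP_SPANS[cusp]
            arantius = (geom.commissures[c1n] + geom.commissures[c2n]) / 2.0
            vals[f"geometric_height_{cusp}"] = float(np.linalg.norm(arantius - nd))
        else:
            # fine-mesh Dijkstra oracle on the analytic ruled surface
            surf = geom.cusp_surface(cusp, n_theta=481, n_t=121)
            support = np.ones(surf.shape[:2], dtype=bool)
            mid = (surf.shape[0] - 1) // 2
            vals[f"geometric_height_{cusp}"] = grid_graph_geodesic(
                surf, support, (mid, surf.shape[1] - 1), (mid, 0), radius=3)

    cm = geom.commissures
    vals["commissural_distance_rl_rn"] = float(
        np.linalg.norm(cm["commissure_rl"] - cm["commissure_rn"]))
    vals["commissural_distance_rl_ln"] = float(
        np.linalg.norm(cm["commissure_rl"] - cm["commissure_ln"]))
    vals["commissural_distance_ln_rn"] = float(
        np.linalg.norm(cm["commissure_ln"] - cm["commissure_rn"]))

    vals["nadir_ring_perimeter"] = 2 * np.pi * geom.Rn
    theta = np.linspace(0.0, 2 * np.pi, 8001)
    rho = geom.wall_radius(np.full_like(theta, geom.Hc), theta)
    ring = np.column_stack([rho * np.cos(theta), rho * np.sin(theta)])
    vals["commissure_ring_perimeter"] = float(
        np.sum(np.linalg.norm(np.diff(ring, axis=0), axis=1)))

    vals["coronary_height_right"] = spec.ostium_heights[0] - geom.Hn
    vals["coronary_height_left"] = spec.ostium_heights[1] - geom.Hn

    return PhantomTruth(
        landmarks=landmarks,
        measurements=MeasurementReport(vals),
        nadir_plane=Plane(np.array([0.0, 0.0, geom.Hn]), np.array([0.0, 0.0, 1.0])),
        stj_plane=Plane(np.array([0.0, 0.0, geom.Hstj]), np.array([0.0, 0.0, 1.0])),
    )


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------

def _grid_axes(spec: PhantomSpec):
    n, s = spec.grid_size, spec.voxel_spacing
    c = (np.arange(n) - (n - 1) / 2.0) * s
    return c


def _closed_cusp_distance(geom: _RootGeometry, cusp: str, pts: np.ndarray) -> np.ndarray:
    """Exact distance from points to the closed (planar-sector) cusp sheet."""
    n, d = geom.planes[cusp]
    pd = pts @ n - d
    proj = pts - pd[:, None] * n
    zp = proj[:, 2]
    rp = np.linalg.norm(proj[:, :2], axis=1)
    inside = (zp >= geom.Hn - 1e-9) & (zp <= geom.Hc + 1e-9) \
        & (rp <= geom.a + geom.b * zp + 1e-9)
    dist = np.full(len(pts), np.inf)
    dist[inside] = np.abs(pd[inside])
    out = ~inside
    if np.any(out):
        boundary = np.vstack([geom.attachment_curve(cusp, 2001),
                              geom.free_margin_curve(cusp, 1001)])
        dist[out] = cKDTree(boundary).query(pts[out])[0]
    return dist


def build_phantom(spec: PhantomSpec) -> tuple:
    """Voxelize the phantom; returns ``(label_volume, truth)``.

    The label volume carries exactly the classes {0 background, 1 aortic
    root, 2 RCC, 3 LCC, 4 NCC}; a voxel gets a cusp label when its center
    lies within ``cusp_thickness/2`` of the cusp sheet and inside the root
    lumen, ties between sheets going to the lower label code.
    """
    spec.validate()
    geom = _RootGeometry(spec)
    geom.check()
    c = _grid_axes(spec)
    x = c[:, None, None]
    y = c[None, :, None]
    z = c[None, None, :]
    R = np.sqrt(x**2 + y**2)
    theta = np.arctan2(y, x)

    r_wall = geom.wall_radius(z, theta)
    root = R <= r_wall
    labels = root.astype(np.uint8)

    half_t = spec.cusp_thickness / 2.0
    # distance of every root voxel to each cusp sheet (flat arrays over the
    # candidate set), assigned afterwards with lower-code tie-breaking
    dists = {}
    flat_idx = {}
    for cusp, code in CUSP_LABELS.items():
        if spec.valve_state == "closed":
            n, d = geom.planes[cusp]
            pd = x * n[0] + y * n[1] + z * n[2] - d
            cand = root & (np.abs(pd) <= half_t + spec.voxel_spacing)
        else:
            surf = geom.cusp_surface(cusp).reshape(-1, 3)
            lo = surf.min(axis=0) - (half_t + spec.voxel_spacing)
            hi = surf.max(axis=0) + (half_t + spec.voxel_spacing)
            cand = root & (x >= lo[0]) & (x <= hi[0]) & (y >= lo[1]) \
                & (y <= hi[1]) & (z >= lo[2]) & (z <= hi[2])
        idx = np.argwhere(cand)
        if len(idx) == 0:
            continue
        pts = np.column_stack([c[idx[:, 0]], c[idx[:, 1]], c[idx[:, 2]]])
        if spec.valve_state == "closed":
            dist = _closed_cusp_distance(geom, cusp, pts)
        else:
            surf = geom.cusp_surface(cusp, n_theta=600, n_t=120).reshape(-1, 3)
            dist = cKDTree(surf).query(pts, distance_upper_bound=half_t + 1.0)[0]
        dists[code] = dist
        flat_idx[code] = idx

    dfields = {}
    for code in (2, 3, 4):
        f = np.full(labels.shape, np.inf, dtype=np.float32)
        if code in dists:
            sub = flat_idx[code]
            f[sub[:, 0], sub[:, 1], sub[:, 2]] = dists[code]
        dfields[code] = f
    d2, d3, d4 = dfields[2], dfields[3], dfields[4]
    # overwrite in decreasing code order so ties land on the lower code
    labels[(d4 <= half_t)] = 4
    labels[(d3 <= half_t) & (d3 <= d4)] = 3
    labels[(d2 <= half_t) & (d2 <= d3) & (d2 <= d4)] = 2

    origin = np.full(3, c[0])
    vol = Volume(labels, spacing=np.full(3, spec.voxel_spacing), origin=origin)
    return vol, _truth(geom)


def phantom_intensity(labels: Volume, spec: PhantomSpec,
                      noise_sigma: float = 15.0, rng=None) -> Volume:
    """CT-like intensity volume for a phantom label volume.

    Root lumen ~400 HU (contrast), a ~2 mm myocardium/wall shell ~50 HU,
    air/padding -3024 HU, optional calcium blobs at their specified HU
    (> 800), plus additive Gaussian noise from a seeded generator
    (``spec.rng_seed`` unless ``rng`` is given), so identical seeds give
    identical volumes.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    root = labels.values > 0
    hu = np.full(labels.shape, PAD_HU, dtype=np.float32)
    hu[root] = 400.0
    n_iter = max(1, int(np.ceil(WALL_THICKNESS / float(np.min(labels.spacing)))))
    shell = ndimage.binary_dilation(root, structure=np.ones((3, 3, 3)),
                                    iterations=n_iter) & ~root
    hu[shell] = 50.0
    if spec.calcium_blobs:
        pts = labels.grid_points()
        for center, radius, hu_val in spec.calcium_blobs:
            center = np.asarray(center, dtype=float)
            inside = np.sum((pts - center) ** 2, axis=-1) <= radius**2
            hu[inside] = hu_val
    hu += rng.normal(0.0, noise_sigma, size=hu.shape).astype(np.float32)
    return labels.with_values(hu)


def write_phantom(spec: PhantomSpec, out_dir) -> PhantomTruth:
    """Build a phantom and write labels/intensity/truth into a directory."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    labels, truth = build_phantom(spec)
    intensity = phantom_intensity(labels, spec)
    write_volume(labels, os.path.join(out_dir, "labels.nii.gz"))
    write_volume(intensity, os.path.join(out_dir, "intensity.nii.gz"))
    truth.save(os.path.join(out_dir, "truth.json"))
    truth.landmarks.save(os.path.join(out_dir, "landmarks.json"))
    with open(os.path.join(out_dir, "spec.json"), "w") as fh:
        json.dump(spec.to_dict(), fh, indent=2)
    return truth
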