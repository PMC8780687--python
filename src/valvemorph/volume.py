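"""Volume data model, file I/O and grid resampling.

A :class:`Volume` is a 3D scalar field on a regular grid with physical
geometry: isotropic or anisotropic ``spacing`` (mm), a world ``origin`` (mm,
the physical position of voxel ``(0, 0, 0)``) and a 3x3 orthonormal
``direction`` matrix.  Voxel values are stored in an array indexed
``values[x, y, z]``; a voxel's physical position is its *center*:

    world = origin + direction @ (spacing * index)

SimpleITK backs all file I/O (NIfTI ``.nii``/``.nii.gz`` and MetaImage
``.mha``/``.mhd``) and all resampling, so geometry round-trips bit-exactly
through the standard formats.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = [
    "Volume",
    "PhysBox",
    "AugmentParams",
    "read_volume",
    "write_volume",
    "resample_to_grid",
    "resample_to_box",
    "resample_like",
    "zscore_normalize",
    "bounding_box_scaled",
    "augment_volume",
    "landmark_augmentation",
    "segmentation_augmentation",
]

PAD_HU = -3024.0
"""Background padding value for CT crops, in Hounsfield units."""


def _as_triple(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim == 0:
        a = np.repeat(a, 3)
    if a.shape != (3,):
        raise ValueError(f"expected a scalar or length-3 sequence, got shape {a.shape}")
    return a


@dataclass
class Volume:
    """A 3D scalar grid with physical geometry."""

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix must be orthonormal")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def center(self) -> np.ndarray:
        """Physical position of the grid center (mm)."""
        half = (np.array(self.shape) - 1) / 2.0
        return self.index_to_physical(half)

    def index_to_physical(self, idx) -> np.ndarray:
        """Map (continuous) index coordinates (..., 3) to mm."""
        idx = np.asarray(idx, dtype=float)
        return self.origin + (idx * self.spacing) @ self.direction.T

    def physical_to_index(self, pts) -> np.ndarray:
        """Map mm points (..., 3) to continuous index coordinates."""
        pts = np.asarray(pts, dtype=float)
        return ((pts - self.origin) @ self.direction) / self.spacing

    def grid_points(self) -> np.ndarray:
        """Physical coordinates of every voxel center, shape ``(*shape, 3)``."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        )
        return self.index_to_physical(idx)

    def foreground_points(self) -> np.ndarray:
        """Physical coordinates (N, 3) of nonzero voxel centers."""
        idx = np.argwhere(self.values)
        return self.index_to_physical(idx)

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    def with_values(self, values: np.ndarray) -> "Volume":
        """A volume on the same grid carrying different values."""
        values = np.asarray(values)
        if values.shape != self.shape:
            raise ValueError(f"shape mismatch: {values.shape} vs {self.shape}")
        return dataclasses.replace(self, values=values)

    def copy(self) -> "Volume":
        return dataclasses.replace(self, values=self.values.copy())

    # -- SimpleITK bridge ---------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.values.transpose(2, 1, 0)))
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        img.SetDirection(tuple(self.direction.ravel()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "Volume":
        values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(
            values=values,
            spacing=np.array(img.GetSpacing()),
            origin=np.array(img.GetOrigin()),
            direction=np.array(img.GetDirection()).reshape(3, 3),
        )


def read_volume(path) -> Volume:
    """Read a NIfTI or MetaImage volume."""
    return Volume.from_sitk(sitk.ReadImage(str(path)))


def write_volume(vol: Volume, path) -> None:
    """Write a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume."""
    sitk.WriteImage(vol.to_sitk(), str(path))


@dataclass
class PhysBox:
    """Axis-aligned physical bounding box (mm)."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self):
        self.lo = _as_triple(self.lo)
        self.hi = _as_triple(self.hi)
        if np.any(self.lo > self.hi):
            raise ValueError(f"box min corner {self.lo} exceeds max corner {self.hi}")

    @property
    def center(self) -> np.ndarray:
        return (self.lo + self.hi) / 2.0

    @property
    def extent(self) -> np.ndarray:
        return self.hi - self.lo

    def scaled(self, factor: float) -> "PhysBox":
        """Scale edge lengths by ``factor`` about the box center."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        c, h = self.center, self.extent / 2.0 * factor
        return PhysBox(c - h, c + h)

    @classmethod
    def from_points(cls, pts) -> "PhysBox":
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        if pts.size == 0:
            raise ValueError("cannot build a bounding box from an empty point set")
        return cls(pts.min(axis=0), pts.max(axis=0))


def bounding_box_scaled(mask_or_points, factor: float) -> PhysBox:
    """Physical bounding box of a mask / point set, scaled about its center.

    Accepts a binary :class:`Volume`, an ``(N, 3)`` array of mm points, a
    :class:`PhysBox`, or any object with a ``points`` mapping of mm points
    (e.g. a landmark set).
    """
    if isinstance(mask_or_points, PhysBox):
        return mask_or_points.scaled(factor)
    if isinstance(mask_or_points, Volume):
        pts = mask_or_points.foreground_points()
        if pts.size == 0:
            raise ValueError("cannot build a bounding box from an empty mask")
    elif hasattr(mask_or_points, "points"):
        pts = np.array(list(mask_or_points.points.values()), dtype=float)
    else:
        pts = np.asarray(mask_or_points, dtype=float).reshape(-1, 3)
    return PhysBox.from_points(pts).scaled(factor)


_INTERPOLATORS = {"linear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor}


def _resample_onto(vol: Volume, ref: sitk.Image, pad_value: float,
                   interpolation: str, transform: sitk.Transform | None = None) -> Volume:
    try:
        interp = _INTERPOLATORS[interpolation]
    except KeyError:
        raise ValueError(f"unknown interpolation {interpolation!r}; use 'linear' or 'nearest'")
    src = vol.to_sitk()
    # resample in a float pixel type, then restore integer labels if nearest
    out = sitk.Resample(src, ref, transform or sitk.Transform(), interp,
                        float(pad_value), src.GetPixelID())
    res = Volume.from_sitk(out)
    return res


def resample_to_grid(vol: Volume, center, spacing: float, matrix_size,
                     pad_value: float = PAD_HU, interpolation: str = "linear") -> Volume:
    """Resample onto an isotropic, axis-aligned grid centered on ``center``.

    This is the fixed-size crop used ahead of each network stage: the output
    grid has the requested ``spacing`` (mm) and ``matrix_size`` voxels per
    axis, voxel centers aligned so the grid center coincides with ``center``.
    Voxels that map outside the source field of view carry ``pad_value``
    (CT convention: -3024 HU).  Use nearest interpolation for label volumes.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    size = np.asarray(matrix_size, dtype=int)
    if size.ndim == 0:
        size = np.repeat(size, 3)
    if np.any(size < 1):
        raise ValueError("matrix_size must be >= 1")
    center = _as_triple(center)
    origin = center - spacing * (size - 1) / 2.0
    ref = sitk.Image(int(size[0]), int(size[1]), int(size[2]), sitk.sitkFloat32)
    ref.SetSpacing((float(spacing),) * 3)
    ref.SetOrigin(tuple(origin))
    return _resample_onto(vol, ref, pad_value, interpolation)


def resample_to_box(vol: Volume, box: PhysBox, spacing: float,
                    pad_value: float = PAD_HU, interpolation: str = "linear") -> Volume:
    """Resample onto an isotropic grid that covers a physical box.

    The matrix size is variable: the smallest grid at ``spacing`` whose
    physical extent covers ``box``, centered on the box center.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    size = np.maximum(1, np.ceil(box.extent / spacing).astype(int) + 1)
    return resample_to_grid(vol, box.center, spacing, size, pad_value, interpolation)


def resample_like(vol: Volume, reference: Volume, pad_value: float = 0.0,
                  interpolation: str = "nearest") -> Volume:
    """Resample ``vol`` onto the grid of ``reference``."""
    ref = reference.to_sitk()
    return _resample_onto(vol, ref, pad_value, interpolation)


def zscore_normalize(vol: Volume, mean: float, std: float) -> Volume:
    """``(values - mean) / std`` with a fixed (training-set) mean and std."""
    if std <= 0:
        raise ValueError(f"std must be positive, got {std}")
    return vol.with_values((vol.values.astype(np.float32) - mean) / std)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentParams:
    """Random-augmentation parameter ranges.

    Two presets mirror the two training stages: the landmark stage multiplies
    intensities by [0.75, 1.25], shifts by [-0.25, 0.25] and adds a B-spline
    elastic deformation; the segmentation stage rotates by (-30, 30) degrees
    and multiplies intensities by (0.7, 1.4).  Geometric ranges the source
    method leaves open are package defaults (see docs/methods.md).
    """

    intensity_scale_range: tuple = (1.0, 1.0)
    intensity_shift_range: tuple = (0.0, 0.0)
    translation_mm_range: tuple = (0.0, 0.0)
    rotation_deg_range: tuple = (0.0, 0.0)
    scale_range: tuple = (1.0, 1.0)
    elastic: bool = False
    elastic_grid_points: int = 15
    elastic_max_shift_voxels: float = 5.0
    interpolation: str = "linear"
    pad_value: float = PAD_HU


def landmark_augmentation() -> AugmentParams:
    """Augmentation preset for the landmark-detection stage."""
    return AugmentParams(
        intensity_scale_range=(0.75, 1.25),
        intensity_shift_range=(-0.25, 0.25),
        translation_mm_range=(-10.0, 10.0),
        rotation_deg_range=(-15.0, 15.0),
        scale_range=(0.9, 1.1),
        elastic=True,
    )


def segmentation_augmentation() -> AugmentParams:
    """Augmentation preset for the segmentation stage."""
    return AugmentParams(
        intensity_scale_range=(0.7, 1.4),
        rotation_deg_range=(-30.0, 30.0),
        scale_range=(0.9, 1.1),
    )


def augment_volume(vol: Volume, params: AugmentParams, rng) -> Volume:
    """Apply a random intensity + geometric augmentation, reproducibly.

    All random draws come from ``rng`` (a :class:`numpy.random.Generator`),
    so a fixed seed gives bit-identical output.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    m = rng.uniform(*params.intensity_scale_range)
    s = rng.uniform(*params.intensity_shift_range)
    trans = rng.uniform(*params.translation_mm_range, size=3)
    rot = np.deg2rad(rng.uniform(*params.rotation_deg_range, size=3))
    scale = rng.uniform(*params.scale_range)

    geometric = (
        np.any(trans != 0) or np.any(rot != 0) or scale != 1.0 or params.elastic
    )
    if geometric:
        composite = sitk.CompositeTransform(3)
        center = tuple(vol.center)
        sim = sitk.Similarity3DTransform()
        sim.SetCenter(center)
        euler = sitk.Euler3DTransform()
        euler.SetRotation(float(rot[0]), float(rot[1]), float(rot[2]))
        sim.SetMatrix(euler.GetMatrix())
        sim.SetScale(float(scale))
        sim.SetTranslation(tuple(trans))
        composite.AddTransform(sim)
        if params.elastic:
            n = params.elastic_grid_points
            bsp = sitk.BSplineTransformInitializer(vol.to_sitk(), [n, n, n])
            max_mm = params.elastic_max_shift_voxels * float(np.min(vol.spacing))
            coeffs = rng.uniform(-max_mm, max_mm, size=len(bsp.GetParameters()))
            bsp.SetParameters(tuple(coeffs))
            composite.AddTransform(bsp)
        out = _resample_onto(vol, vol.to_sitk(), params.pad_value,
                             params.interpolation, composite)
    else:
        out = vol.copy()

    if m != 1.0 or s != 0.0:
        out = out.with_values(out.values * m + s)
    return out
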