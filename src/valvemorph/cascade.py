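"""Five-step segmentation cascade with pluggable components.

The pipeline alternates landmark detection and segmentation, each stage
working on a tighter crop of the CT volume:

1. coarse landmark detection on a 1.5 mm / 128^3 crop around the volume
   center;
2. aortic-root segmentation at 0.4 mm inside the coarse-landmark bounding
   box scaled 1.5x (variable matrix size covering the physical box);
3. accurate landmark detection on a 0.5 mm / 128^3 crop centered on the
   segmented root's bounding box;
4. cusp segmentation at 0.4 mm inside the root bounding box;
5. label post-processing (largest component, hole filling, insertion-line
   extension).

The deep networks enter only through two small contracts — a
``LandmarkDetector`` maps a preprocessed Volume to a LandmarkSet, a
``Segmenter`` maps a preprocessed Volume (or 128^3 patch, via the sliding
window) to a label volume on the same grid.  Reference implementations are
shipped: oracles that read phantom ground truth, and a classical
HU-threshold root segmenter, so the pipeline runs end-to-end without any
trained model; real network weights plug in through the same contracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, runtime_checkable

import numpy as np

from .landmarks import LandmarkSet
from .postprocess import fill_holes, keep_largest_component, postprocess_cusps
from .volume import (PAD_HU, PhysBox, Volume, bounding_box_scaled,
                     resample_like, resample_to_box, resample_to_grid,
                     zscore_normalize)

__all__ = [
    "CascadeConfig",
    "CascadeResult",
    "CascadeError",
    "run_cascade",
    "sliding_window_partition",
    "sliding_window_apply",
    "LandmarkDetector",
    "Segmenter",
    "OracleDetector",
    "OracleSegmenter",
    "ThresholdRootSegmenter",
]


class CascadeError(RuntimeError):
    """Pipeline failure, naming the stage that produced it."""


@dataclass
class CascadeConfig:
    """Crop/resample parameters of the five stages (defaults as published)."""

    coarse_spacing: float = 1.5
    coarse_size: int = 128
    fine_spacing: float = 0.5
    fine_size: int = 128
    seg_spacing: float = 0.4
    box_scale: float = 1.5
    pad_value: float = PAD_HU
    patch_size: int = 128
    max_gap: float = 2.0
    #: optional (mean, std) of the training intensities; when set, inputs to
    #: the segmenters are z-score normalized with these fixed statistics
    normalization: tuple | None = None


@runtime_checkable
class LandmarkDetector(Protocol):
    def __call__(self, vol: Volume) -> LandmarkSet: ...


@runtime_checkable
class Segmenter(Protocol):
    def __call__(self, vol: Volume) -> Volume: ...


# ---------------------------------------------------------------------------
# Sliding window
# ---------------------------------------------------------------------------

def sliding_window_partition(grid_size, patch: int = 128) -> list:
    """Offsets of patch^3 blocks covering a grid.

    Stride equals the patch size along each axis; a final block is shifted
    back to end-align when the axis length is not a multiple of the patch
    (no partial blocks), so e.g. a 130^3 grid yields offsets {0, 2} per
    axis.  Axes shorter than the patch get a single block of the axis
    length.
    """
    grid_size = np.asarray(grid_size, dtype=int)
    if grid_size.ndim == 0:
        grid_size = np.repeat(grid_size, 3)
    if np.any(grid_size < 1):
        raise ValueError("grid_size must be >= 1 per axis")
    per_axis = []
    for n in grid_size:
        n = int(n)
        if n <= patch:
            per_axis.append([0])
            continue
        offs = list(range(0, n - patch + 1, patch))
        if offs[-1] + patch < n:
            offs.append(n - patch)
        per_axis.append(offs)
    return [(i, j, k) for i in per_axis[0] for j in per_axis[1]
            for k in per_axis[2]]


def sliding_window_apply(vol: Volume, predict: Callable, n_classes: int,
                         patch: int = 128, class_values=None) -> Volume:
    """Patch-wise prediction with probability averaging in overlaps.

    ``predict`` maps a patch Volume to either a label Volume on the same
    grid or a probability array of shape ``(n_classes, *patch_shape)``.
    Label outputs are converted to one-hot probabilities; overlapping
    block predictions are averaged per voxel before the final argmax.
    ``class_values`` maps class indices back to label codes (default
    ``0..n_classes-1``).
    """
    if class_values is None:
        class_values = np.arange(n_classes)
    class_values = np.asarray(class_values)
    shape = vol.shape
    acc = np.zeros((n_classes,) + shape, dtype=np.float32)
    cnt = np.zeros(shape, dtype=np.float32)
    blocks = sliding_window_partition(shape, patch)
    for off in blocks:
        sl = tuple(slice(o, min(o + patch, n)) for o, n in zip(off, shape))
        sub_vals = vol.values[sl]
        sub = Volume(sub_vals, spacing=vol.spacing,
                     origin=vol.index_to_physical(np.array(off, dtype=float)),
                     direction=vol.direction)
        out = predict(sub)
        if isinstance(out, Volume):
            probs = np.stack([(out.values == cv).astype(np.float32)
                              for cv in class_values])
        else:
            probs = np.asarray(out, dtype=np.float32)
            if probs.shape != (n_classes,) + sub_vals.shape:
                raise ValueError("probability block has wrong shape")
        acc[(slice(None),) + sl] += probs
        cnt[sl] += 1.0
    acc /= cnt[None]
    lab = class_values[np.argmax(acc, axis=0)]
    return vol.with_values(lab.astype(np.uint8))


# ---------------------------------------------------------------------------
# Reference components
# ---------------------------------------------------------------------------

@dataclass
class OracleDetector:
    """Detector returning fixed (ground-truth) landmarks; pure by design."""

    landmarks: LandmarkSet

    def __call__(self, vol: Volume) -> LandmarkSet:
        return self.landmarks


@dataclass
class OracleSegmenter:
    """Segmenter that resamples a reference label volume onto the input grid.

    ``class_values`` selects which label codes this segmenter emits (e.g.
    ``(1,)`` for the binary root stage, ``(2, 3, 4)`` for the cusp stage);
    other codes map to background.
    """

    reference: Volume
    class_values: tuple = (1,)
    binarize: bool = False

    def __call__(self, vol: Volume) -> Volume:
        lab = resample_like(self.reference, vol, pad_value=0,
                            interpolation="nearest")
        vals = np.where(np.isin(lab.values, self.class_values), lab.values, 0)
        if self.binarize:
            vals = (vals > 0).astype(np.uint8)
        return vol.with_values(vals.astype(np.uint8))


@dataclass
class ThresholdRootSegmenter:
    """Classical fallback for the root stage: HU threshold + largest component.

    Works on raw (non-normalized) HU crops of a contrast-filled root.
    """

    threshold_hu: float = 200.0

    def __call__(self, vol: Volume) -> Volume:
        m = vol.with_values((vol.values >= self.threshold_hu).astype(np.uint8))
        m = keep_largest_component(m)
        return fill_holes(m)


# ---------------------------------------------------------------------------
# The cascade
# ---------------------------------------------------------------------------

@dataclass
class CascadeResult:
    root: Volume            # {0,1} on the source grid
    cusps: Volume           # {0,2,3,4} on the source grid
    landmarks: LandmarkSet  # from the accurate detection stage
    intermediates: dict = field(default_factory=dict)

    @property
    def labels(self) -> Volume:
        """Combined 5-class label volume on the source grid."""
        from .morphometry import combine_labels
        return combine_labels(self.root, self.cusps)


def _maybe_normalize(vol: Volume, config: CascadeConfig) -> Volume:
    if config.normalization is None:
        return vol
    mean, std = config.normalization
    return zscore_normalize(vol, mean, std)


def run_cascade(ct: Volume, coarse_detector: LandmarkDetector,
                root_segmenter: Segmenter, fine_detector: LandmarkDetector,
                cusp_segmenter: Segmenter,
                config: CascadeConfig | None = None,
                postprocess: bool = True) -> CascadeResult:
    """Run the five-step cascade on a CT volume.

    Component outputs are resampled back onto the source grid with nearest
    interpolation; detected landmark coordinates are physical and need no
    transform.  An empty root segmentation aborts with a
    :class:`CascadeError` naming the stage.
    """
    cfg = config or CascadeConfig()
    inter = {}

    # (1) coarse landmark detection
    coarse_in = resample_to_grid(ct, ct.center, cfg.coarse_spacing,
                                 cfg.coarse_size, cfg.pad_value, "linear")
    coarse_lm = coarse_detector(coarse_in)
    inter["coarse_landmarks"] = coarse_lm

    # (2) root segmentation in the scaled coarse-landmark box
    box = bounding_box_scaled(coarse_lm, cfg.box_scale)
    root_in = _maybe_normalize(
        resample_to_box(ct, box, cfg.seg_spacing, cfg.pad_value, "linear"), cfg)
    root_pred = sliding_window_apply(
        root_in, root_segmenter, n_classes=2, patch=cfg.patch_size,
        class_values=(0, 1))
    if not (root_pred.values > 0).any():
        raise CascadeError("stage 2 (aortic root segmentation) produced an "
                           "empty mask")
    if postprocess:
        root_pred = fill_holes(keep_largest_component(root_pred))
    inter["root_crop"] = root_pred
    root_box = PhysBox.from_points(root_pred.foreground_points())

    # (3) accurate landmark detection around the root box
    fine_in = resample_to_grid(ct, root_box.center, cfg.fine_spacing,
                               cfg.fine_size, cfg.pad_value, "linear")
    fine_lm = fine_detector(fine_in)

    # (4) cusp segmentation in the root box
    cusp_in = _maybe_normalize(
        resample_to_box(ct, root_box, cfg.seg_spacing, cfg.pad_value,
                        "linear"), cfg)
    cusp_pred = sliding_window_apply(
        cusp_in, cusp_segmenter, n_classes=4, patch=cfg.patch_size,
        class_values=(0, 2, 3, 4))
    inter["cusp_crop_raw"] = cusp_pred

    # (5) post-processing
    if postprocess:
        root_on_cusp = resample_like(root_pred, cusp_pred, pad_value=0,
                                     interpolation="nearest")
        cusp_region = root_on_cusp.with_values(
            ((root_on_cusp.values > 0) | (cusp_pred.values > 0)).astype(np.uint8))
        cusp_pred, reports = postprocess_cusps(cusp_pred, cusp_region,
                                               max_gap=cfg.max_gap)
        inter["extend_reports"] = reports

    root_out = resample_like(root_pred, ct, pad_value=0, interpolation="nearest")
    cusp_out = resample_like(cusp_pred, ct, pad_value=0, interpolation="nearest")
    return CascadeResult(root=root_out, cusps=cusp_out, landmarks=fine_lm,
                         intermediates=inter)
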