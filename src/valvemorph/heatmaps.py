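"""Landmark heatmap machinery for spatial-configuration networks.

The landmark detector regresses one heatmap per landmark; its pure-math
surface lives here: Gaussian target heatmaps g_i(x; sigma_i), the combined
regression loss

    L = sum_i sum_x || h_i(x; w, b) - g_i(x; sigma_i) ||^2
        + alpha * ||sigma||^2 + lambda * ||w||^2

with learnable per-landmark widths sigma_i penalized by alpha and network
weights w penalized by lambda (biases b enter the prediction only, not the
penalty), and heatmap -> coordinate extraction.  The convolutional network
itself is a pluggable component (see :mod:`valvemorph.cascade`); heatmaps
are ordinary :class:`~valvemorph.volume.Volume` objects and therefore
NIfTI-serializable for inspection.
"""

from __future__ import annotations

import warnings

import numpy as np

from .volume import Volume

__all__ = [
    "gaussian_heatmap",
    "scn_loss",
    "heatmap_to_landmark",
    "SCN_TRAINING_CONFIG",
]

#: Optimizer/loss settings of the landmark stage, recorded as a config
#: template (training itself is out of scope for this package).
SCN_TRAINING_CONFIG = {
    "optimizer": "adam",
    "learning_rate": 5e-5,
    "beta1": 0.9,
    "beta2": 0.999,
    "iterations": 200_000,
    "batch_size": 1,
    "alpha": 50.0,
    "lambda": 0.0005,
    "n_landmarks": 8,
}


def gaussian_heatmap(coord, sigma: float, grid: Volume, peak: float = 1.0) -> Volume:
    """Isotropic Gaussian target heatmap centered at a physical point.

    Parameters
    ----------
    coord : (3,) mm point.
    sigma : Gaussian width in mm; must be positive.
    grid : a Volume whose geometry (shape/spacing/origin/direction) defines
        the output grid; its values are ignored.
    peak : value at the exact center.  The peak-1 convention is the package
        default; the scale is exposed because loss balance between data and
        penalty terms is configuration, not geometry.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    coord = np.asarray(coord, dtype=float).reshape(3)
    pts = grid.grid_points()
    d2 = np.sum((pts - coord) ** 2, axis=-1)
    values = peak * np.exp(-0.5 * d2 / sigma**2)
    return grid.with_values(values.astype(np.float32))


def _target_heatmaps(targets, sigmas, grid: Volume, peak: float):
    out = []
    for t, s in zip(targets, sigmas):
        if isinstance(t, Volume):
            out.append(t)
        else:
            out.append(gaussian_heatmap(t, s, grid, peak=peak))
    return out


def scn_loss(
    predicted,
    targets,
    sigmas,
    weights=None,
    biases=None,
    alpha: float = 50.0,
    lam: float = 0.0005,
    peak: float = 1.0,
) -> float:
    """Combined heatmap-regression loss.

    ``predicted`` is a sequence of N heatmap Volumes sharing one grid;
    ``targets`` is a matching sequence of either target heatmap Volumes or
    mm landmark coordinates (rendered with :func:`gaussian_heatmap` at the
    corresponding ``sigmas`` entry).  ``weights``/``biases`` are the flat
    network parameter vectors; only ``weights`` is penalized.
    """
    predicted = list(predicted)
    sigmas = np.asarray(sigmas, dtype=float).ravel()
    if len(predicted) != len(sigmas):
        raise ValueError("need one sigma per predicted heatmap")
    if np.any(sigmas <= 0):
        raise ValueError("all sigmas must be positive")
    grid = predicted[0]
    for h in predicted[1:]:
        if not h.same_grid(grid):
            raise ValueError("all predicted heatmaps must share one grid")
    gs = _target_heatmaps(targets, sigmas, grid, peak)
    if len(gs) != len(predicted):
        raise ValueError("need one target per predicted heatmap")
    data = 0.0
    for h, g in zip(predicted, gs):
        if not g.same_grid(grid):
            raise ValueError("target heatmap grid does not match predictions")
        diff = h.values.astype(np.float64) - g.values.astype(np.float64)
        data += float(np.sum(diff * diff))
    w2 = float(np.sum(np.square(np.asarray(weights, dtype=float)))) if weights is not None else 0.0
    penalty = alpha * float(np.sum(sigmas**2)) + lam * w2
    return data + penalty


def heatmap_to_landmark(heatmap: Volume) -> np.ndarray:
    """Physical coordinate (mm) of the maximal heatmap voxel.

    Ties break toward the smallest flat index of the ``[x, y, z]`` array
    (C order).  A completely flat heatmap still returns the tie-break voxel
    but raises a ``UserWarning`` since the maximum is then meaningless.
    """
    vals = heatmap.values
    if vals.size == 0:
        raise ValueError("empty heatmap")
    if np.ptp(vals) == 0:
        warnings.warn("heatmap is constant; landmark position is a tie-break result")
    idx = np.unravel_index(int(np.argmax(vals)), vals.shape)
    return heatmap.index_to_physical(np.array(idx, dtype=float))
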