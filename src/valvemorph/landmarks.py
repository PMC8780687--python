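"""The eight named aortic-valve landmarks and their JSON serialization.

The valve is described by three cusp nadirs (the most LVOT-ward point of
each cusp), three commissures (where adjacent cusps meet at the wall) and
the two coronary ostia.  Commissure naming follows the cusps it separates:
``commissure_rl`` sits between RCC and LCC, ``commissure_rn`` between RCC
and NCC, ``commissure_ln`` between LCC and NCC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

LANDMARK_NAMES = (
    "nadir_rcc",
    "nadir_lcc",
    "nadir_ncc",
    "commissure_rl",
    "commissure_rn",
    "commissure_ln",
    "ostium_r",
    "ostium_l",
)

#: the two commissures flanking each cusp
CUSP_COMMISSURES = {
    "rcc": ("commissure_rl", "commissure_rn"),
    "lcc": ("commissure_rl", "commissure_ln"),
    "ncc": ("commissure_rn", "commissure_ln"),
}

#: cusp label codes in multi-label volumes (0 background, 1 aortic root)
CUSP_LABELS = {"rcc": 2, "lcc": 3, "ncc": 4}
ROOT_LABEL = 1


@dataclass
class LandmarkSet:
    """Eight named physical-space points (mm)."""

    points: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [n for n in LANDMARK_NAMES if n not in self.points]
        if missing:
            raise ValueError(f"missing landmarks: {missing}")
        pts = {}
        for name in LANDMARK_NAMES:
            p = np.asarray(self.points[name], dtype=float).reshape(3)
            if not np.all(np.isfinite(p)):
                raise ValueError(f"landmark {name!r} has non-finite coordinates: {p}")
            pts[name] = p
        self.points = pts

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def as_array(self) -> np.ndarray:
        """(8, 3) array in canonical name order."""
        return np.array([self.points[n] for n in LANDMARK_NAMES])

    def transformed(self, fn) -> "LandmarkSet":
        """Apply ``fn(point) -> point`` to every landmark."""
        return LandmarkSet({n: fn(p) for n, p in self.points.items()})

    # -- JSON schema shared across the package -----------------------------
    def to_dict(self) -> dict:
        return {n: [float(x) for x in p] for n, p in self.points.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        return cls({n: d[n] for n in LANDMARK_NAMES})

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "LandmarkSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
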