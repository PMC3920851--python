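"""The in-memory CT volume container.

A volume is a 3-D scalar grid plus the spatial metadata needed to map
voxel indices to world millimetres. Axis ``i`` of the array corresponds to
world ``x``, ``j`` to ``y`` and ``k`` to ``z``; the world position of voxel
``(i, j, k)`` is ``origin + (i*sx, j*sy, k*sz)`` at the voxel center
(direction cosines beyond axis scaling are out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Point3


@dataclass
class CTVolume:
    intensities: np.ndarray  # (nx, ny, nz) scalar grid
    spacing: np.ndarray  # (sx, sy, sz) mm
    origin: Point3 = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("volume intensities must be a 3-D array")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("volume intensities must be finite")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0) or not np.all(np.isfinite(self.spacing)):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world mm coordinates (..., 3) to fractional voxel indices."""
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) * self.spacing + self.origin

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) world coordinates of the voxel-center grid."""
        upper = self.origin + (np.array(self.shape) - 1) * self.spacing
        return self.origin.copy(), upper

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: which world points fall inside the voxel grid."""
        idx = self.world_to_index(points)
        shape = np.array(self.shape)
        return np.all((idx >= 0) & (idx <= shape - 1), axis=-1)
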