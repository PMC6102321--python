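"""Shared voxel-grid containers used across the package.

Volumes are kept in stored voxel space (no reorientation): inputs are assumed
already spatially co-registered, so voxel (i, j, k) means the same anatomical
location in every volume of a cohort. Coordinates are 0-based voxel indices;
conversion to millimetres is presentation-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["IntensityVolume", "ROILabelMap", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Two grids that must share a shape do not."""


@dataclass
class IntensityVolume:
    """A single subject's 3-D intensity image.

    Parameters
    ----------
    data:
        3-D array of finite intensities (non-negative for tracer-uptake
        images, but only finiteness is enforced).
    voxel_size_mm:
        Isotropic voxel edge length in millimetres.
    """

    data: np.ndarray
    voxel_size_mm: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class ROILabelMap:
    """Integer atlas on the cohort grid; label 0 is background.

    ``left_labels`` / ``right_labels`` name the striatal labels per hemisphere
    (default 1 = left striatum, 2 = right striatum). ``hemisphere_rule``
    selects how voxels are split into hemispheres:

    - ``"labels"``: by the label sets above;
    - ``"midplane"``: striatal voxels with axis-0 index below the grid midpoint
      are left, the rest right (sagittal midplane of the grid).
    """

    labels: np.ndarray
    label_table: dict[int, str] = field(
        default_factory=lambda: {1: "left_striatum", 2: "right_striatum"}
    )
    left_labels: frozenset[int] = frozenset({1})
    right_labels: frozenset[int] = frozenset({2})
    hemisphere_rule: str = "labels"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("atlas labels must be non-negative")
        if self.hemisphere_rule not in ("labels", "midplane"):
            raise ValueError(f"unknown hemisphere_rule {self.hemisphere_rule!r}")
        self.left_labels = frozenset(self.left_labels)
        self.right_labels = frozenset(self.right_labels)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def striatal_labels(self) -> frozenset[int]:
        return self.left_labels | self.right_labels

    def striatal_mask(self) -> np.ndarray:
        """Boolean mask of all striatal (left + right) voxels."""
        return np.isin(self.labels, sorted(self.striatal_labels))

    def hemisphere_mask(self, hemisphere: str) -> np.ndarray:
        """Boolean mask of the striatal voxels in one hemisphere.

        Parameters
        ----------
        hemisphere:
            ``"left"`` or ``"right"``.
        """
        if hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")
        if self.hemisphere_rule == "labels":
            wanted = self.left_labels if hemisphere == "left" else self.right_labels
            return np.isin(self.labels, sorted(wanted))
        mid = self.labels.shape[0] / 2.0
        xs = np.arange(self.labels.shape[0])
        side = xs < mid if hemisphere == "left" else xs >= mid
        return self.striatal_mask() & side[:, None, None]

    def check_same_grid(self, volume: IntensityVolume) -> None:
        if volume.grid_shape != self.grid_shape:
            raise GridMismatchError(
                f"volume grid {volume.grid_shape} != atlas grid {self.grid_shape}"
            )
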