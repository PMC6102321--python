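"""Striatal ROI features: voxels-as-features and the 55-element shape vector.

Two feature families are extracted from each (already normalized) uptake
volume against a shared integer atlas:

- **VAF (voxels-as-features)**: the raw intensity of every striatal voxel, in
  a fixed raster (C-order) scan of the grid, giving one high-dimensional
  feature vector per subject.
- **Morphological descriptor** (55 values, fixed order):

  1. nine intensity means — (full ROI, left hemisphere, right hemisphere) ×
     (all voxels, the 1% most intense, the 1% least intense), grouped by
     statistic: all-3, top-3, bottom-3;
  2. six coordinates — intensity-weighted centre of mass of each hemisphere
     (left xyz, right xyz), in 0-based voxel units;
  3. thirty projection properties — the N most intense striatal voxels are
     collapsed along each of the three axes (axial = along axis 2, coronal =
     along axis 1, sagittal = along axis 0); per view and per hemisphere the
     footprint's area, eccentricity, major/minor axis lengths and orientation
     are measured from the ellipse with the same normalized second central
     moments as the footprint. Order: view (axial, coronal, sagittal) ×
     hemisphere (left, right) × property (area, eccentricity, major, minor,
     orientation);
  4. ten threshold counts — striatal voxels strictly above t·m for
     t = 0.1, 0.2, …, 1.0, where m is the mean of the 1% most intense
     striatal voxels.

Boundary semantics (documented, tested): "1%" subsets use ceil(0.01·n)
voxels; threshold comparisons are strict (>), so a constant ROI yields zero
voxels above 1.0·m; ties when selecting the N most intense voxels are broken
by raster order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .grids import GridMismatchError, IntensityVolume, ROILabelMap

__all__ = [
    "CoM",
    "ProjectionProps",
    "MorphFeatures",
    "MORPH_FEATURE_NAMES",
    "extract_vaf",
    "intensity_means",
    "center_of_mass",
    "project_top_voxels",
    "projection_props",
    "volume_counts",
    "morph_vector",
]

#: View name → axis collapsed by the maximum-intensity projection.
PROJECTION_AXES = {"axial": 2, "coronal": 1, "sagittal": 0}

_PROP_NAMES = ("area", "eccentricity", "major_axis_length",
               "minor_axis_length", "orientation_deg")


def _morph_feature_names() -> tuple[str, ...]:
    names: list[str] = []
    for stat in ("mean", "top1", "bottom1"):
        for scope in ("full", "lh", "rh"):
            names.append(f"intensity_{stat}_{scope}")
    for hemi in ("lh", "rh"):
        for ax in "xyz":
            names.append(f"com_{hemi}_{ax}")
    for view in ("axial", "coronal", "sagittal"):
        for hemi in ("lh", "rh"):
            for prop in _PROP_NAMES:
                names.append(f"proj_{view}_{hemi}_{prop}")
    for t in range(1, 11):
        names.append(f"volume_count_{10 * t}pct")
    return tuple(names)


#: Canonical order of the 55 morphological features.
MORPH_FEATURE_NAMES: tuple[str, ...] = _morph_feature_names()
assert len(MORPH_FEATURE_NAMES) == 55


@dataclass(frozen=True)
class CoM:
    """Intensity-weighted centre of mass, 0-based voxel coordinates."""

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class ProjectionProps:
    """Shape properties of one 2-D projection footprint.

    ``orientation_deg`` is the angle in degrees, in (−90, 90], between the
    major axis of the moment-matched ellipse and the first image axis of the
    projection. ``empty`` flags a degenerate (no-pixel) region whose
    properties are recorded as zeros so feature vectors keep full length.
    """

    area: int
    eccentricity: float
    major_axis_length: float
    minor_axis_length: float
    orientation_deg: float
    empty: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([
            float(self.area), self.eccentricity, self.major_axis_length,
            self.minor_axis_length, self.orientation_deg,
        ])


@dataclass(frozen=True)
class MorphFeatures:
    """The 55-element morphological descriptor of one subject."""

    intensity_means: np.ndarray   # (9,)
    com_lh: CoM
    com_rh: CoM
    projections: np.ndarray       # (30,)
    volume_counts: np.ndarray     # (10,)
    flags: tuple[str, ...] = field(default=())

    def as_array(self) -> np.ndarray:
        vec = np.concatenate([
            self.intensity_means,
            self.com_lh.as_array(),
            self.com_rh.as_array(),
            self.projections,
            self.volume_counts.astype(float),
        ])
        assert vec.shape == (55,)
        return vec


def _roi_mask(atlas: ROILabelMap, roi_labels=None) -> np.ndarray:
    if roi_labels is None:
        mask = atlas.striatal_mask()
    else:
        mask = np.isin(atlas.labels, sorted(set(roi_labels)))
    return mask


def extract_vaf(
    volume: IntensityVolume, atlas: ROILabelMap, roi_labels=None
) -> np.ndarray:
    """Striatal voxel intensities in fixed raster (C-)order.

    All subjects sharing an atlas get identically ordered, equal-length
    vectors, so the result can be stacked into a feature matrix directly.
    ``roi_labels`` restricts/extends the ROI beyond the default striatal
    labels.
    """
    atlas.check_same_grid(volume)
    mask = _roi_mask(atlas, roi_labels)
    if not mask.any():
        raise ValueError("empty ROI: no voxels carry the requested labels")
    return volume.data[mask].astype(float)


def _top_fraction_mean(values: np.ndarray, fraction: float, top: bool) -> float:
    k = math.ceil(fraction * values.size)
    ordered = np.sort(values)
    subset = ordered[-k:] if top else ordered[:k]
    return float(subset.mean())


def intensity_means(volume: IntensityVolume, atlas: ROILabelMap) -> np.ndarray:
    """Nine ROI intensity means: (all, top-1%, bottom-1%) × (full, LH, RH)."""
    atlas.check_same_grid(volume)
    scopes = []
    for name, mask in (
        ("full", atlas.striatal_mask()),
        ("lh", atlas.hemisphere_mask("left")),
        ("rh", atlas.hemisphere_mask("right")),
    ):
        if not mask.any():
            raise ValueError(f"empty {name} ROI")
        scopes.append(volume.data[mask].astype(float))
    out = [float(v.mean()) for v in scopes]
    out += [_top_fraction_mean(v, 0.01, top=True) for v in scopes]
    out += [_top_fraction_mean(v, 0.01, top=False) for v in scopes]
    return np.array(out)


def center_of_mass(
    volume: IntensityVolume, atlas: ROILabelMap, hemisphere: str
) -> CoM:
    """Intensity-weighted mean voxel coordinate of one hemisphere's ROI."""
    atlas.check_same_grid(volume)
    mask = atlas.hemisphere_mask(hemisphere)
    if not mask.any():
        raise ValueError(f"empty {hemisphere} hemisphere ROI")
    weights = volume.data[mask].astype(float)
    total = weights.sum()
    if total <= 0:
        raise ValueError(f"zero total intensity in {hemisphere} hemisphere ROI")
    coords = np.argwhere(mask)
    com = (coords * weights[:, None]).sum(axis=0) / total
    return CoM(*map(float, com))


def project_top_voxels(
    volume: IntensityVolume,
    atlas: ROILabelMap,
    n_top: int,
    axis: int,
    roi_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Binary footprint of the n_top most intense ROI voxels along one axis.

    A pixel of the 2-D output is set iff at least one selected voxel projects
    onto it (maximum-intensity-projection footprint). Ties at the selection
    boundary are broken by raster order.
    """
    atlas.check_same_grid(volume)
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    mask = atlas.striatal_mask() if roi_mask is None else roi_mask
    n_roi = int(mask.sum())
    if n_roi == 0:
        raise ValueError("empty ROI")
    if not 0 < n_top <= n_roi:
        raise ValueError(f"n_top must be in [1, {n_roi}], got {n_top}")
    flat_idx = np.flatnonzero(mask.ravel())
    intensities = volume.data.ravel()[flat_idx]
    # stable sort on negated intensities: ties keep raster order
    order = np.argsort(-intensities, kind="stable")[:n_top]
    selected = np.zeros(volume.data.size, dtype=bool)
    selected[flat_idx[order]] = True
    return selected.reshape(volume.grid_shape).any(axis=axis)


def projection_props(binary_image: np.ndarray) -> ProjectionProps:
    """Area and moment-matched-ellipse properties of a 2-D binary footprint."""
    binary_image = np.asarray(binary_image, dtype=bool)
    if binary_image.ndim != 2:
        raise ValueError("projection must be 2-D")
    area = int(binary_image.sum())
    if area == 0:
        return ProjectionProps(0, 0.0, 0.0, 0.0, 0.0, empty=True)
    region = measure.regionprops(binary_image.astype(np.uint8))[0]
    # skimage orientation: angle between axis 0 and the major axis,
    # counter-clockwise, in (-pi/2, pi/2]; map -90 to +90 for the (−90, 90]
    # convention used here.
    deg = math.degrees(region.orientation)
    if deg <= -90.0:
        deg += 180.0
    return ProjectionProps(
        area=area,
        eccentricity=float(region.eccentricity),
        major_axis_length=float(region.axis_major_length),
        minor_axis_length=float(region.axis_minor_length),
        orientation_deg=deg,
    )


def volume_counts(volume: IntensityVolume, atlas: ROILabelMap) -> np.ndarray:
    """Counts of ROI voxels strictly above t·m for t = 0.1 … 1.0.

    m is the mean intensity of the 1% (ceil) most intense ROI voxels. Counts
    are non-increasing in t; with a constant ROI the final count is 0 because
    no voxel strictly exceeds 1.0·m.
    """
    atlas.check_same_grid(volume)
    mask = atlas.striatal_mask()
    if not mask.any():
        raise ValueError("empty ROI")
    values = volume.data[mask].astype(float)
    m = _top_fraction_mean(values, 0.01, top=True)
    thresholds = np.arange(1, 11) * 0.1 * m
    return (values[:, None] > thresholds[None, :]).sum(axis=0)


def morph_vector(
    volume: IntensityVolume,
    atlas: ROILabelMap,
    n_top: int | float | None = None,
) -> MorphFeatures:
    """Full 55-element morphological descriptor of one subject.

    ``n_top`` controls how many of the most intense voxels enter the
    projections: an int count, a float fraction of each hemisphere's ROI
    size, or None (default) for the full hemisphere ROI.
    """
    atlas.check_same_grid(volume)
    means = intensity_means(volume, atlas)
    com_lh = center_of_mass(volume, atlas, "left")
    com_rh = center_of_mass(volume, atlas, "right")

    flags: list[str] = []
    proj_vals: list[float] = []
    hemi_masks = {
        "lh": atlas.hemisphere_mask("left"),
        "rh": atlas.hemisphere_mask("right"),
    }
    for view, axis in PROJECTION_AXES.items():
        for hemi, hmask in hemi_masks.items():
            n_roi = int(hmask.sum())
            if n_top is None:
                n_sel = n_roi
            elif isinstance(n_top, float) and 0 < n_top <= 1:
                n_sel = max(1, math.ceil(n_top * n_roi))
            else:
                n_sel = min(int(n_top), n_roi)
            footprint = project_top_voxels(volume, atlas, n_sel, axis, roi_mask=hmask)
            props = projection_props(footprint)
            if props.empty:
                flags.append(f"empty_projection_{view}_{hemi}")
            proj_vals.extend(props.as_array())

    counts = volume_counts(volume, atlas)
    return MorphFeatures(
        intensity_means=means,
        com_lh=com_lh,
        com_rh=com_rh,
        projections=np.array(proj_vals),
        volume_counts=counts,
        flags=tuple(flags),
    )
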