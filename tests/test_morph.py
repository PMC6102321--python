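"""ROI feature extraction against brute-force oracles and symmetry checks."""

import math

import numpy as np
import pytest

from datfuse import IntensityVolume, MORPH_FEATURE_NAMES, ROILabelMap
from datfuse.grids import GridMismatchError
from datfuse.morph import (
    center_of_mass,
    extract_vaf,
    intensity_means,
    morph_vector,
    project_top_voxels,
    projection_props,
    volume_counts,
)


# ---------------------------------------------------------------- oracles

def ellipse_props_oracle(mask):
    """Moment-matched ellipse from an explicit eigen-decomposition of the
    pixel covariance — independent of the library implementation."""
    coords = np.argwhere(mask).astype(float)
    d = coords - coords.mean(0)
    cov = d.T @ d / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    lam_minor, lam_major = evals
    major = 4.0 * math.sqrt(max(lam_major, 0.0))
    minor = 4.0 * math.sqrt(max(lam_minor, 0.0))
    ecc = math.sqrt(1.0 - lam_minor / lam_major) if lam_major > 0 else 0.0
    v = evecs[:, 1]
    angle = math.degrees(math.atan2(v[1], v[0]))
    angle = ((angle + 90.0) % 180.0) - 90.0    # fold into (-90, 90]
    if angle <= -90.0:
        angle += 180.0
    return int(mask.sum()), ecc, major, minor, angle


def rotated_ellipse(a, b, theta_deg, size=101):
    c = (size - 1) / 2
    th = math.radians(theta_deg)
    rr, cc = np.mgrid[0:size, 0:size]
    u = (rr - c) * math.cos(th) + (cc - c) * math.sin(th)
    v = -(rr - c) * math.sin(th) + (cc - c) * math.cos(th)
    return (u / a) ** 2 + (v / b) ** 2 <= 1


def tiny_volume_and_atlas(values_at, shape=(6, 6, 6), label=1):
    """Volume + atlas with the given {voxel: intensity} mapping as ROI."""
    data = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int64)
    for voxel, value in values_at.items():
        data[voxel] = value
        labels[voxel] = label
    return IntensityVolume(data), ROILabelMap(labels)


# ----------------------------------------------------------- extract_vaf

class TestExtractVAF:
    def test_raster_order(self):
        vol, atlas = tiny_volume_and_atlas(
            {(0, 0, 0): 1.0, (0, 0, 2): 2.0, (3, 1, 0): 3.0}
        )
        np.testing.assert_array_equal(extract_vaf(vol, atlas), [1.0, 2.0, 3.0])

    def test_equal_lengths_across_subjects(self, small_cohort):
        lengths = {
            extract_vaf(v, small_cohort.atlas).size
            for v in small_cohort.volumes.values()
        }
        assert len(lengths) == 1

    def test_grid_mismatch_rejected(self, atlas):
        with pytest.raises(GridMismatchError):
            extract_vaf(IntensityVolume(np.zeros((4, 4, 4))), atlas)

    def test_empty_roi_rejected(self):
        vol, _ = tiny_volume_and_atlas({})
        atlas = ROILabelMap(np.zeros((6, 6, 6), dtype=np.int64))
        with pytest.raises(ValueError, match="empty"):
            extract_vaf(vol, atlas)


# -------------------------------------------------------- intensity means

class TestIntensityMeans:
    def test_constant_roi(self, atlas):
        vol = IntensityVolume(np.full(atlas.grid_shape, 7.0))
        np.testing.assert_allclose(intensity_means(vol, atlas), 7.0)

    def test_extreme_voxel_oracle(self):
        # 100-voxel ROI, one voxel at 100: full mean 1, top-1% mean 100,
        # bottom-1% mean 0 (1% of 100 voxels = 1 voxel)
        shape = (10, 10, 2)
        labels = np.zeros(shape, dtype=np.int64)
        labels[:, :, 0] = 1
        labels[5:, :, 0] = 2
        data = np.zeros(shape)
        data[0, 0, 0] = 100.0
        vol, atlas = IntensityVolume(data), ROILabelMap(labels)
        means = intensity_means(vol, atlas)
        assert means[0] == pytest.approx(1.0)    # full mean
        assert means[3] == pytest.approx(100.0)  # full top-1%
        assert means[6] == pytest.approx(0.0)    # full bottom-1%

    def test_mirror_swaps_hemisphere_triples(self, small_cohort):
        vol = small_cohort.volumes["PD001"]
        mirrored = IntensityVolume(np.flip(vol.data, axis=0).copy())
        m, mm = (intensity_means(v, small_cohort.atlas) for v in (vol, mirrored))
        for base in (0, 3, 6):
            assert mm[base] == pytest.approx(m[base], rel=1e-6)       # full
            assert mm[base + 1] == pytest.approx(m[base + 2], rel=1e-6)  # LH<->RH
            assert mm[base + 2] == pytest.approx(m[base + 1], rel=1e-6)

    def test_means_scale_linearly_with_intensity(self, small_cohort):
        vol = small_cohort.volumes["HC002"]
        scaled = IntensityVolume(3.0 * vol.data)
        np.testing.assert_allclose(
            intensity_means(scaled, small_cohort.atlas),
            3.0 * intensity_means(vol, small_cohort.atlas),
            rtol=1e-6,
        )


# ---------------------------------------------------------- center of mass

class TestCenterOfMass:
    def test_two_voxel_weighting(self):
        vol, atlas = tiny_volume_and_atlas({(0, 0, 0): 1.0, (4, 0, 0): 3.0})
        com = center_of_mass(vol, atlas, "left")
        assert (com.x, com.y, com.z) == pytest.approx((3.0, 0.0, 0.0))

    def test_uniform_ellipsoid_center(self, atlas):
        vol = IntensityVolume(np.ones(atlas.grid_shape))
        com = center_of_mass(vol, atlas, "left")
        centroid = np.argwhere(atlas.hemisphere_mask("left")).mean(axis=0)
        np.testing.assert_allclose(com.as_array(), centroid, atol=1e-9)

    def test_intensity_scale_invariance(self, small_cohort):
        vol = small_cohort.volumes["HC003"]
        doubled = IntensityVolume(2.0 * vol.data)
        np.testing.assert_allclose(
            center_of_mass(doubled, small_cohort.atlas, "right").as_array(),
            center_of_mass(vol, small_cohort.atlas, "right").as_array(),
            atol=1e-9,
        )

    def test_zero_intensity_rejected(self, atlas):
        vol = IntensityVolume(np.zeros(atlas.grid_shape))
        with pytest.raises(ValueError, match="zero total intensity"):
            center_of_mass(vol, atlas, "left")

    def test_matches_weighted_sum_oracle(self, small_cohort):
        vol = small_cohort.volumes["PD002"]
        mask = small_cohort.atlas.hemisphere_mask("left")
        coords = np.argwhere(mask).astype(float)
        w = vol.data[mask].astype(float)
        expected = (coords * w[:, None]).sum(0) / w.sum()
        np.testing.assert_allclose(
            center_of_mass(vol, small_cohort.atlas, "left").as_array(),
            expected, rtol=1e-12,
        )


# ------------------------------------------------------------- projections

class TestProjections:
    def test_full_roi_projection_is_footprint(self, small_cohort):
        atlas = small_cohort.atlas
        vol = small_cohort.volumes["HC001"]
        roi = atlas.striatal_mask()
        for axis in (0, 1, 2):
            footprint = project_top_voxels(vol, atlas, int(roi.sum()), axis)
            np.testing.assert_array_equal(footprint, roi.any(axis=axis))

    def test_single_voxel_projection(self):
        vol, atlas = tiny_volume_and_atlas({(2, 3, 4): 5.0})
        img = project_top_voxels(vol, atlas, 1, axis=2)
        assert img.sum() == 1 and img[2, 3]

    def test_collapse_along_axis(self):
        # two voxels differing only along the projection axis -> one pixel
        vol, atlas = tiny_volume_and_atlas({(1, 2, 0): 1.0, (1, 2, 5): 2.0})
        img = project_top_voxels(vol, atlas, 2, axis=2)
        assert img.sum() == 1

    def test_invalid_n_top_rejected(self, small_cohort):
        vol = small_cohort.volumes["HC001"]
        with pytest.raises(ValueError):
            project_top_voxels(vol, small_cohort.atlas, 0, axis=0)

    def test_disk_is_circular(self):
        props = projection_props(rotated_ellipse(10, 10, 0))
        assert props.eccentricity < 0.05
        assert props.major_axis_length == pytest.approx(
            props.minor_axis_length, rel=0.02
        )

    def test_axis_aligned_ellipse(self):
        props = projection_props(rotated_ellipse(8, 4, 0))
        assert props.major_axis_length / props.minor_axis_length == pytest.approx(
            2.0, rel=0.05
        )
        assert abs(props.orientation_deg) < 2.0

    def test_rotation_equivariance(self):
        base = projection_props(rotated_ellipse(20, 8, 0))
        rot = projection_props(rotated_ellipse(20, 8, 30))
        assert rot.orientation_deg == pytest.approx(30.0, abs=1.0)
        assert rot.eccentricity == pytest.approx(base.eccentricity, abs=0.02)

    def test_matches_brute_force_moments_on_random_ellipses(self, rng):
        for _ in range(20):
            a = rng.uniform(6, 25)
            b = rng.uniform(3, a)
            theta = rng.uniform(-89, 89)
            mask = rotated_ellipse(a, b, theta)
            props = projection_props(mask)
            area, ecc, major, minor, angle = ellipse_props_oracle(mask)
            assert props.area == area
            assert props.eccentricity == pytest.approx(ecc, abs=1e-6)
            assert props.major_axis_length == pytest.approx(major, abs=1e-6)
            assert props.minor_axis_length == pytest.approx(minor, abs=1e-6)
            # undirected line: compare modulo 180 degrees
            diff = abs(props.orientation_deg - angle) % 180.0
            assert min(diff, 180.0 - diff) < 1e-6

    def test_empty_projection_flagged(self):
        props = projection_props(np.zeros((5, 5), dtype=bool))
        assert props.empty and props.area == 0


# ----------------------------------------------------------- volume counts

class TestVolumeCounts:
    def test_constant_roi_boundary(self, atlas):
        vol = IntensityVolume(np.full(atlas.grid_shape, 4.0))
        counts = volume_counts(vol, atlas)
        n_roi = int(atlas.striatal_mask().sum())
        np.testing.assert_array_equal(counts[:9], n_roi)
        assert counts[9] == 0  # strict > at t = 1.0

    def test_monotone_nonincreasing(self, small_cohort):
        for vol in small_cohort.volumes.values():
            counts = volume_counts(vol, small_cohort.atlas)
            assert (np.diff(counts) <= 0).all()

    def test_ramp_against_threshold_sweep_oracle(self, small_cohort):
        atlas = small_cohort.atlas
        data = np.arange(np.prod(atlas.grid_shape), dtype=float).reshape(
            atlas.grid_shape
        )
        vol = IntensityVolume(data)
        counts = volume_counts(vol, atlas)
        roi_values = data[atlas.striatal_mask()]
        k = math.ceil(0.01 * roi_values.size)
        m = np.sort(roi_values)[-k:].mean()
        expected = [int((roi_values > 0.1 * t * m).sum()) for t in range(1, 11)]
        np.testing.assert_array_equal(counts, expected)


# ------------------------------------------------------------ morph_vector

class TestMorphVector:
    def test_deterministic(self, small_cohort):
        vol = small_cohort.volumes["PD003"]
        a = morph_vector(vol, small_cohort.atlas).as_array()
        b = morph_vector(vol, small_cohort.atlas).as_array()
        np.testing.assert_array_equal(a, b)

    def test_mirror_swaps_hemisphere_blocks(self, small_cohort):
        atlas = small_cohort.atlas
        vol = small_cohort.volumes["PD001"]
        nx = atlas.grid_shape[0]
        names = list(MORPH_FEATURE_NAMES)
        m = dict(zip(names, morph_vector(vol, atlas).as_array()))
        mm = dict(
            zip(names, morph_vector(
                IntensityVolume(np.flip(vol.data, axis=0).copy()), atlas
            ).as_array())
        )
        # hemispheric intensity means swap; full-ROI ones unchanged
        for stat in ("mean", "top1", "bottom1"):
            assert mm[f"intensity_{stat}_full"] == pytest.approx(
                m[f"intensity_{stat}_full"], rel=1e-6)
            assert mm[f"intensity_{stat}_lh"] == pytest.approx(
                m[f"intensity_{stat}_rh"], rel=1e-6)
        # centres of mass swap and mirror in x
        assert mm["com_lh_x"] == pytest.approx((nx - 1) - m["com_rh_x"], abs=1e-6)
        assert mm["com_lh_y"] == pytest.approx(m["com_rh_y"], abs=1e-6)
        # projection areas/eccentricities swap hemispheres
        for view in ("axial", "coronal", "sagittal"):
            for prop in ("area", "eccentricity", "major_axis_length"):
                assert mm[f"proj_{view}_lh_{prop}"] == pytest.approx(
                    m[f"proj_{view}_rh_{prop}"], rel=1e-6)
        # whole-ROI threshold counts unchanged
        for t in range(1, 11):
            assert mm[f"volume_count_{10 * t}pct"] == m[f"volume_count_{10 * t}pct"]

    def test_invariant_to_extra_background(self, small_cohort):
        atlas = small_cohort.atlas
        vol = small_cohort.volumes["HC004"]
        pad = ((0, 3), (0, 3), (0, 3))
        grown_vol = IntensityVolume(np.pad(vol.data, pad, constant_values=1.0))
        grown_atlas = ROILabelMap(np.pad(atlas.labels, pad))
        np.testing.assert_allclose(
            morph_vector(grown_vol, grown_atlas).as_array(),
            morph_vector(vol, atlas).as_array(),
            rtol=1e-12,
        )
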