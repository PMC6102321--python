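"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

Each phantom subject is a 3-D uptake volume on a common grid (default
79×95×78 voxels, 2 mm isotropic): an ellipsoidal "brain" envelope filled with
α-stable background intensities, plus two mirror-image ellipsoidal
striatum-like high-uptake regions (one per hemisphere, caudate and putamen
merged). Controls carry a striatal mean of ``striatal_mean``; patients carry
``striatal_mean / striatum_contrast``, optionally redistributed between
hemispheres — the affected side (chosen at random per patient) is scaled by
(1 − asymmetry) and the other by (1 + asymmetry), so the bilateral mean ratio
between classes stays at ``striatum_contrast`` while patients become
left/right asymmetric. Every subject finally receives a multiplicative
lognormal scanner gain, which the α-stable intensity normalization is meant
to remove.

Biomarker tables are standard-normal noise per test; the first
ceil(informative_fraction · n) columns of each source receive a mean shift of
``effect_size`` (in SD units) in the patient class. Cells go missing
completely at random with probability ``missing_rate``.

Randomness: every draw descends from the single integer ``seed`` through
fixed-entropy child streams — subject i uses ``SeedSequence((seed, 0, i))``
(draw order within a subject: affected side, gain, background voxels,
striatal voxels), biomarker source j uses ``SeedSequence((seed, 1, j))``
(values, then the missingness mask). Adding subjects or sources therefore
never reshuffles earlier draws.

No attempt is made at SPECT physics (scatter, attenuation, point-spread);
the phantom's job is to exercise the statistics, not the scanner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .grids import IntensityVolume, ROILabelMap
from .io import Cohort, write_cohort
from .stable_norm import StableParams, stable_rvs

__all__ = [
    "PhantomConfig",
    "PhantomCohort",
    "PhantomConfigError",
    "generate_cohort",
    "write_cohort",
]


class PhantomConfigError(ValueError):
    """Invalid phantom configuration."""


DEFAULT_GRID = (79, 95, 78)

#: Fractional grid geometry: centre and semi-axes of the left striatal
#: ellipsoid (the right one is its mirror image through the sagittal
#: midplane) and semi-axes of the brain envelope.
_LEFT_CENTER_FRAC = (0.33, 0.55, 0.50)
_STRIATUM_SEMI_FRAC = (0.10, 0.14, 0.11)
_BRAIN_SEMI_FRAC = (0.44, 0.46, 0.44)


@dataclass(frozen=True)
class PhantomConfig:
    """All knobs of the synthetic cohort generator.

    ``striatum_contrast`` is the HC/PD ratio of mean striatal uptake (> 1);
    ``asymmetry`` in [0, 1) redistributes patient uptake between hemispheres;
    ``gain_sd`` is the log-SD of the per-subject multiplicative scanner gain;
    ``background_stable`` is the S0-parameterized background intensity law.
    """

    n_hc: int = 75
    n_pd: int = 75
    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    voxel_size_mm: float = 2.0
    striatum_contrast: float = 2.0
    asymmetry: float = 0.2
    background_stable: StableParams = StableParams(
        alpha=1.8, beta=0.5, gamma=5.41, delta=28.42, method="configured"
    )
    striatal_mean: float = 100.0
    striatal_noise_sd: float = 10.0
    gain_sd: float = 0.15
    n_biomarkers_per_source: Mapping[str, int] = field(
        default_factory=lambda: {"CSF": 4, "RNA": 34, "Serum": 1}
    )
    informative_fraction: float = 0.25
    effect_size: float = 0.3
    missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hc <= 0 or self.n_pd <= 0:
            raise PhantomConfigError("subject counts must be positive")
        if len(self.grid_shape) != 3 or any(s < 8 for s in self.grid_shape):
            raise PhantomConfigError(
                f"grid_shape must be three counts >= 8, got {self.grid_shape}"
            )
        if self.voxel_size_mm <= 0:
            raise PhantomConfigError("voxel_size_mm must be positive")
        if self.striatum_contrast <= 1:
            raise PhantomConfigError("striatum_contrast must exceed 1")
        if not 0 <= self.asymmetry < 1:
            raise PhantomConfigError("asymmetry must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise PhantomConfigError("missing_rate must be in [0, 1)")
        if not 0 <= self.informative_fraction <= 1:
            raise PhantomConfigError("informative_fraction must be in [0, 1]")
        if self.striatal_mean <= 0 or self.striatal_noise_sd < 0:
            raise PhantomConfigError("invalid striatal intensity settings")
        if self.gain_sd < 0:
            raise PhantomConfigError("gain_sd must be non-negative")
        if any(n <= 0 for n in self.n_biomarkers_per_source.values()):
            raise PhantomConfigError("biomarker counts must be positive")


@dataclass
class PhantomCohort(Cohort):
    """A generated cohort, carrying its configuration as provenance."""

    config: PhantomConfig | None = None


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    center: tuple[float, float, float],
    semi_axes: tuple[float, float, float],
) -> np.ndarray:
    grids = np.ogrid[[slice(0, s) for s in shape]]
    acc = np.zeros(shape)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def make_atlas(config: PhantomConfig) -> tuple[ROILabelMap, np.ndarray]:
    """Striatal atlas (1 = left, 2 = right) and the brain-envelope mask."""
    shape = tuple(config.grid_shape)
    center = tuple((s - 1) / 2.0 for s in shape)
    left_center = tuple(f * (s - 1) for f, s in zip(_LEFT_CENTER_FRAC, shape))
    semi = tuple(max(2.0, f * s) for f, s in zip(_STRIATUM_SEMI_FRAC, shape))
    left = _ellipsoid_mask(shape, left_center, semi)
    right = np.flip(left, axis=0)          # exact mirror: equal voxel counts
    overlap = left & right
    left, right = left & ~overlap, right & ~overlap
    labels = np.zeros(shape, dtype=np.int16)
    labels[left] = 1
    labels[right] = 2
    envelope_semi = tuple(f * s for f, s in zip(_BRAIN_SEMI_FRAC, shape))
    envelope = _ellipsoid_mask(shape, center, envelope_semi)
    envelope |= left | right
    return ROILabelMap(labels.astype(np.int64)), envelope


def _subject_volume(
    config: PhantomConfig,
    atlas: ROILabelMap,
    envelope: np.ndarray,
    index: int,
    is_patient: bool,
) -> IntensityVolume:
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0, index)))
    affected_left = bool(rng.random() < 0.5)               # draw 1: side
    gain = float(np.exp(rng.normal(0.0, config.gain_sd)))  # draw 2: gain

    data = np.zeros(config.grid_shape, dtype=np.float64)
    n_bg = int(envelope.sum())
    data[envelope] = stable_rvs(config.background_stable, n_bg, rng)  # draw 3

    if is_patient:
        base = config.striatal_mean / config.striatum_contrast
        factor_left = 1.0 - config.asymmetry if affected_left else 1.0 + config.asymmetry
        mean_left, mean_right = base * factor_left, base * (2.0 - factor_left)
    else:
        mean_left = mean_right = config.striatal_mean

    for mean, mask in (
        (mean_left, atlas.hemisphere_mask("left")),
        (mean_right, atlas.hemisphere_mask("right")),
    ):
        n = int(mask.sum())
        data[mask] = rng.normal(mean, config.striatal_noise_sd, size=n)  # draw 4

    np.clip(data * gain, 0.0, None, out=data)
    return IntensityVolume(data.astype(np.float32), config.voxel_size_mm)


def _biomarker_table(
    config: PhantomConfig,
    source_index: int,
    source: str,
    n_tests: int,
    subject_ids: list[str],
    is_patient: np.ndarray,
) -> pd.DataFrame:
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1, source_index)))
    n = len(subject_ids)
    values = rng.standard_normal((n, n_tests))
    n_informative = math.ceil(config.informative_fraction * n_tests)
    values[np.ix_(is_patient, np.arange(n_informative))] += config.effect_size
    if config.missing_rate > 0:
        missing = rng.random((n, n_tests)) < config.missing_rate
        values[missing] = np.nan
    columns = [f"{source}_{j + 1:02d}" for j in range(n_tests)]
    return pd.DataFrame(values, index=pd.Index(subject_ids, name="subject_id"),
                        columns=columns)


def generate_cohort(config: PhantomConfig) -> PhantomCohort:
    """Generate a full synthetic cohort (volumes, atlas, tables, labels).

    Deterministic: identical configuration and seed give bit-identical
    output. Requires at least two subjects per class.
    """
    if config.n_hc < 2 or config.n_pd < 2:
        raise PhantomConfigError("need at least 2 subjects per class")

    atlas, envelope = make_atlas(config)
    subject_ids = [f"HC{i + 1:03d}" for i in range(config.n_hc)]
    subject_ids += [f"PD{i + 1:03d}" for i in range(config.n_pd)]
    is_patient = np.array([sid.startswith("PD") for sid in subject_ids])

    volumes = {
        sid: _subject_volume(config, atlas, envelope, i, bool(is_patient[i]))
        for i, sid in enumerate(subject_ids)
    }
    sources = {
        source: _biomarker_table(config, j, source, n_tests, subject_ids, is_patient)
        for j, (source, n_tests) in enumerate(config.n_biomarkers_per_source.items())
    }
    labels = pd.Series(
        np.where(is_patient, "PD", "HC"), index=subject_ids, name="label"
    )
    return PhantomCohort(
        volumes=volumes,
        atlas=atlas,
        sources=sources,
        labels=labels,
        name="phantom",
        classes=("HC", "PD"),
        provenance={"seed": config.seed, "generator": "datfuse.phantom"},
        config=config,
    )
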