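"""α-stable intensity normalization of tracer-uptake volumes.

Between-subject differences in global image intensity (scanner gain, injected
dose, acquisition time) confound voxel-wise comparison of uptake images. The
normalization implemented here models the intensity histogram of the
*non-specific* brain background — every in-brain voxel outside the striatal
region of interest — as an α-stable law with stability α, skewness β,
dispersion γ and location δ, and linearly maps each image

    y = a·x + b,    a = γ*/γ,    b = δ* − a·δ,

onto the cohort reference (γ*, δ*), the arithmetic means of the per-image
dispersions and locations. After the transform every image's background law
has dispersion γ* and location δ* exactly (given exact fits), so images become
comparable voxel-by-voxel while the transform, being affine, preserves the
relative striatal uptake pattern within each image.

Parameterization: all (α, β, γ, δ) here use the continuous ("S0")
convention, in which the law is a location-scale family for fixed (α, β):
x → c·x + d maps (γ, δ) → (c·γ, c·δ + d). SciPy's default is the S1
convention; conversions are handled internally.

Fitting: McCulloch-style quantile estimation of all four parameters, then a
numerical maximum-likelihood refinement of (γ, δ) — a location-scale profile
likelihood with (α, β) fixed, evaluated through an interpolated standard pdf
grid. When the refinement fails the quantile estimate is kept and flagged in
the parameter provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import interpolate, ndimage, optimize
from scipy.stats import levy_stable

from .grids import IntensityVolume, ROILabelMap

__all__ = [
    "StableParams",
    "PopulationReference",
    "LinearTransform",
    "StableFitError",
    "background_mask",
    "fit_stable",
    "population_reference",
    "make_transform",
    "normalize_volume",
    "normalize_cohort",
]

#: Minimum number of voxels accepted by :func:`fit_stable`.
MIN_SAMPLES = 100

#: Points in the standard-pdf interpolation grid used by the ML refinement.
_PDF_GRID_POINTS = 512

#: Samples are thinned (by order statistics) above this size before refinement.
_REFINE_MAX_SAMPLES = 100_000


class StableFitError(ValueError):
    """Raised when a sample cannot support an α-stable fit."""


@dataclass(frozen=True)
class StableParams:
    """α-stable parameters in the continuous (S0) parameterization.

    ``method`` records provenance: ``"quantile+ml"`` for the default two-stage
    fit, ``"quantile"`` when the ML refinement was skipped or failed, or
    ``"configured"`` for parameters specified rather than fitted.
    """

    alpha: float
    beta: float
    gamma: float
    delta: float
    method: str = "configured"

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 2:
            raise ValueError(f"alpha must be in (0, 2], got {self.alpha}")
        if not -1 <= self.beta <= 1:
            raise ValueError(f"beta must be in [-1, 1], got {self.beta}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if not math.isfinite(self.delta):
            raise ValueError("delta must be finite")


@dataclass(frozen=True)
class PopulationReference:
    """Cohort reference (γ*, δ*): means of per-image dispersion and location."""

    gamma_star: float
    delta_star: float

    def __post_init__(self) -> None:
        if not self.gamma_star > 0:
            raise ValueError("gamma_star must be positive")


@dataclass(frozen=True)
class LinearTransform:
    """The per-image intensity map y = a·x + b."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ValueError("transform coefficients must be finite")
        if not self.a > 0:
            raise ValueError("gain a must be positive")


def _s0_to_s1_location(alpha: float, beta: float, gamma: float, delta0: float) -> float:
    if alpha == 1.0:
        return delta0 - beta * (2.0 / math.pi) * gamma * math.log(gamma)
    return delta0 - beta * gamma * math.tan(math.pi * alpha / 2.0)


def _s1_to_s0_location(alpha: float, beta: float, gamma: float, delta1: float) -> float:
    if alpha == 1.0:
        return delta1 + beta * (2.0 / math.pi) * gamma * math.log(gamma)
    return delta1 + beta * gamma * math.tan(math.pi * alpha / 2.0)


def stable_rvs(
    params: StableParams,
    size: int | tuple[int, ...],
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw variates from an S0-parameterized stable law."""
    loc1 = _s0_to_s1_location(params.alpha, params.beta, params.gamma, params.delta)
    return levy_stable.rvs(
        params.alpha, params.beta, loc=loc1, scale=params.gamma,
        size=size, random_state=rng,
    )


def background_mask(volume: IntensityVolume, atlas: ROILabelMap) -> np.ndarray:
    """In-brain, extra-striatal voxels used for the background fit.

    The brain envelope is estimated from the image itself: voxels above 10% of
    the volume's 99th-percentile intensity, restricted to the largest connected
    component, with interior holes filled. Striatal voxels (per the atlas) are
    then removed. A user-supplied mask can replace this envelope by calling
    :func:`fit_stable` on any voxel selection directly.
    """
    atlas.check_same_grid(volume)
    data = volume.data
    threshold = 0.10 * np.percentile(data, 99)
    envelope = data > threshold
    if envelope.any():
        labeled, n = ndimage.label(envelope)
        if n > 1:
            sizes = ndimage.sum_labels(envelope, labeled, index=np.arange(1, n + 1))
            envelope = labeled == (1 + int(np.argmax(sizes)))
        envelope = ndimage.binary_fill_holes(envelope)
    return envelope & ~atlas.striatal_mask()


def _quantile_estimate(x: np.ndarray) -> StableParams:
    # McCulloch quantile matching, via scipy's initializer (S1 location).
    alpha, beta, loc1, scale = levy_stable._fitstart(x)
    alpha = float(np.clip(alpha, 0.05, 2.0))
    beta = float(np.clip(beta, -1.0, 1.0))
    scale = float(scale)
    if not scale > 0:
        raise StableFitError("quantile stage produced non-positive dispersion")
    delta0 = _s1_to_s0_location(alpha, beta, scale, float(loc1))
    return StableParams(alpha, beta, scale, delta0, method="quantile")


def _refine_gamma_delta(x: np.ndarray, init: StableParams) -> StableParams | None:
    """Profile-ML refinement of (γ, δ) with (α, β) fixed at the quantile fit."""
    alpha, beta = init.alpha, init.beta
    loc1 = _s0_to_s1_location(alpha, beta, init.gamma, init.delta)
    z = (x - loc1) / init.gamma
    # Interpolate log-pdf on an asinh-transformed grid: uniform resolution in
    # the core, while linear extrapolation in u = asinh(z) matches the
    # power-law decay log f ~ -(1+alpha)·log|z| of heavy stable tails.
    u_lo = math.asinh(float(z.min())) - 0.5
    u_hi = math.asinh(float(z.max())) + 0.5
    u_grid = np.linspace(u_lo, u_hi, _PDF_GRID_POINTS)
    with np.errstate(all="ignore"):
        f0 = levy_stable.pdf(np.sinh(u_grid), alpha, beta)
    if not np.all(np.isfinite(f0)):
        return None
    log_f0 = interpolate.interp1d(
        u_grid, np.log(np.maximum(f0, 1e-300)),
        bounds_error=False, fill_value="extrapolate",
    )
    n = x.size

    def nll(p: np.ndarray) -> float:
        g, d1 = p
        if g <= 0:
            return 1e300
        return float(n * math.log(g) - log_f0(np.arcsinh((x - d1) / g)).sum())

    res = optimize.minimize(
        nll, [init.gamma, loc1], method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-6, "maxiter": 400},
    )
    gamma, d1 = res.x
    if not (res.success and gamma > 0 and np.isfinite(d1)):
        return None
    delta0 = _s1_to_s0_location(alpha, beta, float(gamma), float(d1))
    return replace(init, gamma=float(gamma), delta=delta0, method="quantile+ml")


def fit_stable(samples: Sequence[float] | np.ndarray, refine: bool = True) -> StableParams:
    """Fit an α-stable law (S0 parameterization) to a 1-D intensity sample.

    Parameters
    ----------
    samples:
        At least :data:`MIN_SAMPLES` finite values with nonzero spread.
    refine:
        Apply the (γ, δ) maximum-likelihood refinement after the quantile
        stage. With ``refine=False`` the quantile estimate is returned.
    """
    x = np.asarray(samples, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < MIN_SAMPLES:
        raise StableFitError(
            f"need at least {MIN_SAMPLES} finite samples, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise StableFitError("degenerate sample: all values identical")

    params = _quantile_estimate(x)
    if not refine:
        return params
    if x.size > _REFINE_MAX_SAMPLES:
        # Deterministic order-statistic thinning keeps the empirical shape.
        x_ref = np.sort(x)[:: int(np.ceil(x.size / _REFINE_MAX_SAMPLES))]
    else:
        x_ref = x
    refined = _refine_gamma_delta(x_ref, params)
    return refined if refined is not None else params


def population_reference(all_params: Sequence[StableParams]) -> PopulationReference:
    """Cohort reference (γ*, δ*) = arithmetic means of per-image (γ, δ)."""
    if len(all_params) == 0:
        raise ValueError("need at least one fitted image")
    gamma_star = float(np.mean([p.gamma for p in all_params]))
    delta_star = float(np.mean([p.delta for p in all_params]))
    return PopulationReference(gamma_star, delta_star)


def make_transform(params: StableParams, ref: PopulationReference) -> LinearTransform:
    """Per-image map onto the reference: a = γ*/γ, b = δ* − a·δ."""
    a = ref.gamma_star / params.gamma
    b = ref.delta_star - a * params.delta
    return LinearTransform(a, b)


def normalize_volume(volume: IntensityVolume, transform: LinearTransform) -> IntensityVolume:
    """Apply y = a·x + b to every voxel; the grid is unchanged."""
    return IntensityVolume(
        transform.a * volume.data + transform.b, volume.voxel_size_mm
    )


def normalize_cohort(
    volumes: Sequence[IntensityVolume],
    atlas: ROILabelMap,
    subject_ids: Sequence[str] | None = None,
) -> tuple[list[IntensityVolume], list[StableParams], PopulationReference]:
    """Full five-step cohort normalization.

    For each image: mask the in-brain extra-striatal background, fit the
    stable law, pool (γ, δ) into the cohort reference, build the per-image
    linear transform and apply it. Returns the normalized volumes together
    with every fitted parameter set (provenance) and the reference.
    """
    if len(volumes) < 2:
        raise ValueError("cohort normalization needs at least 2 volumes")
    ids = list(subject_ids) if subject_ids is not None else [
        f"subject{i}" for i in range(len(volumes))
    ]
    if len(ids) != len(volumes):
        raise ValueError("subject_ids length must match volumes")

    params: list[StableParams] = []
    for sid, vol in zip(ids, volumes):
        mask = background_mask(vol, atlas)
        try:
            params.append(fit_stable(vol.data[mask]))
        except StableFitError as err:
            raise StableFitError(f"background fit failed for {sid!r}: {err}") from err
    ref = population_reference(params)
    normalized = [
        normalize_volume(vol, make_transform(p, ref))
        for vol, p in zip(volumes, params)
    ]
    return normalized, params, ref
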