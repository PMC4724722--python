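"""Synthetic cohorts of brain-like 3D volumes with known statistical structure.

Every downstream stage (mass-univariate GLM, permutation inference, random-field
corrections, the false-positive-rate harness) is exercised on cohorts produced
here, so the generator controls exactly the properties those stages are
sensitive to:

* spatial smoothness — white noise convolved with a Gaussian kernel of a
  requested FWHM, on a periodic lattice so the field is stationary;
* marginal shape — either Gaussian, or log-normal (``exp(s * z)`` applied to the
  standardized smooth field ``z``), which preserves the spatial rank-correlation
  structure while giving the positively skewed voxel intensities that break
  parametric single-case tests;
* per-subject global intensity variation, removed later by proportional scaling;
* a brain-shaped (ellipsoidal) support so masking and RESEL counting see a
  non-trivial geometry;
* subject covariates: age ~ Normal(21.1, 1.8) years and Bernoulli gender,
  matching a typical young-adult volunteer cohort.

All randomness flows from a single master seed through
:class:`numpy.random.SeedSequence` spawning, so cohorts are bit-reproducible
and per-subject streams are independent of the covariate stream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CohortSpec",
    "SubjectImage",
    "BrainMask",
    "RegionPartition",
    "generate_cohort",
    "smooth_volume",
    "ellipsoid_mask",
    "make_partition",
    "fwhm_to_sigma",
]

#: conversion between full width at half maximum and Gaussian sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def fwhm_to_sigma(fwhm_mm: float, voxel_size_mm: float) -> float:
    """Gaussian sigma in voxel units for a kernel of ``fwhm_mm`` millimetres."""
    return fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm


class CohortSpecError(ValueError):
    """A cohort specification field is invalid."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    The defaults describe the reference condition used throughout the package:
    a 24^3 lattice of 3 mm voxels, an 8 mm smoothing kernel, Gaussian marginals
    with 20% intensity amplitude, 10% between-subject global variation, and
    young-adult covariates.
    """

    n_subjects: int = 120
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    smoothing_fwhm: float = 8.0
    marginal: str = "gaussian"           # {"gaussian", "skewed"}
    skew: float = 0.0                    # log-normal shape parameter s >= 0
    amplitude: float = 0.20              # intensity sd relative to the mean level
    global_cv: float = 0.10              # CV of per-subject global factors
    age_mean: float = 21.1
    age_sd: float = 1.8
    gender_p: float = 0.5
    condition_tag: str = "modulated"     # {"modulated", "unmodulated"}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise CohortSpecError(f"n_subjects must be >= 2, got {self.n_subjects}")
        if len(self.grid_shape) != 3 or any(int(d) < 4 for d in self.grid_shape):
            raise CohortSpecError(f"grid_shape dimensions must all be >= 4, got {self.grid_shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise CohortSpecError(f"voxel_size entries must be > 0, got {self.voxel_size}")
        if self.smoothing_fwhm < 0:
            raise CohortSpecError(f"smoothing_fwhm must be >= 0, got {self.smoothing_fwhm}")
        if self.marginal not in ("gaussian", "skewed"):
            raise CohortSpecError(f"marginal must be 'gaussian' or 'skewed', got {self.marginal!r}")
        if self.skew < 0:
            raise CohortSpecError(f"skew must be >= 0, got {self.skew}")
        if self.marginal == "gaussian" and self.skew != 0:
            raise CohortSpecError("gaussian marginal requires skew == 0")
        if self.amplitude <= 0:
            raise CohortSpecError(f"amplitude must be > 0, got {self.amplitude}")
        if self.global_cv < 0:
            raise CohortSpecError(f"global_cv must be >= 0, got {self.global_cv}")
        if self.age_sd < 0:
            raise CohortSpecError(f"age_sd must be >= 0, got {self.age_sd}")
        if not 0.0 <= self.gender_p <= 1.0:
            raise CohortSpecError(f"gender_p must be in [0, 1], got {self.gender_p}")
        if self.condition_tag not in ("modulated", "unmodulated"):
            raise CohortSpecError(
                f"condition_tag must be 'modulated' or 'unmodulated', got {self.condition_tag!r}"
            )

    def replace(self, **kwargs) -> "CohortSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SubjectImage:
    """One subject's 3D scalar volume plus covariates."""

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    age: float
    gender: int
    subject_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"subject volume must be 3D, got {self.values.ndim}D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"subject {self.subject_id}: non-finite voxel values")


@dataclass
class BrainMask:
    """Boolean analysis support."""

    include: np.ndarray
    n_voxels: int = field(init=False)

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include, dtype=bool)
        self.n_voxels = int(self.include.sum())
        if self.n_voxels < 1:
            raise ValueError("mask is empty")


@dataclass
class RegionPartition:
    """Integer labelling of the mask into named regions (0 = outside)."""

    labels: np.ndarray
    region_names: list[str]
    region_volumes_mm3: np.ndarray

    @property
    def n_regions(self) -> int:
        return len(self.region_names)


def smooth_volume(
    values: np.ndarray,
    fwhm_mm: float,
    voxel_size: tuple[float, float, float],
    mode: str = "nearest",
) -> np.ndarray:
    """Isotropic Gaussian smoothing with kernel width given in millimetres.

    The per-axis sigma in voxel units is ``fwhm / (2 sqrt(2 ln 2)) / voxel_size``.
    ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    values = np.asarray(values, dtype=np.float64)
    if fwhm_mm == 0:
        return values.copy()
    sigmas = [fwhm_to_sigma(fwhm_mm, v) for v in voxel_size]
    return ndimage.gaussian_filter(values, sigma=sigmas, mode=mode)


def _smoothed_noise_sd(grid_shape, sigmas) -> float:
    """Standard deviation of periodically smoothed unit white noise.

    Equal to the L2 norm of the (wrapped) smoothing kernel, obtained exactly by
    smoothing a unit impulse.
    """
    impulse = np.zeros(grid_shape)
    impulse[tuple(d // 2 for d in grid_shape)] = 1.0
    kernel = ndimage.gaussian_filter(impulse, sigma=sigmas, mode="wrap")
    return float(np.sqrt(np.sum(kernel**2)))


def standardized_smooth_field(rng: np.random.Generator, spec: CohortSpec) -> np.ndarray:
    """A zero-mean unit-variance Gaussian random field with the spec's smoothness.

    White noise is smoothed on a periodic lattice (so the field is strictly
    stationary) and rescaled by the exact kernel norm.
    """
    noise = rng.standard_normal(spec.grid_shape)
    if spec.smoothing_fwhm == 0:
        return noise
    sigmas = [fwhm_to_sigma(spec.smoothing_fwhm, v) for v in spec.voxel_size]
    smooth = ndimage.gaussian_filter(noise, sigma=sigmas, mode="wrap")
    return smooth / _smoothed_noise_sd(spec.grid_shape, sigmas)


def skew_transform(z: np.ndarray, skew: float) -> np.ndarray:
    """Monotone log-normal transform of a standard field, restandardized.

    Maps ``z -> exp(skew * z)``, then centres and scales so the output again has
    mean 0 and variance 1 but positive skewness ``(e^{s^2}+2) sqrt(e^{s^2}-1)``.
    Monotonicity preserves the spatial rank-correlation structure. ``skew = 0``
    returns ``z`` unchanged.
    """
    if skew < 0:
        raise ValueError(f"skew must be >= 0, got {skew}")
    if skew < 1e-8:
        # the transform approaches the identity as skew -> 0; below this
        # threshold the restandardization only amplifies rounding noise
        return z
    s2 = skew * skew
    mean = np.exp(s2 / 2.0)
    sd = np.sqrt(np.exp(s2) * (np.expm1(s2)))
    return (np.exp(skew * z) - mean) / sd


def ellipsoid_mask(grid_shape, semi_axis_fraction: float = 0.49) -> BrainMask:
    """Axis-aligned ellipsoidal support occupying roughly half the grid."""
    coords = np.indices(grid_shape).astype(np.float64)
    centre = [(d - 1) / 2.0 for d in grid_shape]
    semi = [semi_axis_fraction * d for d in grid_shape]
    r2 = sum(((coords[a] - centre[a]) / semi[a]) ** 2 for a in range(3))
    return BrainMask(include=r2 <= 1.0)


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectImage], pd.DataFrame]:
    """Generate a cohort of subject volumes and their covariate table.

    Each subject's volume is ``g_i * (1 + amplitude * w_i)`` inside the
    ellipsoidal support and 0 outside, where ``w_i`` is a standardized smooth
    field (Gaussian or skew-transformed) and ``g_i`` a per-subject global factor
    with the requested coefficient of variation. Values are clipped at 0.

    Returns the images and a DataFrame with columns subject_id, age, gender.
    """
    master = np.random.SeedSequence(spec.seed)
    # substream 0: covariates and global factors; substreams 1..n: per-subject fields
    streams = master.spawn(spec.n_subjects + 1)
    cov_rng = np.random.Generator(np.random.Philox(streams[0]))

    ages = cov_rng.normal(spec.age_mean, spec.age_sd, size=spec.n_subjects)
    genders = (cov_rng.random(spec.n_subjects) < spec.gender_p).astype(int)
    globals_ = np.maximum(0.05, 1.0 + spec.global_cv * cov_rng.standard_normal(spec.n_subjects))

    support = ellipsoid_mask(spec.grid_shape).include
    images: list[SubjectImage] = []
    for i in range(spec.n_subjects):
        rng = np.random.Generator(np.random.Philox(streams[i + 1]))
        z = standardized_smooth_field(rng, spec)
        w = skew_transform(z, spec.skew) if spec.marginal == "skewed" else z
        vol = globals_[i] * (1.0 + spec.amplitude * w)
        vol = np.clip(vol, 0.0, None)
        vol[~support] = 0.0
        images.append(
            SubjectImage(
                values=vol,
                voxel_size=spec.voxel_size,
                age=float(ages[i]),
                gender=int(genders[i]),
                subject_id=f"sub-{i:03d}",
            )
        )
    covariates = pd.DataFrame(
        {
            "subject_id": [im.subject_id for im in images],
            "age": ages,
            "gender": genders,
        }
    )
    return images, covariates


def make_partition(
    mask: BrainMask,
    voxel_size: tuple[float, float, float],
    n_regions: int,
) -> RegionPartition:
    """Deterministic partition of the mask into ``n_regions`` unequal slabs.

    In-mask voxels are ordered along the slowest axis (then within-slice) and
    split into contiguous slabs whose target sizes grow linearly (region k gets
    a share proportional to k+1), giving unequal volumes like an anatomical
    lobe partition. Every in-mask voxel receives exactly one positive label.
    """
    if n_regions < 1:
        raise ValueError(f"n_regions must be >= 1, got {n_regions}")
    if n_regions > mask.n_voxels:
        raise ValueError(f"n_regions ({n_regions}) exceeds mask voxel count ({mask.n_voxels})")
    idx = np.argwhere(mask.include)  # lexicographic order: x slowest
    n = len(idx)
    weights = np.arange(1, n_regions + 1, dtype=float)
    cum = np.cumsum(weights) / weights.sum()
    boundaries = np.round(cum * n).astype(int)
    boundaries[-1] = n
    labels = np.zeros(mask.include.shape, dtype=np.int32)
    start = 0
    counts = np.zeros(n_regions, dtype=int)
    for k, stop in enumerate(boundaries):
        # every region gets >= 1 voxel; reserve one voxel per remaining region
        stop = min(max(stop, start + 1), n - (n_regions - k - 1))
        sel = idx[start:stop]
        labels[sel[:, 0], sel[:, 1], sel[:, 2]] = k + 1
        counts[k] = stop - start
        start = stop
    voxel_vol = float(np.prod(voxel_size))
    return RegionPartition(
        labels=labels,
        region_names=[f"region_{k + 1:02d}" for k in range(n_regions)],
        region_volumes_mm3=counts * voxel_vol,
    )
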