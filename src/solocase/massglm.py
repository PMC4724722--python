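"""Mass-univariate GLM core shared by both inference engines.

Implements the standard voxel-based-morphometry preprocessing conventions:
global intensity as the mean of voxels above one-eighth of the overall mean,
proportional scaling of every image to a common global target, a relative
intensity threshold mask (voxels kept only where they exceed a fraction of the
global in *every* image), a single-case design matrix
``[case, intercept, age, gender]``, and vectorized ordinary-least-squares
t-maps for increase/decrease contrasts on the case indicator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthdata import BrainMask, SubjectImage

__all__ = [
    "DesignMatrix",
    "Contrast",
    "TMap",
    "compute_global",
    "proportional_scale",
    "compute_analysis_mask",
    "build_design",
    "fit_tmap",
    "stack_masked",
]

#: default proportional-scaling target; t-statistics are invariant to its value
SCALE_TARGET = 100.0

#: SPM-style global threshold divisor: global = mean of voxels > mean/8
GLOBAL_DIVISOR = 8.0

DESIGN_COLUMNS = ("case", "intercept", "age", "gender")


class RankDeficientDesignWarning(UserWarning):
    """Covariates are degenerate; error degrees of freedom were adjusted."""


@dataclass
class Contrast:
    """Weights over design columns; direction refers to the single case."""

    weights: np.ndarray
    direction: str  # {"increase", "decrease"}


@dataclass
class DesignMatrix:
    """Per-comparison design: case indicator, intercept, age, gender."""

    matrix: np.ndarray           # n_subjects x 4
    case_index: int
    rank: int
    df_error: int
    columns: tuple[str, ...] = DESIGN_COLUMNS

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]


@dataclass
class TMap:
    """Voxelwise t-statistics over the analysis mask (flat, mask order)."""

    t_values: np.ndarray
    df: int
    contrast: Contrast
    mask: BrainMask
    zero_variance: np.ndarray    # flags voxels where the residual variance is 0

    def volume(self, fill: float = 0.0) -> np.ndarray:
        """Embed the flat t-vector back into the 3D grid."""
        vol = np.full(self.mask.include.shape, fill, dtype=np.float64)
        vol[self.mask.include] = self.t_values
        return vol


def compute_global(image: SubjectImage | np.ndarray) -> float:
    """Global intensity: mean of voxels exceeding (overall mean) / 8.

    The single-pass convention of classical SPM global calculation. Raises on
    an all-zero (or non-positive-mean) image, for which the global is undefined.
    """
    values = image.values if isinstance(image, SubjectImage) else np.asarray(image)
    overall = values.mean()
    if overall <= 0:
        raise ValueError("global intensity undefined: overall mean is not positive")
    above = values > overall / GLOBAL_DIVISOR
    return float(values[above].mean())


def proportional_scale(
    images: list[SubjectImage], target: float = SCALE_TARGET
) -> list[SubjectImage]:
    """Rescale every image so its global equals ``target``."""
    scaled = []
    for im in images:
        try:
            g = compute_global(im)
        except ValueError as exc:
            raise ValueError(f"subject {im.subject_id}: {exc}") from exc
        if g <= 0:
            raise ValueError(f"subject {im.subject_id}: non-positive global {g}")
        scaled.append(
            SubjectImage(
                values=im.values * (target / g),
                voxel_size=im.voxel_size,
                age=im.age,
                gender=im.gender,
                subject_id=im.subject_id,
            )
        )
    return scaled


def compute_analysis_mask(
    scaled_images: list[SubjectImage], rel_threshold: float = 0.2
) -> BrainMask:
    """Relative-threshold mask, intersected over all images.

    A voxel is analysed only if its intensity exceeds ``rel_threshold`` times
    the image's global intensity in every image of the comparison.
    """
    if not 0.0 < rel_threshold < 1.0:
        raise ValueError(f"rel_threshold must be in (0, 1), got {rel_threshold}")
    include = np.ones(scaled_images[0].values.shape, dtype=bool)
    for im in scaled_images:
        include &= im.values > rel_threshold * compute_global(im)
    if not include.any():
        raise ValueError("analysis mask is empty after relative thresholding")
    return BrainMask(include=include)


def build_design(
    case_index: int, covariates=None, n_subjects: int | None = None
) -> tuple[DesignMatrix, Contrast, Contrast]:
    """Design matrix [case, intercept, age, gender] and both contrasts.

    Age is mean-centred (a reparametrization that leaves the case t-statistic
    unchanged but conditions the normal equations). Degenerate covariates
    (constant age, single-gender cohort) trigger a rank-deficiency warning and
    an adjusted ``df_error = n - rank``. With ``covariates=None`` (pass
    ``n_subjects``) the design reduces to [case, intercept] — the classic
    pooled two-sample t-test.
    """
    if covariates is None:
        if n_subjects is None:
            raise ValueError("n_subjects is required when covariates is None")
        n = int(n_subjects)
        if not 0 <= case_index < n:
            raise ValueError(f"case_index {case_index} out of range for {n} subjects")
        X = np.zeros((n, 2))
        X[case_index, 0] = 1.0
        X[:, 1] = 1.0
        rank = 2
        columns = ("case", "intercept")
    else:
        age = np.asarray(covariates["age"], dtype=float)
        gender = np.asarray(covariates["gender"], dtype=float)
        n = len(age)
        if not 0 <= case_index < n:
            raise ValueError(f"case_index {case_index} out of range for {n} subjects")
        X = np.zeros((n, 4))
        X[case_index, 0] = 1.0
        X[:, 1] = 1.0
        X[:, 2] = age - age.mean()
        X[:, 3] = gender
        rank = int(np.linalg.matrix_rank(X))
        columns = DESIGN_COLUMNS
        if rank < 4:
            warnings.warn(
                f"design matrix is rank deficient (rank {rank} < 4); "
                "df_error adjusted accordingly",
                RankDeficientDesignWarning,
                stacklevel=2,
            )
    design = DesignMatrix(
        matrix=X, case_index=case_index, rank=rank, df_error=n - rank, columns=columns
    )
    w = np.zeros(X.shape[1])
    w[0] = 1.0
    inc = Contrast(weights=w, direction="increase")
    dec = Contrast(weights=-w, direction="decrease")
    return design, inc, dec


def stack_masked(images: list[SubjectImage], mask: BrainMask) -> np.ndarray:
    """Subjects-by-voxels data matrix restricted to the mask."""
    return np.stack([im.values[mask.include] for im in images], axis=0)


def fit_tmap(
    scaled_images: list[SubjectImage] | np.ndarray,
    mask: BrainMask,
    design: DesignMatrix,
    contrast: Contrast,
) -> TMap:
    """Voxelwise OLS t-map for the given contrast.

    ``t = c' beta_hat / sqrt(sigma2_hat c' (X'X)^- c)`` with the residual
    variance estimated at ``df_error`` degrees of freedom. Voxels with zero
    residual variance get ``t = +/-inf`` and are flagged. Accepts either a list
    of images or a precomputed subjects-by-voxels matrix.
    """
    Y = (
        scaled_images
        if isinstance(scaled_images, np.ndarray)
        else stack_masked(scaled_images, mask)
    )
    X = design.matrix
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError(f"data has {Y.shape[0]} subjects but design has {n} rows")
    if design.df_error < 1:
        raise ValueError(
            f"no error degrees of freedom: {n} subjects, design rank {design.rank}"
        )
    xtx_inv = np.linalg.pinv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    df = design.df_error
    c = contrast.weights
    cvc = float(c @ xtx_inv @ c)
    effect = c @ beta
    sigma2 = rss / df
    zero_var = sigma2 <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(sigma2 * cvc)
    t[zero_var] = np.where(effect[zero_var] >= 0, np.inf, -np.inf)
    return TMap(t_values=t, df=df, contrast=contrast, mask=mask, zero_variance=zero_var)
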