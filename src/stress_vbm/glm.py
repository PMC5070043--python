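"""Voxelwise general linear model on grey-matter volume images.

Implements the morphometric arm of the analysis: Gaussian smoothing of the
registered, modulated grey-matter maps, proportional scaling to remove
global volume differences, and per-voxel ordinary least squares for (i) the
CAR covariate contrast, adjusting for age, gender and antidepressant use,
and (ii) the group-by-CAR interaction contrast that asks where the
volume–cortisol slope differs between ultra-high-risk subjects and controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import (
    DesignError,
    GeometryError,
    InsufficientGroupError,
)

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

CAR_MODEL_COLUMNS = ["intercept", "car", "age", "gender", "antidepressant"]
INTERACTION_MODEL_COLUMNS = CAR_MODEL_COLUMNS + ["group", "group_x_car"]


@dataclass
class VolumetricImage:
    """A 3D grid of grey-matter values with isotropic voxel size in mm."""

    values: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise GeometryError("volumetric image must be 3D")
        if not np.all(np.isfinite(self.values)):
            raise GeometryError("volumetric image contains non-finite values")
        if self.voxel_size <= 0:
            raise GeometryError("voxel size must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class DesignMatrix:
    """Subjects-by-regressors matrix with named columns."""

    X: np.ndarray
    columns: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise DesignError("design shape does not match column names")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]


@dataclass
class StatMap:
    """Per-voxel t statistics for one contrast, with shared df and betas."""

    t_values: np.ndarray
    df: int
    contrast: str
    betas: dict[str, np.ndarray]
    voxel_size: float


def _collinear_columns(X: np.ndarray, columns: list[str]) -> list[str]:
    """Name columns involved in a rank deficiency (removal restores rank)."""
    rank = np.linalg.matrix_rank(X)
    bad = []
    for j, name in enumerate(columns):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            bad.append(name)
    return bad


def build_design(
    covariates: pd.DataFrame,
    car: np.ndarray | pd.Series,
    model: str = "car",
    center_car: bool = True,
) -> DesignMatrix:
    """Assemble the design matrix from a covariate table and CAR values.

    ``covariates`` needs columns subject_id, group (0 = control, 1 = UHR),
    age, gender (0/1) and antidepressant (0/1), one row per retained
    subject, aligned with ``car``. The CAR column is mean-centred by default
    so the interaction column ``group * car_centred`` is less collinear with
    the group main effect; centring leaves the CAR and interaction contrasts
    unchanged.
    """
    car = np.asarray(car, dtype=float)
    n = len(covariates)
    if car.shape != (n,):
        raise DesignError("CAR vector length does not match covariate rows")
    car_col = car - car.mean() if center_car else car
    cols = {
        "intercept": np.ones(n),
        "car": car_col,
        "age": covariates["age"].to_numpy(dtype=float),
        "gender": covariates["gender"].to_numpy(dtype=float),
        "antidepressant": covariates["antidepressant"].to_numpy(dtype=float),
    }
    if model == "car":
        names = list(CAR_MODEL_COLUMNS)
    elif model == "interaction":
        group = covariates["group"].to_numpy(dtype=float)
        cols["group"] = group
        cols["group_x_car"] = group * car_col
        names = list(INTERACTION_MODEL_COLUMNS)
    else:
        raise DesignError(f"unknown model {model!r}")
    # a constant nuisance covariate (e.g. nobody on antidepressants) is
    # collinear with the intercept; drop it rather than fail the fit
    for nuisance in ("age", "gender", "antidepressant"):
        if nuisance in names and np.ptp(cols[nuisance]) == 0:
            logger.info("dropping constant covariate column %r", nuisance)
            names.remove(nuisance)
    X = np.column_stack([cols[c] for c in names])
    return DesignMatrix(
        X=X, columns=list(names), subject_ids=[str(s) for s in covariates["subject_id"]]
    )


def smooth_gaussian(image: VolumetricImage, fwhm_mm: float = 8.0) -> VolumetricImage:
    """Separable Gaussian smoothing with the kernel width given as FWHM.

    sigma_mm = fwhm / (2 sqrt(2 ln 2)), converted to voxels through the
    voxel size. Boundaries use replicate (nearest-value) extension so a
    constant image is a fixed point; ``fwhm_mm=0`` returns the input
    unchanged.
    """
    if fwhm_mm < 0:
        raise GeometryError("FWHM must be >= 0")
    if fwhm_mm == 0:
        return image
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / image.voxel_size
    sm = ndimage.gaussian_filter(image.values, sigma=sigma_vox, mode="nearest")
    return VolumetricImage(values=sm, voxel_size=image.voxel_size)


def proportional_scale(
    stack: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale each subject so all share the same in-mask mean.

    Each subject's volume is multiplied by (grand mean of the subject
    means) / (that subject's in-mask mean), removing global volumetric
    differences while preserving the grand mean. Returns the scaled stack
    and the per-subject scale factors.
    """
    stack = np.asarray(stack, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if stack.shape[1:] != mask.shape:
        raise GeometryError("stack grid does not match mask grid")
    if not mask.any():
        raise GeometryError("empty mask")
    subject_means = stack[:, mask].mean(axis=1)
    if np.any(subject_means <= 0):
        raise GeometryError("non-positive in-mask mean; cannot scale globally")
    grand = subject_means.mean()
    factors = grand / subject_means
    return stack * factors[:, None, None, None], factors


def analysis_mask(stack: np.ndarray, atlas: np.ndarray) -> np.ndarray:
    """Voxels with a nonzero atlas label and positive mean GMV across subjects."""
    stack = np.asarray(stack, dtype=float)
    atlas = np.asarray(atlas)
    if stack.shape[1:] != atlas.shape:
        raise GeometryError("stack grid does not match atlas grid")
    return (atlas > 0) & (stack.mean(axis=0) > 0)


def fit_voxelwise_glm(
    stack: np.ndarray,
    design: DesignMatrix,
    contrast: np.ndarray | str,
    voxel_size: float = 1.0,
) -> StatMap:
    """Ordinary least squares at every voxel with a single t contrast.

    Per voxel y: beta = (X'X)^-1 X'y; t = c'beta / sqrt(s^2 c'(X'X)^-1 c)
    with s^2 = RSS / (n - rank X). df is shared by the whole map. Voxels
    with zero residual variance report a signed infinity sentinel (or 0 when
    the contrast effect is itself 0).
    """
    X = design.X
    n, k = X.shape
    if isinstance(contrast, str):
        c = np.zeros(k)
        try:
            c[design.columns.index(contrast)] = 1.0
        except ValueError:
            raise DesignError(f"contrast column {contrast!r} not in design") from None
    else:
        c = np.asarray(contrast, dtype=float)
        if c.shape != (k,):
            raise DesignError("contrast length does not match design columns")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        raise DesignError(
            f"design is rank deficient; collinear columns: "
            f"{_collinear_columns(X, design.columns)}"
        )
    stack = np.asarray(stack, dtype=float)
    if stack.shape[0] != n:
        raise DesignError("image stack size does not match design rows")
    shape = stack.shape[1:]
    Y = stack.reshape(n, -1)

    xtx_inv = np.linalg.inv(X.T @ X)
    B = xtx_inv @ X.T @ Y  # k x V
    resid = Y - X @ B
    df = int(n - rank)
    rss = (resid**2).sum(axis=0)
    # exact interpolation leaves only rounding noise in the residuals;
    # judge "zero residual" relative to the response's own scale
    ss_total = (Y**2).sum(axis=0)
    zero_res = rss <= 1e-24 * np.maximum(ss_total, np.finfo(float).tiny)
    s2 = rss / df
    cb = c @ B
    denom2 = s2 * float(c @ xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cb / np.sqrt(denom2)
    zero_res |= denom2 <= 0
    if zero_res.any():
        t = np.where(zero_res & (cb > 0), np.inf, t)
        t = np.where(zero_res & (cb < 0), -np.inf, t)
        t = np.where(zero_res & (cb == 0), 0.0, t)
    betas = {
        name: B[i].reshape(shape) for i, name in enumerate(design.columns)
    }
    return StatMap(
        t_values=t.reshape(shape),
        df=df,
        contrast=str(contrast),
        betas=betas,
        voxel_size=voxel_size,
    )


def fit_interaction_glm(
    stack: np.ndarray,
    covariates: pd.DataFrame,
    car: np.ndarray | pd.Series,
    voxel_size: float = 1.0,
    min_group_n: int = 3,
) -> StatMap:
    """t-map for the group-by-CAR interaction coefficient.

    Positive t means a stronger volume–CAR slope in the UHR group, negative
    a stronger slope in controls; both directions of the same map are
    meaningful and are thresholded separately downstream.
    """
    group = covariates["group"].to_numpy(dtype=float)
    n_uhr = int((group == 1).sum())
    n_ctl = int((group == 0).sum())
    if n_uhr < min_group_n or n_ctl < min_group_n:
        raise InsufficientGroupError(
            f"need >= {min_group_n} subjects per group "
            f"(got UHR={n_uhr}, control={n_ctl})"
        )
    design = build_design(covariates, car, model="interaction")
    return fit_voxelwise_glm(stack, design, "group_x_car", voxel_size=voxel_size)
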