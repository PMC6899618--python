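"""Image-quality and error metrics for reconstruction intercomparison.

Conventions follow the printed definitions used throughout the evaluation:

* SSIM in its simplified single-number form
  (2 mu_gt mu + C1)(2 cov + C2) / ((mu^2 + mu_gt^2 + C1)(s^2 + s_gt^2 + C2))
  evaluated either once over a masked ROI (default) or as a local-window
  map averaged over the mask.
* Multi-realization voxel statistics: mean, bias (mean - ground truth) and
  the population (1/N) standard deviation — the 1/N divisor is deliberate
  and used everywhere, including single-image ROI standard deviations.
* ROI percent metrics: Bias_ROI, sigma_ROI and their exact decomposition
  NRMSE^2 = Bias_ROI^2 + sigma_ROI^2, all normalized by the ground-truth
  energy over the ROI and reported in percent.
* Parameter selection: the point maximizing
  SSIM_unique^2 + SSIM_whole_brain^2, where the unique-region SSIM is the
  average over the four PET-unique tumor ROIs; ties prefer the smaller
  regularization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import VoxelImage, as_values

__all__ = [
    "SSIMConstants",
    "RealizationStack",
    "ssim",
    "voxel_stats",
    "roi_bias",
    "roi_std",
    "roi_nrmse",
    "roi_mean_std_single",
    "resample_to_grid",
    "select_params",
    "write_table",
    "read_table",
]

TABLE_COLUMNS = [
    "method",
    "param_name",
    "param_value",
    "iteration",
    "brain_ssim",
    "unique_ssim",
    "brain_nrmse",
    "unique_nrmse",
    "brain_bias",
    "brain_std",
    "wm_eroded_std",
    "wm_mean",
    "gm_mean",
    "csf_mean",
    "tumor_A_mean",
    "tumor_B_mean",
    "tumor_C_mean",
    "tumor_D_mean",
]


@dataclass
class SSIMConstants:
    """Stabilizing constants C1 = (K1 L)^2, C2 = (K2 L)^2 with L the dynamic
    range of the ground truth over the evaluation mask (standard K1/K2)."""

    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float | None = None  # None -> max-min of GT over the mask
    window_sigma: float = 1.5  # voxels, local mode only

    def c1c2(self, gt_masked: np.ndarray) -> tuple[float, float]:
        L = self.dynamic_range
        if L is None:
            L = float(gt_masked.max() - gt_masked.min())
        if L <= 0:
            L = 1.0
        c1, c2 = (self.k1 * L) ** 2, (self.k2 * L) ** 2
        if c1 <= 0 or c2 <= 0:
            raise ValueError("SSIM constants must be positive")
        return c1, c2


@dataclass
class RealizationStack:
    """N reconstructed noise realizations plus the shared ground truth."""

    images: list[np.ndarray]
    ground_truth: np.ndarray

    def __post_init__(self) -> None:
        self.ground_truth = as_values(self.ground_truth).astype(float)
        self.images = [as_values(im).astype(float) for im in self.images]
        if not self.images:
            raise ValueError("need at least one realization")
        for im in self.images:
            if im.shape != self.ground_truth.shape:
                raise ValueError("realization grid differs from ground truth")

    @property
    def n(self) -> int:
        return len(self.images)

    def array(self) -> np.ndarray:
        return np.stack(self.images, axis=0)


def _mask_values(mask) -> np.ndarray:
    m = as_values(mask).astype(bool)
    if not m.any():
        raise ValueError("empty mask")
    return m


def ssim(theta, theta_gt, mask, constants: SSIMConstants | None = None, mode: str = "global") -> float:
    """Structural similarity of ``theta`` to the ground truth over a mask.

    ``mode="global"`` (default) evaluates the formula once from ROI-wide
    moments; ``mode="local"`` computes a Gaussian-window SSIM map and
    averages it over the mask.
    """
    t = as_values(theta).astype(float)
    g = as_values(theta_gt).astype(float)
    m = _mask_values(mask)
    if constants is None:
        constants = SSIMConstants()
    c1, c2 = constants.c1c2(g[m])

    if mode == "global":
        tv, gv = t[m], g[m]
        mu_t, mu_g = tv.mean(), gv.mean()
        var_t, var_g = tv.var(), gv.var()
        cov = ((tv - mu_t) * (gv - mu_g)).mean()
        return float(
            (2 * mu_g * mu_t + c1)
            * (2 * cov + c2)
            / ((mu_t**2 + mu_g**2 + c1) * (var_t + var_g + c2))
        )
    if mode == "local":
        sig = constants.window_sigma
        f = lambda a: ndimage.gaussian_filter(a, sig, mode="nearest")
        mu_t, mu_g = f(t), f(g)
        var_t = f(t * t) - mu_t**2
        var_g = f(g * g) - mu_g**2
        cov = f(t * g) - mu_t * mu_g
        smap = ((2 * mu_g * mu_t + c1) * (2 * cov + c2)) / (
            (mu_t**2 + mu_g**2 + c1) * (var_t + var_g + c2)
        )
        return float(smap[m].mean())
    raise ValueError(f"unknown SSIM mode {mode!r}")


def voxel_stats(stack: RealizationStack):
    """Voxel-wise mean, bias and population standard deviation across
    realizations (1/N divisor)."""
    arr = stack.array()
    mean = arr.mean(axis=0)
    bias = mean - stack.ground_truth
    std = np.sqrt(((arr - mean) ** 2).mean(axis=0))
    return mean, bias, std


def _gt_energy(stack: RealizationStack, mask) -> float:
    m = _mask_values(mask)
    e = float((stack.ground_truth[m] ** 2).sum())
    if e <= 0:
        raise ValueError("ground truth is identically zero on the mask")
    return e


def roi_bias(stack: RealizationStack, mask) -> float:
    """Percent ROI bias: 100 sqrt(sum (mean - GT)^2 / sum GT^2)."""
    m = _mask_values(mask)
    mean, _, _ = voxel_stats(stack)
    return 100.0 * float(
        np.sqrt(((mean[m] - stack.ground_truth[m]) ** 2).sum() / _gt_energy(stack, m))
    )


def roi_std(stack: RealizationStack, mask) -> float:
    """Percent ROI standard deviation across realizations."""
    m = _mask_values(mask)
    mean, _, _ = voxel_stats(stack)
    num = sum(((mean[m] - im[m]) ** 2).sum() for im in stack.images)
    return 100.0 * float(np.sqrt(num / (stack.n * _gt_energy(stack, m))))


def roi_nrmse(stack: RealizationStack, mask) -> float:
    """Percent NRMSE; satisfies NRMSE^2 = Bias_ROI^2 + sigma_ROI^2."""
    m = _mask_values(mask)
    num = sum(((im[m] - stack.ground_truth[m]) ** 2).sum() for im in stack.images)
    return 100.0 * float(np.sqrt(num / (stack.n * _gt_energy(stack, m))))


def roi_mean_std_single(image, mask) -> tuple[float, float]:
    """Plain ROI mean and population (1/N) standard deviation of one image."""
    v = as_values(image).astype(float)[_mask_values(mask)]
    return float(v.mean()), float(np.sqrt(((v - v.mean()) ** 2).mean()))


def resample_to_grid(image: VoxelImage, target_spacing, order: int = 1) -> VoxelImage:
    """Linear interpolation onto a grid with the given spacing (e.g. back to
    the 1 mm ground-truth grid before metric evaluation)."""
    ts = np.atleast_1d(np.asarray(target_spacing, dtype=float))
    if ts.size == 1:
        ts = np.repeat(ts, image.ndim)
    if (ts <= 0).any():
        raise ValueError("target spacing must be positive")
    factors = [s / t for s, t in zip(image.spacing, ts)]
    if np.allclose(factors, 1.0):
        return image.copy()
    out = ndimage.zoom(
        image.values.astype(float),
        factors,
        order=order,
        mode="nearest",
        grid_mode=True,
    )
    return VoxelImage(out, tuple(ts))


def select_params(table: pd.DataFrame) -> pd.Series:
    """Row maximizing unique-SSIM^2 + whole-brain-SSIM^2 (ties -> smaller
    regularization parameter)."""
    if len(table) == 0:
        raise ValueError("empty trade-off table")
    score = table["unique_ssim"] ** 2 + table["brain_ssim"] ** 2
    t = table.assign(_score=score).sort_values(
        ["_score", "param_value"], ascending=[False, True], kind="stable"
    )
    return t.iloc[0].drop("_score")


def write_table(table: pd.DataFrame, path: str) -> None:
    cols = [c for c in TABLE_COLUMNS if c in table.columns] + [
        c for c in table.columns if c not in TABLE_COLUMNS
    ]
    table[cols].to_csv(path, index=False)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path)
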