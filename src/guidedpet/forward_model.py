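"""Linear acquisition model: q = A*theta + b with Gaussian resolution model.

A generic parallel-beam projector stands in for a scanner-specific system
matrix.  The projector is pixel-driven: each voxel center is projected onto
the radial axis of every view and its value is split between the two
nearest radial bins by linear interpolation, scaled by the voxel side
length so values approximate line integrals.  The operator is assembled
once as a scipy.sparse matrix, so the backprojector is its exact transpose
and the adjoint identity <A x, y> = <x, A^T y> holds to machine precision.

Resolution modelling is an isotropic Gaussian point spread function (PSF,
default FWHM 4.5 mm) applied in image space before projection and, adjointly,
after backprojection.  Background (randoms + scatter) is an additive
sinogram term: spatially uniform randoms plus a heavily smoothed copy of
the true sinogram for scatter, each scaled to a stated fraction of total
prompts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse

from .images import VoxelImage, as_values

__all__ = [
    "Sinogram",
    "ForwardModel",
    "AcquisitionSpec",
    "project",
    "backproject",
    "sensitivity_image",
    "make_background",
    "scale_to_counts",
    "poisson_sample",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class Sinogram:
    """Projection-domain data over (angle, radial bin)."""

    values: np.ndarray
    bin_spacing: float = 1.0  # mm

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram contains non-finite values")

    @property
    def n_angles(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def total(self) -> float:
        return float(self.values.sum())

    def copy(self) -> "Sinogram":
        return Sinogram(self.values.copy(), self.bin_spacing)


@dataclass
class AcquisitionSpec:
    """Count level, background fractions and realization bookkeeping."""

    total_prompts: float = 1e6
    randoms_fraction: float = 0.2
    scatter_fraction: float = 0.2
    scatter_fwhm_mm: float = 40.0
    n_realizations: int = 10
    base_seed: int = 1234

    def __post_init__(self) -> None:
        if not (0 <= self.randoms_fraction < 1 and 0 <= self.scatter_fraction < 1):
            raise ValueError("fractions must lie in [0, 1)")
        if self.randoms_fraction + self.scatter_fraction >= 1:
            raise ValueError("randoms_fraction + scatter_fraction must be < 1")
        if self.total_prompts <= 0:
            raise ValueError("total_prompts must be positive")


class ForwardModel:
    """Parallel-beam projector over 2D images (PSF + exact sparse adjoint).

    Parameters
    ----------
    shape
        Image grid shape (2D).
    spacing
        Voxel side length in mm (isotropic).
    n_angles
        Number of views over 180 degrees (default 180).
    psf_fwhm
        Isotropic Gaussian resolution model, FWHM in mm (0 disables).
    n_bins
        Radial bins; default covers the grid diagonal.
    """

    def __init__(
        self,
        shape: tuple[int, int],
        spacing: float = 1.0,
        n_angles: int = 180,
        psf_fwhm: float = 4.5,
        n_bins: int | None = None,
    ) -> None:
        if len(shape) != 2:
            raise ValueError("ForwardModel is 2D; pass a 2-element shape")
        if psf_fwhm < 0:
            raise ValueError("psf_fwhm must be >= 0")
        self.shape = tuple(int(n) for n in shape)
        self.spacing = float(spacing)
        self.n_angles = int(n_angles)
        self.psf_fwhm = float(psf_fwhm)
        if n_bins is None:
            n_bins = int(np.ceil(np.hypot(*self.shape))) + 3
        self.n_bins = int(n_bins)
        self.bin_spacing = self.spacing
        self.angles = np.arange(self.n_angles) * np.pi / self.n_angles
        self._matrix = self._build_matrix()

    # -- geometry -------------------------------------------------------------

    def _build_matrix(self) -> sparse.csr_array:
        ny, nx = self.shape
        yy, xx = np.meshgrid(
            (np.arange(ny) - (ny - 1) / 2.0) * self.spacing,
            (np.arange(nx) - (nx - 1) / 2.0) * self.spacing,
            indexing="ij",
        )
        y = yy.ravel()
        x = xx.ravel()
        npix = y.size
        cols_base = np.arange(npix)

        rows_all, cols_all, data_all = [], [], []
        for a, ang in enumerate(self.angles):
            s = y * np.cos(ang) + x * np.sin(ang)
            f = s / self.bin_spacing + (self.n_bins - 1) / 2.0
            k0 = np.floor(f).astype(np.int64)
            w1 = f - k0
            for k, w in ((k0, 1.0 - w1), (k0 + 1, w1)):
                ok = (k >= 0) & (k < self.n_bins) & (w > 0)
                rows_all.append(a * self.n_bins + k[ok])
                cols_all.append(cols_base[ok])
                data_all.append(w[ok] * self.spacing)
        mat = sparse.coo_array(
            (
                np.concatenate(data_all),
                (np.concatenate(rows_all), np.concatenate(cols_all)),
            ),
            shape=(self.n_angles * self.n_bins, npix),
        )
        return mat.tocsr()

    @property
    def psf_sigma_vox(self) -> float:
        return self.psf_fwhm * FWHM_TO_SIGMA / self.spacing

    def _smooth(self, img: np.ndarray) -> np.ndarray:
        if self.psf_fwhm == 0:
            return img
        # mode="constant" keeps the (symmetric) kernel exactly self-adjoint
        return ndimage.gaussian_filter(img, self.psf_sigma_vox, mode="constant")

    # -- operator pair --------------------------------------------------------

    def project(self, image) -> Sinogram:
        vals = as_values(image).astype(float)
        if vals.shape != self.shape:
            raise ValueError(f"image shape {vals.shape} != model grid {self.shape}")
        smoothed = self._smooth(vals)
        sino = self._matrix @ smoothed.ravel()
        return Sinogram(sino.reshape(self.n_angles, self.n_bins), self.bin_spacing)

    def backproject(self, sinogram) -> VoxelImage:
        vals = sinogram.values if isinstance(sinogram, Sinogram) else np.asarray(sinogram)
        if vals.shape != (self.n_angles, self.n_bins):
            raise ValueError(
                f"sinogram shape {vals.shape} != ({self.n_angles}, {self.n_bins})"
            )
        img = (self._matrix.T @ vals.astype(float).ravel()).reshape(self.shape)
        return VoxelImage(self._smooth(img), (self.spacing,) * 2)

    def sensitivity(self) -> VoxelImage:
        """Backprojection of a unit sinogram: A^T 1 (with the PSF adjoint)."""
        ones = Sinogram(np.ones((self.n_angles, self.n_bins)), self.bin_spacing)
        sens = self.backproject(ones)
        return sens.with_values(np.maximum(sens.values, 0.0))


# module-level operation surface -------------------------------------------


def project(model: ForwardModel, image) -> Sinogram:
    return model.project(image)


def backproject(model: ForwardModel, sinogram) -> VoxelImage:
    return model.backproject(sinogram)


def sensitivity_image(model: ForwardModel) -> VoxelImage:
    return model.sensitivity()


def make_background(true_sino: Sinogram, spec: AcquisitionSpec) -> Sinogram:
    """Randoms (uniform) + scatter (smoothed true sinogram), scaled so that
    each component is the stated fraction of total prompts, where
    total prompts = trues + background."""
    t = true_sino.total()
    rf, sf = spec.randoms_fraction, spec.scatter_fraction
    if t <= 0:
        if rf > 0 or sf > 0:
            raise ValueError("cannot build background fractions of a zero sinogram")
        return Sinogram(np.zeros_like(true_sino.values), true_sino.bin_spacing)
    total_prompts = t / (1.0 - rf - sf)

    randoms = np.ones_like(true_sino.values)
    randoms *= rf * total_prompts / randoms.sum()

    sigma_bins = spec.scatter_fwhm_mm * FWHM_TO_SIGMA / true_sino.bin_spacing
    scatter = ndimage.gaussian_filter1d(
        true_sino.values, sigma_bins, axis=1, mode="nearest"
    )
    ssum = scatter.sum()
    scatter = scatter * (sf * total_prompts / ssum) if ssum > 0 else scatter
    return Sinogram(randoms + scatter, true_sino.bin_spacing)


def scale_to_counts(
    true_sino: Sinogram, background: Sinogram, total_prompts: float
) -> tuple[Sinogram, Sinogram]:
    """Multiply trues and background by one common factor so the expected
    total (trues + background) equals ``total_prompts``; fractions are
    preserved exactly."""
    if total_prompts <= 0:
        raise ValueError("total_prompts must be positive")
    current = true_sino.total() + background.total()
    if current <= 0:
        raise ValueError("cannot scale an empty sinogram")
    c = total_prompts / current
    return (
        Sinogram(true_sino.values * c, true_sino.bin_spacing),
        Sinogram(background.values * c, background.bin_spacing),
    )


def measure_psf_fwhm(model: ForwardModel, angle_index: int = 0) -> float:
    """Measure the effective resolution of the forward model, in mm.

    Projects a single-voxel point source at the grid center and fits a
    Gaussian to one view's radial profile.  The source voxel generally
    projects between two radial bins; the linear-interpolation splat then
    adds a known variance w(1-w) (in bin units) to the profile, which is
    subtracted before converting the fitted width to a FWHM.
    """
    from scipy.optimize import curve_fit

    ny, nx = model.shape
    src = np.zeros(model.shape)
    src[ny // 2, nx // 2] = 1.0
    profile = model.project(src).values[angle_index]
    s = (np.arange(model.n_bins) - (model.n_bins - 1) / 2.0) * model.bin_spacing

    def gauss(x, a, mu, sigma):
        return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))

    a0 = float(profile.max())
    mu0 = float(s[np.argmax(profile)])
    sig0 = max(model.psf_fwhm * FWHM_TO_SIGMA, model.bin_spacing)
    popt, _ = curve_fit(gauss, s, profile, p0=(a0, mu0, sig0))

    ang = model.angles[angle_index]
    y0 = (ny // 2 - (ny - 1) / 2.0) * model.spacing
    x0 = (nx // 2 - (nx - 1) / 2.0) * model.spacing
    f = (y0 * np.cos(ang) + x0 * np.sin(ang)) / model.bin_spacing
    w = f - np.floor(f)
    splat_var = w * (1.0 - w) * model.bin_spacing**2
    var = max(popt[2] ** 2 - splat_var, 0.0)
    return float(np.sqrt(var) / FWHM_TO_SIGMA)


def poisson_sample(expected: Sinogram, seed: int) -> Sinogram:
    """Independent Poisson draw per bin; fixed seed -> identical counts."""
    vals = expected.values
    if (vals < 0).any():
        raise ValueError("expected counts must be nonnegative")
    rng = np.random.default_rng(seed)
    return Sinogram(rng.poisson(vals).astype(float), expected.bin_spacing)
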