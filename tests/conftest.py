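"""Shared fixtures: small simulated datasets and a dense toy model.

The session-scoped fixtures fix the desk-scale study conditions used across
the suite: a 64x64 brain phantom at 2 mm voxels (the reconstruction
resolution regime), 96 views, 2e5 prompts with 20% randoms / 20% scatter,
4.5 mm PSF, seeded Poisson realizations.
"""

from __future__ import annotations

import numpy as np
import pytest

from guidedpet import AcquisitionSpec, PhantomSpec, Sinogram
from guidedpet.bench import BenchmarkConfig, simulate_data
from guidedpet.images import VoxelImage


def desk_config(n_realizations: int = 3, n_iterations: int = 120) -> BenchmarkConfig:
    return BenchmarkConfig(
        phantom=PhantomSpec(shape=(64, 64), spacing=2.0),
        acquisition=AcquisitionSpec(
            total_prompts=2e5, n_realizations=n_realizations, base_seed=1234
        ),
        n_angles=96,
        psf_fwhm=4.5,
        n_iterations=n_iterations,
    )


@pytest.fixture(scope="session")
def sim64():
    """Simulated acquisition on the 64x64 / 2 mm desk phantom."""
    return simulate_data(desk_config())


@pytest.fixture(scope="session")
def noisy_small():
    """A small noisy dataset for fast engine-equivalence checks."""
    cfg = BenchmarkConfig(
        phantom=PhantomSpec(shape=(48, 48), spacing=2.0),
        acquisition=AcquisitionSpec(total_prompts=5e4, n_realizations=1, base_seed=7),
        n_angles=64,
        psf_fwhm=4.5,
    )
    data = simulate_data(cfg)
    return data, data.realizations[0]


class DenseModel:
    """Toy forward model from an explicit dense matrix (for closed forms)."""

    def __init__(self, A: np.ndarray, shape: tuple[int, ...]):
        self.A = np.asarray(A, dtype=float)
        self.shape = tuple(shape)
        self.spacing = 1.0

    def project(self, image):
        vals = image.values if isinstance(image, VoxelImage) else np.asarray(image)
        return Sinogram((self.A @ vals.ravel()).reshape(1, -1))

    def backproject(self, sinogram):
        vals = sinogram.values if isinstance(sinogram, Sinogram) else np.asarray(sinogram)
        return (self.A.T @ vals.ravel()).reshape(self.shape)

    def sensitivity(self):
        return self.A.sum(axis=0).reshape(self.shape)


@pytest.fixture
def dense_model_factory():
    def make(rng: np.random.Generator, n_vox: int = 6, n_bins: int = 9) -> DenseModel:
        A = rng.uniform(0.1, 1.0, size=(n_bins, n_vox))
        return DenseModel(A, (n_vox,))

    return make
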