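"""Sparse neighborhood similarity weights shared by kernel and MAP methods.

Every guided method here — KEM, KEM-LVS, HKEM on the kernel side and
Gaussian MR-guided, Bowsher, anato-functional on the MAP side — reduces to
the same construction: compare each voxel with the voxels in its cubic
(square in 2D) spatial neighborhood through a Gaussian similarity in some
feature space, optionally keep only the k nearest neighbors in that
feature space, and normalize.  The methods differ only in

* which feature drives the Gaussian (MR intensity, MR + spatial position,
  or the product of MR and current-PET Gaussians),
* which feature drives the k-nearest-neighbor selection (or none — full
  neighborhood),
* the normalization: kernel rows include the center voxel with
  self-similarity 1 and sum to 1 (``row_sum_1``); MAP neighborhoods
  exclude the center and their weights sum to 1 (``neighborhood_sum_1``).

Sparsification happens before normalization, so zeroed neighbors do not
absorb probability mass.  MR intensities are rescaled to [0, 1] before any
similarity so that sigma_mr values are comparable across inputs; the PET
iterate enters in raw activity units.  Ties in the k-nearest-neighbor
selection break deterministically toward the lower voxel index.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import sparse

from .images import as_values

__all__ = [
    "METHODS",
    "KERNEL_METHODS",
    "MAP_METHODS",
    "NeighborhoodSpec",
    "SimilarityParams",
    "SparseNeighborhoodWeights",
    "gaussian_similarity",
    "composite_feature",
    "knn_select",
    "build_weights",
    "normalize01",
]

KERNEL_METHODS = ("KEM", "KEM_LVS", "HKEM")
MAP_METHODS = ("MR_GAUSSIAN", "BOWSHER", "ANATO_FUNCTIONAL")
METHODS = KERNEL_METHODS + MAP_METHODS
_NEEDS_PET = ("HKEM", "ANATO_FUNCTIONAL")


@dataclass
class NeighborhoodSpec:
    """Cubic/square spatial neighborhood of odd side length (default 5)."""

    side: int = 5
    ndim: int = 2

    def __post_init__(self) -> None:
        if self.side < 1 or self.side % 2 == 0:
            raise ValueError("neighborhood side must be odd and >= 1")
        if self.ndim not in (2, 3):
            raise ValueError("neighborhood must be 2D or 3D")

    @property
    def offsets(self) -> np.ndarray:
        """Neighbor offsets excluding the center, in C order (so the linear
        index offset — and hence the tie-break order — is ascending)."""
        h = self.side // 2
        offs = [
            o
            for o in product(range(-h, h + 1), repeat=self.ndim)
            if any(c != 0 for c in o)
        ]
        return np.array(offs, dtype=np.int64)

    @property
    def n_neighbors(self) -> int:
        return self.side**self.ndim - 1


@dataclass
class SimilarityParams:
    """Per-method similarity configuration (Table-style tags).

    ``k`` counts retained neighbors excluding the center (the center is
    always kept in kernel rows); ``None`` keeps the full neighborhood.
    """

    method: str
    sigma_mr: float | None = None
    sigma_pet: float | None = None
    sigma_s: float | None = None
    k: int | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; one of {METHODS}")
        for name in ("sigma_mr", "sigma_pet", "sigma_s"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")


class SparseNeighborhoodWeights:
    """Per-voxel sparse weights over a spatial neighborhood.

    Wraps a CSR matrix of shape (n_voxels, n_voxels).  ``mode`` records the
    normalization: ``row_sum_1`` rows include the diagonal (kernel matrix
    K), ``neighborhood_sum_1`` rows exclude it (MAP weights w).
    """

    def __init__(self, matrix: sparse.csr_array, shape: tuple[int, ...], mode: str):
        if mode not in ("row_sum_1", "neighborhood_sum_1"):
            raise ValueError(f"unknown normalization mode {mode!r}")
        self.matrix = matrix
        self.shape = tuple(shape)
        self.mode = mode

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def dot(self, flat: np.ndarray) -> np.ndarray:
        return self.matrix @ flat

    def tdot(self, flat: np.ndarray) -> np.ndarray:
        return self.matrix.T @ flat

    def symmetrized(self) -> sparse.csr_array:
        return ((self.matrix + self.matrix.T) * 0.5).tocsr()

    def to_triplets(self) -> np.ndarray:
        """(row, col, value) triplets for inspection / plain-text export."""
        coo = self.matrix.tocoo()
        return np.column_stack([coo.row, coo.col, coo.data])

    def save_triplets(self, path: str) -> None:
        np.savetxt(
            path,
            self.to_triplets(),
            fmt=["%d", "%d", "%.10g"],
            delimiter=",",
            header="row,col,value",
            comments="",
        )


# -- elementary operations ---------------------------------------------------


def gaussian_similarity(a_j, a_l, sigma: float):
    """exp(-(a_j - a_l)^2 / (2 sigma^2)); in (0, 1]."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d = np.asarray(a_j, dtype=float) - np.asarray(a_l, dtype=float)
    return np.exp(-(d**2) / (2.0 * sigma**2))


def composite_feature(x_j, r_j, sigma_mr: float, sigma_s: float) -> np.ndarray:
    """Joint intensity/position feature z = (x/sigma_mr, r/sigma_s); the
    Euclidean metric on z gives the KEM-LVS exponent ||z_j - z_l||^2 / 2."""
    if sigma_mr <= 0 or sigma_s <= 0:
        raise ValueError("sigmas must be positive")
    r = np.atleast_1d(np.asarray(r_j, dtype=float))
    return np.concatenate([[float(x_j) / sigma_mr], r / sigma_s])


def knn_select(feature_distances: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k smallest distances; ties break toward the lower
    candidate index (stable order).  The center voxel is handled by the
    caller — it is always retained in addition to these k."""
    d = np.asarray(feature_distances, dtype=float)
    if not 1 <= k <= d.size:
        raise ValueError(f"k={k} out of range for {d.size} candidates")
    order = np.argsort(d, kind="stable")
    return np.sort(order[:k])


def normalize01(values: np.ndarray) -> np.ndarray:
    """Rescale to [0, 1]; a constant image maps to all zeros."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi <= lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


# -- neighborhood table ------------------------------------------------------


def _neighbor_table(shape: tuple[int, ...], spec: NeighborhoodSpec):
    """Flat neighbor indices (n_vox, n_nb) with validity mask for
    edge-truncated neighborhoods, plus per-column spatial offset norms."""
    coords = np.indices(shape).reshape(len(shape), -1)  # (ndim, n_vox)
    offs = spec.offsets  # (n_nb, ndim)
    nbr_coords = coords[None, :, :] + offs[:, :, None]  # (n_nb, ndim, n_vox)
    valid = np.ones((offs.shape[0], coords.shape[1]), dtype=bool)
    for a, n in enumerate(shape):
        valid &= (nbr_coords[:, a, :] >= 0) & (nbr_coords[:, a, :] < n)
    flat = np.ravel_multi_index(
        tuple(np.clip(nbr_coords[:, a, :], 0, shape[a] - 1) for a in range(len(shape))),
        shape,
    )
    sq_offsets = (offs.astype(float) ** 2).sum(axis=1)  # voxel units
    return flat.T.copy(), valid.T.copy(), sq_offsets  # (n_vox, n_nb)


def _knn_mask(dist: np.ndarray, valid: np.ndarray, k: int) -> np.ndarray:
    """Row-wise k-nearest selection with stable (lower-index-first) ties;
    k is capped at the number of valid candidates per row."""
    d = np.where(valid, dist, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    n_vox, n_nb = d.shape
    kk = min(k, n_nb)
    keep = np.zeros_like(valid)
    rows = np.arange(n_vox)[:, None]
    keep[rows, order[:, :kk]] = True
    return keep & valid


def build_weights(
    params: SimilarityParams,
    mr_image,
    pet_iterate=None,
    neighborhood: NeighborhoodSpec | None = None,
) -> SparseNeighborhoodWeights:
    """Assemble the sparse similarity structure for one method.

    KEM: MR Gaussian, kNN by MR intensity, row_sum_1.
    KEM_LVS: Gaussian on the joint (MR, position) feature, kNN by that
        feature, row_sum_1.
    HKEM: product of MR and current-PET Gaussians, kNN by PET value,
        row_sum_1.
    MR_GAUSSIAN: MR Gaussian, full neighborhood, neighborhood_sum_1.
    BOWSHER: binary 1 on the k MR-nearest neighbors, neighborhood_sum_1.
    ANATO_FUNCTIONAL: product of MR and current-PET Gaussians, full
        neighborhood, neighborhood_sum_1.
    """
    method = params.method
    mr = as_values(mr_image).astype(float)
    if neighborhood is None:
        neighborhood = NeighborhoodSpec(side=5, ndim=mr.ndim)
    if neighborhood.ndim != mr.ndim:
        raise ValueError("neighborhood dimensionality does not match the image")
    pet = None
    if method in _NEEDS_PET:
        if pet_iterate is None:
            raise ValueError(f"{method} requires the current PET iterate")
        pet = as_values(pet_iterate).astype(float)
        if pet.shape != mr.shape:
            raise ValueError("PET iterate and MR image must share the grid")
        if params.sigma_pet is None:
            raise ValueError(f"{method} requires sigma_pet")
    if method != "BOWSHER" and params.sigma_mr is None:
        raise ValueError(f"{method} requires sigma_mr")
    if method == "KEM_LVS" and params.sigma_s is None:
        raise ValueError("KEM_LVS requires sigma_s")

    shape = mr.shape
    nbr, valid, sq_off = _neighbor_table(shape, neighborhood)
    x = normalize01(mr).ravel()
    dx = x[nbr] - x[:, None]

    knn_dist = None
    if method == "KEM":
        w = np.exp(-(dx**2) / (2.0 * params.sigma_mr**2))
        knn_dist = np.abs(dx)
    elif method == "KEM_LVS":
        z2 = (dx / params.sigma_mr) ** 2 + sq_off[None, :] / params.sigma_s**2
        w = np.exp(-z2 / 2.0)
        knn_dist = np.sqrt(z2)
    elif method in ("HKEM", "ANATO_FUNCTIONAL"):
        th = pet.ravel()
        dth = th[nbr] - th[:, None]
        w = np.exp(-(dx**2) / (2.0 * params.sigma_mr**2)) * np.exp(
            -(dth**2) / (2.0 * params.sigma_pet**2)
        )
        if method == "HKEM":
            knn_dist = np.abs(dth)
    elif method == "MR_GAUSSIAN":
        w = np.exp(-(dx**2) / (2.0 * params.sigma_mr**2))
    elif method == "BOWSHER":
        if params.k is None:
            raise ValueError("BOWSHER requires k")
        knn_dist = np.abs(dx)
        w = np.ones_like(dx)
    else:  # pragma: no cover
        raise ValueError(f"unknown method {method!r}")

    keep = valid
    if knn_dist is not None and params.k is not None:
        keep = _knn_mask(knn_dist, valid, params.k)
    w = np.where(keep, w, 0.0)

    n_vox = x.size
    rows = np.repeat(np.arange(n_vox), keep.sum(axis=1))
    cols = nbr[keep]
    data = w[keep]

    kernel = method in KERNEL_METHODS
    if kernel:
        # center voxel: self-similarity 1, always retained
        rows = np.concatenate([rows, np.arange(n_vox)])
        cols = np.concatenate([cols, np.arange(n_vox)])
        data = np.concatenate([data, np.ones(n_vox)])

    mat = sparse.coo_array((data, (rows, cols)), shape=(n_vox, n_vox)).tocsr()
    rs = np.asarray(mat.sum(axis=1)).ravel()
    rs[rs == 0] = 1.0
    mat = sparse.csr_array(sparse.diags_array(1.0 / rs) @ mat)
    mode = "row_sum_1" if kernel else "neighborhood_sum_1"
    return SparseNeighborhoodWeights(mat, shape, mode)
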