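"""Iterative reconstruction: MLEM, kernelized EM, and De Pierro MAP-EM.

All methods maximize (or penalize) the Poisson log-likelihood
L = sum_i m_i log q_i - q_i with q = A theta + b.

MLEM is the multiplicative EM update
theta' = theta / (A^T 1) * A^T[m / (A theta + b)].

The kernel methods reparameterize theta = K alpha with K a row-normalized
guidance-similarity matrix and run EM on the coefficients:
alpha' = alpha / (K^T A^T 1) * K^T A^T[m / (A K alpha + b)].
HKEM rebuilds K each iteration from the current image.

The MAP methods penalize a weighted quadratic roughness
R(theta) = sum_j sum_{l in N_j} w_jl (theta_j - theta_l)^2 and take, per
iteration, one EM step followed by De Pierro's separable surrogate
maximizer, evaluated in the cancellation-free root form
theta' = 2B / (D + sqrt(D^2 + 4 C B)) with
D_j = s_j - (beta/2) sum_l w_jl (theta_j + theta_l),
B_j = theta_EM_j s_j,  C_j = beta sum_l w_jl,  s = A^T 1.
The weights are symmetrized first — R depends only on the symmetric part
of w, and symmetrization is what makes the surrogate argument (and hence
monotone ascent of the penalized objective) exact.  With the neighborhood
double counting and the surrogate's 1/2 convention, this update ascends
Omega = L - (beta/8) R exactly; that is the objective traced and reported.
The anato-functional method refreshes w from the current iterate each
iteration (no monotonicity guarantee, like HKEM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, sparse

from .forward_model import FWHM_TO_SIGMA, ForwardModel, Sinogram
from .images import VoxelImage, as_values
from .similarity import (
    KERNEL_METHODS,
    MAP_METHODS,
    NeighborhoodSpec,
    SimilarityParams,
    SparseNeighborhoodWeights,
    build_weights,
)

__all__ = [
    "ReconConfig",
    "ReconResult",
    "mlem_update",
    "kem_reconstruct",
    "depierro_map_update",
    "reconstruct",
    "postsmooth",
    "poisson_loglik",
    "quadratic_penalty",
    "map_objective",
]

SENS_FLOOR = 1e-12


@dataclass
class ReconConfig:
    """Reconstruction settings.

    ``beta`` applies to MAP methods only; ``post_fwhm_mm`` lists
    post-reconstruction smoothing levels for MLEM; ``snapshot_iters``
    selects iterates to keep (1-based iteration numbers).
    """

    method: str = "MLEM"
    similarity: SimilarityParams | None = None
    beta: float = 0.0
    n_iterations: int = 300
    initial: np.ndarray | None = None
    post_fwhm_mm: tuple[float, ...] = ()
    snapshot_iters: tuple[int, ...] = ()
    neighborhood: NeighborhoodSpec | None = None

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class ReconResult:
    image: VoxelImage
    trace: pd.DataFrame  # columns: iteration, loglik, penalty, objective
    snapshots: dict[int, np.ndarray] = field(default_factory=dict)
    postsmoothed: dict[float, VoxelImage] = field(default_factory=dict)
    config: ReconConfig | None = None


# -- objective pieces --------------------------------------------------------


def _ratio(m: np.ndarray, q: np.ndarray) -> np.ndarray:
    """m/q with 0/0 := 0; m > 0 where q = 0 is a model inconsistency."""
    bad = (q <= 0) & (m > 0)
    if bad.any():
        raise ValueError("measured counts in bins with zero expected counts")
    out = np.zeros_like(q)
    pos = q > 0
    out[pos] = m[pos] / q[pos]
    return out


def poisson_loglik(theta, m, model: ForwardModel, background=None) -> float:
    """Eq.-style Poisson log-likelihood sum_i m_i log q_i - q_i (the
    theta-independent log m_i! term is omitted)."""
    q = _expected(theta, model, background)
    mv = _sino_values(m)
    if ((q <= 0) & (mv > 0)).any():
        raise ValueError("zero expected counts where data are positive")
    pos = q > 0
    return float((mv[pos] * np.log(q[pos])).sum() - q.sum())


def quadratic_penalty(theta, weights: SparseNeighborhoodWeights | sparse.csr_array) -> float:
    """R(theta) = sum_j sum_l w_jl (theta_j - theta_l)^2 (pairwise form;
    identical for w and its symmetrization)."""
    W = weights.matrix if isinstance(weights, SparseNeighborhoodWeights) else weights
    coo = W.tocoo()
    t = as_values(theta).ravel()
    d = t[coo.row] - t[coo.col]
    return float((coo.data * d * d).sum())


def map_objective(theta, m, model, weights, beta: float, background=None) -> float:
    """Penalized objective the De Pierro update ascends:
    Omega = L - (beta/8) R(theta)."""
    pen = (beta / 8.0) * quadratic_penalty(theta, weights) if beta > 0 else 0.0
    return poisson_loglik(theta, m, model, background) - pen


# -- elementary updates ------------------------------------------------------


def _sino_values(m) -> np.ndarray:
    return m.values if isinstance(m, Sinogram) else np.asarray(m, dtype=float)


def _expected(theta, model, background) -> np.ndarray:
    q = model.project(as_values(theta)).values
    if background is not None:
        q = q + _sino_values(background)
    return q


def mlem_update(theta, m, model, sens, background=None) -> np.ndarray:
    """One MLEM step; voxels with (near-)zero sensitivity stay at zero."""
    th = as_values(theta).astype(float)
    s = as_values(sens)
    q = _expected(th, model, background)
    r = _ratio(_sino_values(m), q)
    bp = as_values(model.backproject(r))
    out = np.zeros_like(th)
    ok = s > SENS_FLOOR
    out[ok] = th[ok] / s[ok] * bp[ok]
    return out


def depierro_map_update(theta, theta_em, sens, weights, beta: float) -> np.ndarray:
    """De Pierro separable MAP step from the current iterate ``theta`` and
    its EM image ``theta_em``; ``weights`` are neighborhood-normalized MAP
    weights (symmetrized internally)."""
    th = as_values(theta).astype(float).ravel()
    tem = as_values(theta_em).astype(float).ravel()
    s = as_values(sens).astype(float).ravel()
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if beta == 0:
        return tem.reshape(as_values(theta).shape).copy()

    if isinstance(weights, SparseNeighborhoodWeights):
        W = weights.symmetrized()
    else:
        W = ((weights + weights.T) * 0.5).tocsr()
    rs = np.asarray(W.sum(axis=1)).ravel()
    C = beta * rs
    D = s - 0.5 * beta * (th * rs + W @ th)
    B = tem * s

    out = np.empty_like(th)
    pos = C > 0
    disc = np.sqrt(D[pos] ** 2 + 4.0 * C[pos] * B[pos])
    denom = D[pos] + disc
    out[pos] = np.where(denom > 0, 2.0 * B[pos] / np.where(denom > 0, denom, 1.0), 0.0)
    zero = ~pos
    if zero.any():
        if (D[zero] <= 0).any() and (B[zero] > 0).any():
            raise ValueError("degenerate MAP update: C=0 with D<=0 on support")
        out[zero] = np.where(D[zero] > 0, B[zero] / np.where(D[zero] > 0, D[zero], 1.0), 0.0)
    return out.reshape(as_values(theta).shape)


def postsmooth(image, fwhm_mm: float, spacing: float | None = None):
    """Gaussian post-reconstruction smoothing; fwhm 0 is the identity."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if isinstance(image, VoxelImage):
        sp = image.spacing[0]
        if fwhm_mm == 0:
            return image.copy()
        sig = fwhm_mm * FWHM_TO_SIGMA / sp
        return image.with_values(
            ndimage.gaussian_filter(image.values, sig, mode="nearest", truncate=8.0)
        )
    vals = np.asarray(image, dtype=float)
    if fwhm_mm == 0:
        return vals.copy()
    sp = 1.0 if spacing is None else spacing
    return ndimage.gaussian_filter(
        vals, fwhm_mm * FWHM_TO_SIGMA / sp, mode="nearest", truncate=8.0
    )


# -- engines -----------------------------------------------------------------


def _support_init(model: ForwardModel, initial):
    sens = as_values(model.sensitivity()).astype(float)
    support = sens > SENS_FLOOR * max(sens.max(), 1.0)
    if initial is None:
        theta0 = np.where(support, 1.0, 0.0)
    else:
        theta0 = as_values(initial).astype(float).copy()
        theta0[~support] = 0.0
    return sens, support, theta0


def _trace_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["iteration", "loglik", "penalty", "objective"])


def mlem_reconstruct(m, model, config: ReconConfig, background=None) -> ReconResult:
    sens, _, theta = _support_init(model, config.initial)
    mv = _sino_values(m)
    rows, snaps = [], {}
    for it in range(1, config.n_iterations + 1):
        theta = mlem_update(theta, mv, model, sens, background)
        ll = poisson_loglik(theta, mv, model, background)
        rows.append((it, ll, 0.0, ll))
        if it in config.snapshot_iters:
            snaps[it] = theta.copy()
    img = VoxelImage(theta, (model.spacing,) * 2)
    post = {f: postsmooth(img, f) for f in config.post_fwhm_mm}
    return ReconResult(img, _trace_frame(rows), snaps, post, config)


def kem_reconstruct(
    m,
    model,
    K: SparseNeighborhoodWeights | sparse.csr_array,
    config: ReconConfig,
    background=None,
    weight_fn=None,
) -> ReconResult:
    """Kernelized EM.  ``K`` is the (static) row-normalized kernel matrix;
    for HKEM pass ``weight_fn(theta_image) -> SparseNeighborhoodWeights`` to
    rebuild the kernel from the current image before each update."""

    def _mat(k):
        return k.matrix if isinstance(k, SparseNeighborhoodWeights) else k

    Kmat = _mat(K)
    rsums = np.asarray(np.abs(Kmat.sum(axis=1)) - 1.0).ravel()
    if rsums.max() > 1e-8:
        raise ValueError("kernel matrix must be row-normalized")

    sens, _, theta0 = _support_init(model, config.initial)
    shape = model.shape
    mv = _sino_values(m)
    sens_flat = sens.ravel()

    alpha = theta0.ravel().copy()
    rows, snaps = [], {}
    for it in range(1, config.n_iterations + 1):
        if weight_fn is not None:
            theta_img = (Kmat @ alpha).reshape(shape)
            Kmat = _mat(weight_fn(theta_img))
        theta = (Kmat @ alpha).reshape(shape)
        q = _expected(theta, model, background)
        r = _ratio(mv, q)
        bp = as_values(model.backproject(r)).ravel()
        ksens = Kmat.T @ sens_flat
        upd = np.zeros_like(alpha)
        ok = ksens > SENS_FLOOR
        upd[ok] = (Kmat.T @ bp)[ok] / ksens[ok]
        alpha = alpha * upd
        theta = (Kmat @ alpha).reshape(shape)
        ll = poisson_loglik(theta, mv, model, background)
        rows.append((it, ll, 0.0, ll))
        if it in config.snapshot_iters:
            snaps[it] = theta.copy()
    img = VoxelImage(theta, (model.spacing,) * 2)
    return ReconResult(img, _trace_frame(rows), snaps, {}, config)


def map_reconstruct(
    m, model, weights, config: ReconConfig, background=None, weight_fn=None
) -> ReconResult:
    """De Pierro MAP-EM with static weights, or adaptive weights when
    ``weight_fn(theta_image)`` is given (anato-functional)."""
    sens, _, theta = _support_init(model, config.initial)
    mv = _sino_values(m)
    rows, snaps = [], {}
    W = weights
    for it in range(1, config.n_iterations + 1):
        if weight_fn is not None:
            W = weight_fn(theta)
        theta_em = mlem_update(theta, mv, model, sens, background)
        theta = depierro_map_update(theta, theta_em, sens, W, config.beta)
        ll = poisson_loglik(theta, mv, model, background)
        pen = (config.beta / 8.0) * quadratic_penalty(theta, W) if config.beta else 0.0
        rows.append((it, ll, pen, ll - pen))
        if it in config.snapshot_iters:
            snaps[it] = theta.copy()
    img = VoxelImage(theta, (model.spacing,) * 2)
    return ReconResult(img, _trace_frame(rows), snaps, {}, config)


def reconstruct(
    method: str,
    m,
    model: ForwardModel,
    mr_image=None,
    config: ReconConfig | None = None,
    background=None,
) -> ReconResult:
    """Dispatch a full reconstruction by method tag.

    MLEM needs no guidance; kernel methods build K from the MR (HKEM also
    from the evolving PET image); MAP methods build neighborhood weights
    (the anato-functional weights refresh each iteration from the previous
    iterate, so iteration 1 is effectively MR-only under a uniform start).
    """
    if config is None:
        config = ReconConfig(method=method)
    if method == "MLEM":
        return mlem_reconstruct(m, model, config, background)

    if mr_image is None:
        raise ValueError(f"{method} requires an MR guidance image")
    if config.similarity is None:
        raise ValueError(f"{method} requires similarity parameters")
    params = config.similarity
    if params.method != method:
        raise ValueError(
            f"config.similarity.method={params.method!r} does not match {method!r}"
        )
    mr = as_values(mr_image)
    nb = config.neighborhood or NeighborhoodSpec(side=5, ndim=mr.ndim)

    if method in KERNEL_METHODS:
        if method == "HKEM":
            k0 = build_weights(
                params, mr, pet_iterate=np.ones_like(mr, dtype=float), neighborhood=nb
            )
            return kem_reconstruct(
                m,
                model,
                k0,
                config,
                background,
                weight_fn=lambda th: build_weights(params, mr, pet_iterate=th, neighborhood=nb),
            )
        K = build_weights(params, mr, neighborhood=nb)
        return kem_reconstruct(m, model, K, config, background)

    if method in MAP_METHODS:
        if method == "ANATO_FUNCTIONAL":
            w0 = build_weights(
                params, mr, pet_iterate=np.ones_like(mr, dtype=float), neighborhood=nb
            )
            return map_reconstruct(
                m,
                model,
                w0,
                config,
                background,
                weight_fn=lambda th: build_weights(params, mr, pet_iterate=th, neighborhood=nb),
            )
        w = build_weights(params, mr, neighborhood=nb)
        return map_reconstruct(m, model, w, config, background)

    raise ValueError(f"unknown reconstruction method {method!r}")
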