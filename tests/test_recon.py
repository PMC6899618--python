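"""Reconstruction engines: closed forms, surrogate oracle, equivalences."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.optimize import minimize_scalar

from guidedpet import (
    ReconConfig,
    SimilarityParams,
    depierro_map_update,
    kem_reconstruct,
    map_objective,
    mlem_update,
    poisson_loglik,
    postsmooth,
    quadratic_penalty,
    reconstruct,
)
from guidedpet.metrics import RealizationStack, roi_nrmse
from guidedpet.similarity import build_weights
from tests.conftest import DenseModel


# -- MLEM --------------------------------------------------------------------


def test_mlem_single_voxel_closed_form():
    model = DenseModel(np.array([[1.0]]), (1,))
    out = mlem_update(np.array([1.0]), np.array([[5.0]]), model, np.array([1.0]))
    assert out[0] == pytest.approx(5.0)


def test_mlem_fixed_point_on_consistent_data(dense_model_factory):
    rng = np.random.default_rng(0)
    model = dense_model_factory(rng)
    theta = rng.uniform(0.5, 2.0, size=6)
    m = model.project(theta).values
    out = mlem_update(theta, m, model, model.sensitivity())
    np.testing.assert_allclose(out, theta, rtol=1e-12)


def test_mlem_count_conservation(dense_model_factory):
    """With no background, sum_j sens_j theta'_j = sum_i m_i identically."""
    rng = np.random.default_rng(1)
    for _ in range(10):
        model = dense_model_factory(rng)
        theta = rng.uniform(0.1, 3.0, size=6)
        m = rng.poisson(model.project(theta).values + 1.0).astype(float)
        sens = model.sensitivity()
        out = mlem_update(theta, m, model, sens)
        assert float((sens * out).sum()) == pytest.approx(float(m.sum()), rel=1e-12)


def test_mlem_rejects_counts_without_support():
    model = DenseModel(np.zeros((2, 1)), (1,))
    with pytest.raises(ValueError):
        mlem_update(np.array([1.0]), np.array([[1.0, 0.0]]), model, np.array([1.0]))


def test_mlem_loglik_monotone_on_random_instances(dense_model_factory):
    rng = np.random.default_rng(2)
    for _ in range(20):
        model = dense_model_factory(rng)
        theta = np.ones(6)
        m = rng.poisson(model.project(rng.uniform(0.2, 2.0, 6)).values + 0.5).astype(float)
        sens = model.sensitivity()
        prev = poisson_loglik(theta, m, model)
        for _ in range(15):
            theta = mlem_update(theta, m, model, sens)
            cur = poisson_loglik(theta, m, model)
            assert cur >= prev - 1e-9 * abs(prev)
            prev = cur


def test_poisson_loglik_closed_form():
    model = DenseModel(np.array([[1.0]]), (1,))
    assert poisson_loglik(np.array([1.0]), np.array([[1.0]]), model) == pytest.approx(-1.0)


# -- De Pierro MAP -----------------------------------------------------------


def _surrogate_argmax(B, s, beta, wl, c_l):
    """Brute-force maximizer of the separable surrogate
    Phi(t) = B log t - s t - (beta/8) sum_l w_l (2t - c_l)^2."""

    def neg(t):
        return -(B * np.log(t) - s * t - beta / 8.0 * (wl * (2 * t - c_l) ** 2).sum())

    res = minimize_scalar(neg, bounds=(1e-12, 1e4), method="bounded",
                          options={"xatol": 1e-12})
    return res.x


def test_depierro_beta_zero_returns_em_image():
    W = sp.csr_array(sp.identity(4) * 0)
    theta = np.array([1.0, 2.0, 3.0, 4.0])
    tem = np.array([2.0, 1.0, 5.0, 0.5])
    out = depierro_map_update(theta, tem, np.ones(4), W, beta=0.0)
    np.testing.assert_array_equal(out, tem)


def test_depierro_matches_surrogate_oracle_single_neighbor():
    """Voxel with one neighbor at 0: the root of the update quadratic is the
    maximizer of the decoupled surrogate (independent 1-D search)."""
    W = sp.csr_array(np.array([[0.0, 1.0], [1.0, 0.0]]))
    theta = np.array([2.0, 0.0])
    tem = np.array([2.0, 0.0])
    sens = np.array([1.0, 1.0])
    out = depierro_map_update(theta, tem, sens, W, beta=1.0)
    expect = _surrogate_argmax(B=2.0, s=1.0, beta=1.0, wl=np.array([1.0]),
                               c_l=np.array([2.0 + 0.0]))
    assert out[0] == pytest.approx(expect, rel=1e-6)


def test_depierro_matches_surrogate_oracle_random_instances():
    rng = np.random.default_rng(3)
    n = 8
    for trial in range(5):
        Wd = rng.uniform(0.0, 1.0, size=(n, n))
        np.fill_diagonal(Wd, 0.0)
        W = sp.csr_array(Wd)
        Wsym = 0.5 * (Wd + Wd.T)
        theta = rng.uniform(0.1, 3.0, size=n)
        tem = rng.uniform(0.1, 3.0, size=n)
        sens = rng.uniform(0.5, 2.0, size=n)
        beta = rng.uniform(0.1, 2.0)
        out = depierro_map_update(theta, tem, sens, W, beta)
        for j in range(n):
            expect = _surrogate_argmax(
                B=tem[j] * sens[j], s=sens[j], beta=beta,
                wl=Wsym[j], c_l=theta[j] + theta,
            )
            assert out[j] == pytest.approx(expect, rel=1e-6)


def test_depierro_uniform_image_is_fixed_point(dense_model_factory):
    """Consistent data + uniform image: the penalty gradient vanishes and
    the MAP step returns the image unchanged, for any beta."""
    rng = np.random.default_rng(4)
    model = dense_model_factory(rng)
    theta = np.full(6, 1.7)
    m = model.project(theta).values
    sens = model.sensitivity()
    tem = mlem_update(theta, m, model, sens)
    Wd = rng.uniform(0.0, 1.0, size=(6, 6))
    np.fill_diagonal(Wd, 0.0)
    out = depierro_map_update(theta, tem, sens, sp.csr_array(Wd), beta=5.0)
    np.testing.assert_allclose(out, theta, rtol=1e-10)


def test_quadratic_penalty_zero_for_constant_image():
    mr = np.random.default_rng(5).random((10, 10))
    w = build_weights(SimilarityParams("MR_GAUSSIAN", sigma_mr=0.3), mr)
    assert quadratic_penalty(np.full((10, 10), 2.5), w) == pytest.approx(0.0, abs=1e-12)
    assert quadratic_penalty(mr, w) > 0


# -- post-smoothing ----------------------------------------------------------


def test_postsmooth_identity_and_mass():
    img = np.zeros((60, 60))
    img[20:40, 20:40] = np.random.default_rng(6).random((20, 20))  # interior support
    np.testing.assert_array_equal(postsmooth(img, 0.0), img)
    sm = postsmooth(img, 3.5, spacing=1.0)
    assert sm.sum() == pytest.approx(img.sum(), rel=1e-6)


def test_postsmooth_delta_fwhm():
    d = np.zeros((81, 81))
    d[40, 40] = 1.0
    prof = postsmooth(d, 3.5, spacing=1.0)[40]
    x = np.arange(81.0)
    mu = (x * prof).sum() / prof.sum()
    sigma = np.sqrt(((x - mu) ** 2 * prof).sum() / prof.sum())
    assert sigma * 2.3548 == pytest.approx(3.5, abs=0.2)


def test_postsmooth_semigroup():
    d = np.zeros((101, 101))
    d[50, 50] = 1.0
    two = postsmooth(postsmooth(d, 3.5), 3.5)
    one = postsmooth(d, 3.5 * np.sqrt(2.0))
    assert np.abs(two - one).max() / one.max() < 1e-6


# -- engine equivalences -----------------------------------------------------


def test_kem_with_identity_kernel_matches_mlem(noisy_small):
    data, m = noisy_small
    n = int(np.prod(data.model.shape))
    cfg = ReconConfig("MLEM", n_iterations=15)
    ref = reconstruct("MLEM", m, data.model, None, cfg, background=data.background)
    K = sp.csr_array(sp.identity(n, format="csr"))
    kem = kem_reconstruct(m, data.model, K, cfg, background=data.background)
    diff = np.abs(kem.image.values - ref.image.values).max()
    assert diff <= 1e-12 * ref.image.values.max()


def test_map_beta_zero_matches_mlem(noisy_small):
    data, m = noisy_small
    ref = reconstruct("MLEM", m, data.model, None, ReconConfig("MLEM", n_iterations=15),
                      background=data.background)
    cfg = ReconConfig("MR_GAUSSIAN", SimilarityParams("MR_GAUSSIAN", sigma_mr=0.1),
                      beta=0.0, n_iterations=15)
    out = reconstruct("MR_GAUSSIAN", m, data.model, data.bundle.mr_image, cfg,
                      background=data.background)
    np.testing.assert_array_equal(out.image.values, ref.image.values)


def test_constant_mr_gives_uniform_quadratic_trajectory(noisy_small):
    data, m = noisy_small
    const = np.ones(data.model.shape)
    a = reconstruct("MR_GAUSSIAN", m, data.model, const,
                    ReconConfig("MR_GAUSSIAN", SimilarityParams("MR_GAUSSIAN", sigma_mr=0.5),
                                beta=50.0, n_iterations=10), background=data.background)
    b = reconstruct("BOWSHER", m, data.model, const,
                    ReconConfig("BOWSHER", SimilarityParams("BOWSHER", k=24),
                                beta=50.0, n_iterations=10), background=data.background)
    np.testing.assert_allclose(a.image.values, b.image.values, rtol=1e-10)


def test_anato_first_iteration_is_mr_only(noisy_small):
    """From a uniform start the PET Gaussian is 1 everywhere, so iteration 1
    of the anato-functional method equals the Gaussian MR-guided method."""
    data, m = noisy_small
    a = reconstruct(
        "ANATO_FUNCTIONAL", m, data.model, data.bundle.mr_image,
        ReconConfig("ANATO_FUNCTIONAL",
                    SimilarityParams("ANATO_FUNCTIONAL", sigma_mr=0.1, sigma_pet=0.01),
                    beta=100.0, n_iterations=1),
        background=data.background)
    b = reconstruct(
        "MR_GAUSSIAN", m, data.model, data.bundle.mr_image,
        ReconConfig("MR_GAUSSIAN", SimilarityParams("MR_GAUSSIAN", sigma_mr=0.1),
                    beta=100.0, n_iterations=1),
        background=data.background)
    np.testing.assert_allclose(a.image.values, b.image.values, rtol=1e-10)


def test_reconstruct_is_deterministic(noisy_small):
    data, m = noisy_small
    cfg = ReconConfig("HKEM", SimilarityParams("HKEM", sigma_mr=0.1, sigma_pet=0.01, k=8),
                      n_iterations=8)
    a = reconstruct("HKEM", m, data.model, data.bundle.mr_image, cfg,
                    background=data.background)
    b = reconstruct("HKEM", m, data.model, data.bundle.mr_image, cfg,
                    background=data.background)
    assert np.array_equal(a.image.values, b.image.values)
    assert a.trace.equals(b.trace)


def test_unknown_method_rejected(noisy_small):
    data, m = noisy_small
    with pytest.raises(ValueError):
        reconstruct("OSEM", m, data.model, None, ReconConfig("MLEM", n_iterations=1))


def test_kem_noiseless_nrmse_decreases(sim64):
    """On consistent (noiseless) data the kernel-EM image error shrinks
    monotonically after the first update."""
    cfg = ReconConfig("KEM", SimilarityParams("KEM", sigma_mr=1.0, k=8),
                      n_iterations=50, snapshot_iters=tuple(range(1, 51)))
    res = reconstruct("KEM", sim64.expected, sim64.model, sim64.bundle.mr_image, cfg,
                      background=sim64.background)
    gt = sim64.bundle.pet_ground_truth.values
    brain = sim64.bundle.roi_masks["whole_brain"].values
    nr = np.array([
        roi_nrmse(RealizationStack([res.snapshots[i] / sim64.count_scale], gt), brain)
        for i in range(1, 51)
    ])
    assert (np.diff(nr[1:]) < 0).all()
    assert nr[-1] < 0.6 * nr[0]


def test_adaptive_methods_stabilize(sim64):
    """HKEM and anato-functional have no monotonicity guarantee, but their
    objective plateaus by 300 iterations (fixed-point behavior) and the
    residual image drift is no worse than a few times plain MLEM's."""
    mlem = reconstruct("MLEM", sim64.expected, sim64.model, None,
                       ReconConfig("MLEM", n_iterations=300, snapshot_iters=(290, 300)),
                       background=sim64.background)
    drift_mlem = (np.linalg.norm(mlem.snapshots[300] - mlem.snapshots[290])
                  / np.linalg.norm(mlem.snapshots[290]))
    for method, sim, beta in (
        ("HKEM", SimilarityParams("HKEM", sigma_mr=0.1, sigma_pet=0.01, k=8), 0.0),
        ("ANATO_FUNCTIONAL",
         SimilarityParams("ANATO_FUNCTIONAL", sigma_mr=0.1, sigma_pet=0.01), 1e3),
    ):
        cfg = ReconConfig(method, sim, beta=beta, n_iterations=300,
                          snapshot_iters=(290, 300))
        res = reconstruct(method, sim64.expected, sim64.model, sim64.bundle.mr_image,
                          cfg, background=sim64.background)
        obj = res.trace["objective"].to_numpy()
        assert abs(obj[299] - obj[289]) < 1e-4 * abs(obj[289])
        drift = (np.linalg.norm(res.snapshots[300] - res.snapshots[290])
                 / np.linalg.norm(res.snapshots[290]))
        assert drift < 3.0 * drift_mlem


def test_map_objective_consistent_with_pieces(noisy_small):
    data, m = noisy_small
    mr = data.bundle.mr_image
    w = build_weights(SimilarityParams("MR_GAUSSIAN", sigma_mr=0.1), mr.values)
    theta = np.abs(np.random.default_rng(8).random(data.model.shape)) + 0.1
    beta = 10.0
    omega = map_objective(theta, m, data.model, w, beta, background=data.background)
    ll = poisson_loglik(theta, m, data.model, background=data.background)
    assert omega == pytest.approx(ll - beta / 8.0 * quadratic_penalty(theta, w))
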