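"""Hierarchical Bayesian inversion: regularizer algebra, conditional
samplers against analytic oracles, Tikhonov equivalence, posterior
variance bounds, force conservation."""

import numpy as np
import pytest
import scipy.stats as st

from tfmuq.elastic import SubstrateModel, build_spectral_kernel, assemble_dense_operator
from tfmuq.bayes import (
    ObservationModel,
    HyperPriors,
    GibbsConfig,
    build_laplacian,
    heteroskedastic_prior_variant,
    likelihood_logpdf,
    sample_t_conditional,
    sample_alpha_conditional,
    sample_beta_conditional,
    run_gibbs,
)
from tfmuq.tikhonov import solve_tikhonov


@pytest.fixture()
def toy_obs(small_operator):
    """Synthetic observation on the 8x8 grid: smooth truth + noise."""
    rng = np.random.default_rng(0)
    ny, nx = 8, 8
    x = np.linspace(0, 2 * np.pi, nx, endpoint=False)
    tx = 200.0 * np.outer(np.sin(np.linspace(0, np.pi, ny)), np.cos(x))
    ty = np.zeros_like(tx)
    tvec = np.concatenate([tx.ravel(), ty.ravel()])
    uh = small_operator.M @ tvec
    uh = uh + rng.normal(0, 0.01 * np.abs(uh).max(), uh.size)
    return ObservationModel(
        uh=uh, sigma2=np.zeros(uh.size), operator=small_operator
    ), tvec


class TestLaplacian:
    def test_annihilates_constants(self):
        reg = build_laplacian((6, 7))
        t = np.concatenate([np.full(42, 3.3), np.full(42, -1.1)])
        assert reg.energy(t) == pytest.approx(0.0, abs=1e-20)

    def test_linear_field_zero_in_interior(self):
        reg = build_laplacian((6, 6))
        xs = np.tile(np.arange(6.0), (6, 1))
        t = np.concatenate([xs.ravel(), np.zeros(36)])
        lt = (reg.L @ t)[:36].reshape(6, 6)
        assert np.allclose(lt[1:-1, 1:-1], 0.0, atol=1e-12)

    def test_cosine_mode_matches_stencil_eigenvalue(self):
        """With whole-sample mirror boundaries the 1-D stencil has
        eigenvectors cos(pi m j/(n-1)) and eigenvalues
        -4 sin^2(pi m / (2(n-1))); a field varying only along x probes
        the x-part of the 2-D stencil (the y-part sees a constant)."""
        n, m = 12, 3
        reg = build_laplacian((n, n))
        lam = -4 * np.sin(np.pi * m / (2 * (n - 1))) ** 2
        v = np.cos(np.pi * m * np.arange(n) / (n - 1))
        field = np.tile(v, (n, 1))
        t = np.concatenate([field.ravel(), np.zeros(n * n)])
        lt = (reg.L @ t)[: n * n].reshape(n, n)
        assert np.allclose(lt, lam * field, atol=1e-12)
        assert reg.energy(t) == pytest.approx(lam**2 * n * (v @ v))

    def test_identity_variant(self):
        reg = build_laplacian((4, 4), variant="identity")
        t = np.arange(32.0)
        assert reg.energy(t) == pytest.approx(t @ t)


class TestLikelihood:
    def test_zero_residual_closed_form(self, small_operator):
        nw = small_operator.n_windows
        rng = np.random.default_rng(1)
        t = rng.normal(size=2 * nw)
        uh = small_operator.M @ t
        obs = ObservationModel(uh=uh, sigma2=np.zeros(2 * nw), operator=small_operator)
        beta = 7.5
        lp = likelihood_logpdf(t, 1.0, beta, obs)
        assert lp == pytest.approx(-nw * np.log(2 * np.pi) + nw * np.log(beta))

    def test_matches_multivariate_normal(self, small_operator):
        nw = small_operator.n_windows
        rng = np.random.default_rng(2)
        t = rng.normal(size=2 * nw)
        uh = small_operator.M @ t + rng.normal(0, 0.01, 2 * nw)
        sigma2 = rng.uniform(0.001, 0.01, 2 * nw)
        beta = 3.0
        obs = ObservationModel(uh=uh, sigma2=sigma2, operator=small_operator)
        lp = likelihood_logpdf(t, 1.0, beta, obs)
        ref = st.multivariate_normal.logpdf(
            uh, mean=small_operator.M @ t, cov=np.diag(1 / beta + sigma2)
        )
        assert lp == pytest.approx(ref, rel=1e-10)

    def test_invalid_beta_rejected(self, toy_obs):
        obs, tvec = toy_obs
        with pytest.raises(ValueError):
            likelihood_logpdf(tvec, 1.0, -1.0, obs)


class TestAlphaConditional:
    def test_zero_energy_gamma_moments(self):
        """With Lt = 0 the conditional is Gamma(Nw+1, phi_a)."""
        reg = build_laplacian((4, 4))
        t = np.ones(32)  # constant per component -> Lt = 0
        hyper = HyperPriors()
        rng = np.random.default_rng(3)
        nw = 16
        draws = np.array(
            [sample_alpha_conditional(t, reg, hyper, nw, rng) for _ in range(20000)]
        )
        mean = (nw + 1) / hyper.phi_alpha
        assert draws.mean() == pytest.approx(mean, rel=0.03)
        assert draws.std() == pytest.approx(np.sqrt(nw + 1) / hyper.phi_alpha, rel=0.05)

    def test_rate_scales_with_prior_energy(self):
        reg = build_laplacian((4, 4))
        rng1, rng2 = np.random.default_rng(4), np.random.default_rng(4)
        t = np.sin(np.arange(32.0))
        hyper = HyperPriors(phi_alpha=1e-12)
        d1 = np.mean([sample_alpha_conditional(t, reg, hyper, 16, rng1) for _ in range(5000)])
        d2 = np.mean([sample_alpha_conditional(np.sqrt(2) * t, reg, hyper, 16, rng2) for _ in range(5000)])
        assert d1 / d2 == pytest.approx(2.0, rel=0.1)


class TestBetaConditional:
    def test_reduces_to_gamma_when_sigma_zero(self, toy_obs):
        """With Sigma_PIV = 0 the numerical inverse-transform sampler
        must reproduce the analytic Gamma conditional's moments."""
        obs, tvec = toy_obs
        hyper = HyperPriors()
        rng = np.random.default_rng(5)
        t = tvec * 0.9
        r = obs.uh - obs.operator.M @ t
        nw = obs.n_windows
        shape = nw + hyper.theta_beta
        rate = 0.5 * (r @ r) + hyper.phi_beta
        draws = np.array(
            [sample_beta_conditional(t, obs, hyper, rng) for _ in range(2000)]
        )
        assert draws.mean() == pytest.approx(shape / rate, rel=0.02)
        assert draws.std() == pytest.approx(np.sqrt(shape) / rate, rel=0.06)

    def test_deterministic_under_seed(self, toy_obs):
        obs, tvec = toy_obs
        hyper = HyperPriors()
        a = sample_beta_conditional(tvec, obs, hyper, np.random.default_rng(6))
        b = sample_beta_conditional(tvec, obs, hyper, np.random.default_rng(6))
        assert a == b


class TestTConditional:
    def test_moments_match_gaussian_formula(self, substrate):
        """Empirical mean/covariance of draws match the analytic
        conditional N(S M^T Lam^-1 uh, S) on a tiny grid."""
        kernel = build_spectral_kernel(substrate, (2, 2), 20.0)
        op = assemble_dense_operator(kernel)
        rng = np.random.default_rng(7)
        uh = rng.normal(0, 0.5, 8)
        sigma2 = rng.uniform(0.01, 0.05, 8)
        obs = ObservationModel(uh=uh, sigma2=sigma2, operator=op)
        reg = build_laplacian((2, 2))
        alpha, beta = 1e-4, 50.0
        lam = 1 / beta + sigma2
        A = op.M.T @ np.diag(1 / lam) @ op.M + alpha * reg.P
        S = np.linalg.inv(A)
        mean = S @ (op.M.T @ (uh / lam))
        draws = np.array(
            [
                sample_t_conditional(alpha, beta, obs, reg, rng)
                for _ in range(40000)
            ]
        )
        scale = np.sqrt(np.diag(S))
        assert np.allclose(draws.mean(axis=0), mean, atol=4 * scale.max() / np.sqrt(40000) * 3)
        emp_cov = np.cov(draws.T)
        assert np.allclose(emp_cov, S, atol=0.05 * np.abs(S).max())

    def test_strong_prior_shrinks_to_zero(self, toy_obs):
        obs, _ = toy_obs
        reg = build_laplacian((8, 8), variant="identity")
        rng = np.random.default_rng(8)
        t = sample_t_conditional(1e12, 1.0, obs, reg, rng)
        assert np.abs(t).max() < 1e-3


class TestTikhonovEquivalence:
    def test_clamped_hyperparameters_reproduce_tikhonov(self, toy_obs):
        """With Sigma_PIV = 0 and fixed (alpha, beta) the Gaussian
        conditional mean equals the Tikhonov solution at lambda =
        alpha/beta to near round-off."""
        obs, _ = toy_obs
        reg = build_laplacian((8, 8))
        alpha, beta = 2e-3, 40.0
        rng = np.random.default_rng(9)
        _, mean = sample_t_conditional(
            alpha, beta, obs, reg, rng, return_mean=True
        )
        t_tik = solve_tikhonov(obs, alpha / beta, reg=reg)
        assert np.linalg.norm(mean - t_tik) <= 1e-8 * np.linalg.norm(t_tik)


class TestRunGibbs:
    def test_reproducible_draw_for_draw(self, toy_obs):
        obs, _ = toy_obs
        reg = build_laplacian((8, 8))
        cfg = GibbsConfig(n_draws=20, burn_in=5, seed=11, lambda0=1e-3)
        p1 = run_gibbs(obs, reg, config=cfg)
        p2 = run_gibbs(obs, reg, config=cfg)
        assert np.array_equal(p1.draws, p2.draws)
        assert np.array_equal(p1.alpha_chain, p2.alpha_chain)

    def test_posterior_beats_unregularized_inverse(self, toy_obs, substrate):
        """On noisy data the posterior mean has lower error than the
        exact spectral inverse."""
        obs, tvec = toy_obs
        reg = build_laplacian((8, 8))
        cfg = GibbsConfig(n_draws=120, burn_in=40, seed=12, lambda0=1e-4)
        post = run_gibbs(obs, reg, config=cfg)
        t_unreg = np.linalg.solve(obs.operator.M, obs.uh)
        err_post = np.linalg.norm(post.t_hat - tvec)
        err_unreg = np.linalg.norm(t_unreg - tvec)
        assert err_post < err_unreg

    def test_summaries_have_expected_shapes(self, toy_obs):
        obs, _ = toy_obs
        reg = build_laplacian((8, 8))
        post = run_gibbs(
            obs, reg, config=GibbsConfig(n_draws=15, burn_in=5, seed=13, lambda0=1e-3)
        )
        assert post.t_hat.shape == (128,)
        assert post.sigma_t.shape == (64,)
        assert post.angular_std.shape == (64,)
        assert np.all(post.sigma_t >= 0)
        assert len(post.alpha_chain) == 15


class TestSPostBounds:
    def test_long_wavelength_variance_bounds(self):
        """With L = identity, Sigma_PIV = 0 and kh << 1, the pointwise
        posterior variance lies between the weak-regularization bound
        beta^-1 mu^2/h^2 and the strong bound alpha^-1."""
        sub = SubstrateModel(E=5000.0, nu=0.45, h=0.05)  # kh ~ 1e-3
        kernel = build_spectral_kernel(sub, (4, 4), 20.0)
        op = assemble_dense_operator(kernel)
        c = sub.h / sub.mu
        assert np.allclose(np.diag(op.M), c, rtol=1e-4)  # pure-shear regime
        reg = build_laplacian((4, 4), variant="identity")
        beta = 1e4
        for alpha in (1e-8, 1e8):
            A = beta * op.M.T @ op.M + alpha * reg.P
            var = np.diag(np.linalg.inv(A))
            weak = (1 / beta) * (sub.mu / sub.h) ** 2
            strong = 1 / alpha
            assert np.all(var <= min(weak, strong) * 1.001)
            assert np.all(var >= 0.5 * min(weak, strong))


class TestForceConservation:
    def test_laplacian_regularization_conserves_total_force(self, substrate):
        """The area integral of the recovered traction is invariant
        across Laplacian regularization strengths (the constant mode is
        never penalized)."""
        kernel = build_spectral_kernel(substrate, (8, 8), 11.0)
        op = assemble_dense_operator(kernel)
        rng = np.random.default_rng(14)
        # asymmetric truth with nonzero net force
        tx = np.zeros((8, 8))
        tx[2:5, 2:5] = 300.0
        tvec = np.concatenate([tx.ravel(), 0.5 * tx.ravel()])
        uh = op.M @ tvec + rng.normal(0, 1e-4, 128)
        obs = ObservationModel(uh=uh, sigma2=np.zeros(128), operator=op)
        sums = []
        for lam in (1e-8, 1e-5, 1e-2):
            t = solve_tikhonov(obs, lam)
            sums.append([t[:64].sum(), t[64:].sum()])
        sums = np.asarray(sums)
        ref = np.abs(sums[0]).max()
        assert np.all(np.abs(sums - sums[0]) <= 0.01 * ref)


class TestHeteroskedasticPrior:
    def test_uniform_sigma_proportional_to_standard(self, small_operator):
        nw = small_operator.n_windows
        obs = ObservationModel(
            uh=np.zeros(2 * nw),
            sigma2=np.full(2 * nw, 0.04),
            operator=small_operator,
        )
        reg = build_laplacian((8, 8))
        het = heteroskedastic_prior_variant(obs, reg)
        assert np.allclose(het.P, reg.P / 0.04, rtol=1e-12)

    def test_high_noise_weakens_regularization(self, small_operator):
        nw = small_operator.n_windows
        sigma2 = np.full(2 * nw, 0.01)
        sigma2[: nw // 2] = 1.0  # noisy block
        obs = ObservationModel(
            uh=np.zeros(2 * nw), sigma2=sigma2, operator=small_operator
        )
        het = heteroskedastic_prior_variant(obs, build_laplacian((8, 8)))
        assert het.P[0, 0] < het.P[nw - 1, nw - 1]

    def test_zero_sigma_rejected(self, small_operator):
        nw = small_operator.n_windows
        obs = ObservationModel(
            uh=np.zeros(2 * nw), sigma2=np.zeros(2 * nw), operator=small_operator
        )
        with pytest.raises(ValueError):
            heteroskedastic_prior_variant(obs, build_laplacian((8, 8)))


class TestDirectQuadraticForm:
    def test_tLt_precision_is_psd_and_softer(self):
        """The direct quadratic form t^T L t gives the PSD precision -L,
        a |k|^2 penalty that is softer on high frequencies than L^T L."""
        reg_direct = build_laplacian((6, 6), quadratic_form="tLt")
        eig = np.linalg.eigvalsh(reg_direct.P)
        assert eig.min() > -1e-12
        t = np.concatenate([np.full(36, 2.0), np.full(36, -1.0)])
        assert reg_direct.energy(t) == pytest.approx(0.0, abs=1e-18)
        # checkerboard: highest-frequency mode
        cb = np.indices((6, 6)).sum(axis=0) % 2 * 2.0 - 1.0
        tcb = np.concatenate([cb.ravel(), np.zeros(36)])
        reg_sq = build_laplacian((6, 6))
        assert reg_direct.energy(tcb) < reg_sq.energy(tcb)
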