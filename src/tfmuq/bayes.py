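"""Hierarchical Bayesian traction inversion with a hybrid Gibbs sampler.

The observation model treats the stacked PIV displacement vector
``uh`` (um) as the elastic response ``M t`` (t in Pa) plus two Gaussian
error terms: a spatially resolved PIV measurement error with known
diagonal covariance ``Sigma_PIV`` and a global model error of unknown
precision ``beta``.  A smoothness prior on the traction field uses the
discrete Laplacian ``L`` with precision ``L^T L`` scaled by a second
unknown hyperparameter ``alpha``; both hyperparameters carry weakly
informative Gamma hyperpriors (shape 1, rate 1e-5 by default) so the
data set the regularization level.

Sampling cycles through
  * ``t | alpha, beta``  -- multivariate Gaussian with precision
    ``M^T Lambda^-1 M + alpha L^T L``, ``Lambda = beta^-1 I + Sigma_PIV``;
  * ``alpha | t``        -- Gamma(Nw + theta_a, |Lt|^2/2 + phi_a);
  * ``beta | t``         -- no closed form; sampled by numerical
    inverse-transform on a log-spaced grid centered on its conditional
    MAP.

Posterior summaries (mean traction, componentwise and total std,
angular circular std) are computed from the post-burn-in draws.  With
``Sigma_PIV = 0`` and the hyperparameters clamped, the posterior mean
coincides with the Tikhonov solution at ``lambda = alpha / beta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from .elastic import DenseOperator

__all__ = [
    "ObservationModel",
    "RegularizerOperator",
    "HyperPriors",
    "GibbsConfig",
    "TractionPosterior",
    "build_laplacian",
    "heteroskedastic_prior_variant",
    "likelihood_logpdf",
    "sample_t_conditional",
    "sample_alpha_conditional",
    "sample_beta_conditional",
    "run_gibbs",
]


@dataclass
class ObservationModel:
    """Stacked displacement observations plus the elastic operator.

    uh : (2 Nw,) displacement vector in um, ordered
        (ux_1..ux_Nw, uy_1..uy_Nw) row-major over the window grid.
    sigma2 : (2 Nw,) diagonal of Sigma_PIV in um^2 (zeros allowed).
    operator : DenseOperator mapping Pa -> um on the same grid.
    """

    uh: np.ndarray
    sigma2: np.ndarray
    operator: DenseOperator

    def __post_init__(self) -> None:
        self.uh = np.asarray(self.uh, dtype=float).ravel()
        self.sigma2 = np.asarray(self.sigma2, dtype=float).ravel()
        n = self.operator.M.shape[0]
        if self.uh.size != n or self.sigma2.size != n:
            raise ValueError(
                f"uh/sigma2 length {self.uh.size}/{self.sigma2.size} does not"
                f" match operator dimension {n}"
            )
        if np.any(self.sigma2 < 0):
            raise ValueError("Sigma_PIV diagonal must be non-negative")

    @property
    def n_windows(self) -> int:
        return self.uh.size // 2

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.operator.shape


@dataclass
class RegularizerOperator:
    """Smoothness regularizer on the window grid.

    ``L`` is the per-component discrete Laplacian (block diagonal over
    the two traction components); the effective prior precision is
    ``P = L^T L`` so the prior energy is ``|L t|^2``.  The
    ``heteroskedastic`` variant rescales ``P`` by the local PIV noise.
    """

    L: sp.spmatrix
    variant: str = "laplacian"
    quadratic_form: str = "LtL"
    P: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.quadratic_form == "LtL":
            P = np.asarray((self.L.T @ self.L).todense())
        elif self.quadratic_form == "tLt":
            # the mirror-boundary Laplacian is negative semidefinite,
            # so the direct quadratic form t^T L t yields the PSD
            # precision -L (a |k|^2 rather than k^4 penalty)
            P = -np.asarray(self.L.todense())
        else:
            raise ValueError(
                f"unknown quadratic_form {self.quadratic_form!r}"
            )
        self.P = 0.5 * (P + P.T)

    def energy(self, t: np.ndarray) -> float:
        """Prior energy: |L t|^2, or |t^T L t| for the direct form."""
        if self.quadratic_form == "tLt":
            return float(t @ (self.P @ t))
        lt = self.L @ t
        return float(lt @ lt)


def _laplacian_1c(ny: int, nx: int, symmetric: bool = False) -> sp.spmatrix:
    """5-point Laplacian with mirror (Neumann) boundaries, row-major.

    The default whole-sample reflection (boundary row ``[-2, 2]``) is
    the natural finite-difference stencil but is not a symmetric
    matrix; ``symmetric=True`` uses the half-sample Neumann stencil
    (boundary row ``[-1, 1]``), which is symmetric negative
    semidefinite and required when the Laplacian itself serves as a
    (negated) prior precision.
    """
    def d2(n):
        main = np.full(n, -2.0)
        off = np.ones(n - 1)
        D = sp.diags([off, main, off], [-1, 0, 1], format="lil")
        if symmetric:
            D[0, 0] = -1.0
            D[n - 1, n - 1] = -1.0
        else:
            # mirror boundary: ghost node equals interior neighbor
            D[0, 1] = 2.0
            D[n - 1, n - 2] = 2.0
        return D.tocsr()

    Ix = sp.identity(nx)
    Iy = sp.identity(ny)
    return sp.kron(Iy, d2(nx)) + sp.kron(d2(ny), Ix)


def build_laplacian(
    grid_shape: tuple[int, int],
    variant: str = "laplacian",
    quadratic_form: str = "LtL",
) -> RegularizerOperator:
    """Regularizer for a (ny, nx) window grid.

    ``laplacian``: 5-point stencil per component with mirror boundaries
    (annihilates constant fields and, in the interior, linear ones).
    ``identity``: ridge penalty on the traction values themselves.
    ``quadratic_form``: ``LtL`` (default, prior energy |Lt|^2) or
    ``tLt`` (direct form, precision -L).
    """
    ny, nx = grid_shape
    if variant == "laplacian":
        L1 = _laplacian_1c(ny, nx, symmetric=(quadratic_form == "tLt"))
        L = sp.block_diag([L1, L1]).tocsr()
    elif variant == "identity":
        L = sp.identity(2 * ny * nx, format="csr")
    else:
        raise ValueError(f"unknown regularizer variant {variant!r}")
    return RegularizerOperator(L=L, variant=variant, quadratic_form=quadratic_form)


def heteroskedastic_prior_variant(
    obs: ObservationModel, reg: RegularizerOperator
) -> RegularizerOperator:
    """Rescale the prior precision by the local PIV noise.

    Implements the noise-adapted smoothness prior whose precision is
    ``Sigma_PIV^{-1/2} L^T L Sigma_PIV^{-1/2}`` (symmetrized form of
    weighting the prior energy by the inverse PIV variance): high-noise
    regions receive weaker effective regularization per unit alpha and
    the posterior sigma floor scales with the local noise.
    """
    if np.any(obs.sigma2 <= 0):
        raise ValueError(
            "heteroskedastic prior requires strictly positive Sigma_PIV"
        )
    w = sp.diags(obs.sigma2**-0.5)
    out = RegularizerOperator(L=(reg.L @ w).tocsr(), variant="heteroskedastic")
    return out


@dataclass(frozen=True)
class HyperPriors:
    """Gamma hyperprior shapes/rates for alpha and beta (weakly
    informative defaults: shape 1, rate 1e-5)."""

    theta_alpha: float = 1.0
    phi_alpha: float = 1e-5
    theta_beta: float = 1.0
    phi_beta: float = 1e-5

    def __post_init__(self) -> None:
        for v in (self.theta_alpha, self.phi_alpha, self.theta_beta, self.phi_beta):
            if v <= 0:
                raise ValueError("hyperprior parameters must be positive")


@dataclass(frozen=True)
class GibbsConfig:
    """Hybrid Gibbs sampler settings.

    n_draws : total chain length Nd.  burn_in : discarded iterations.
    alpha0/beta0 : optional explicit initialization; by default beta0
    is 1/median(Sigma_PIV) (or 1/var(uh) if Sigma_PIV is zero) and
    alpha0 = lambda0 * beta0 with lambda0 from the caller (falling back
    to a coarse L-curve corner).
    beta_grid_points/beta_grid_decades : log-grid used for the
    numerical inverse-transform beta sampler.
    """

    n_draws: int = 300
    burn_in: int = 50
    alpha0: float | None = None
    beta0: float | None = None
    lambda0: float | None = None
    beta_grid_points: int = 400
    beta_grid_decades: float = 4.0
    fixed_hyperparameters: bool = False
    keep_t_draws: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_draws > self.burn_in >= 0):
            raise ValueError("need n_draws > burn_in >= 0")


@dataclass
class TractionPosterior:
    """MCMC summaries of the marginal traction posterior.

    t_hat : posterior mean, (2 Nw,) Pa.  sigma_t components and total,
    angular circular std per point, and the alpha/beta chains.
    """

    t_hat: np.ndarray
    sigma_tx: np.ndarray
    sigma_ty: np.ndarray
    sigma_t: np.ndarray
    angular_std: np.ndarray
    alpha_chain: np.ndarray
    beta_chain: np.ndarray
    grid_shape: tuple[int, int]
    draws: np.ndarray | None = None

    @property
    def n_windows(self) -> int:
        return self.t_hat.size // 2

    def component_maps(self) -> tuple[np.ndarray, np.ndarray]:
        nw = self.n_windows
        ny, nx = self.grid_shape
        return (
            self.t_hat[:nw].reshape(ny, nx),
            self.t_hat[nw:].reshape(ny, nx),
        )

    def magnitude_map(self) -> np.ndarray:
        tx, ty = self.component_maps()
        return np.hypot(tx, ty)

    def sigma_map(self) -> np.ndarray:
        ny, nx = self.grid_shape
        return self.sigma_t.reshape(ny, nx)


def _lambda_diag(beta: float, sigma2: np.ndarray) -> np.ndarray:
    return 1.0 / beta + sigma2


def likelihood_logpdf(
    t: np.ndarray, alpha: float, beta: float, obs: ObservationModel
) -> float:
    """Gaussian log-likelihood of the observed displacements given t.

    ``Lambda = beta^-1 I + Sigma_PIV`` is diagonal, so the determinant
    is the product of its entries.  (alpha does not enter; accepted for
    interface symmetry with the conditionals.)
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    lam = _lambda_diag(beta, obs.sigma2)
    if np.any(lam <= 0):
        raise ValueError("Lambda has a non-positive diagonal entry")
    r = obs.uh - obs.operator.M @ t
    nw = obs.n_windows
    return float(
        -nw * np.log(2.0 * np.pi)
        - 0.5 * np.sum(np.log(lam))
        - 0.5 * np.sum(r * r / lam)
    )


def sample_t_conditional(
    alpha: float,
    beta: float,
    obs: ObservationModel,
    reg: RegularizerOperator,
    rng: np.random.Generator,
    return_mean: bool = False,
    _cache: dict | None = None,
):
    """Draw from the Gaussian conditional of t given the hyperparameters.

    The conditional has precision ``A = M^T Lambda^-1 M + alpha P`` and
    mean ``A^-1 M^T Lambda^-1 uh``; the draw is
    ``mean + chol(A)^-T z`` with standard normal z.
    """
    M = obs.operator.M
    lam = _lambda_diag(beta, obs.sigma2)
    key = ("mtl", beta) if _cache is not None else None
    if key is not None and key in _cache:
        MtLi, MtLiM = _cache[key]
    else:
        MtLi = M.T / lam  # (2Nw, 2Nw) scaled columns
        MtLiM = MtLi @ M
        if key is not None:
            _cache.clear()
            _cache[key] = (MtLi, MtLiM)
    A = MtLiM + alpha * reg.P
    b = MtLi @ obs.uh
    try:
        cho = sla.cho_factor(A, lower=False)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "posterior precision is not positive definite; "
            "check alpha > 0 or the rank of M^T Lambda^-1 M"
        ) from err
    mean = sla.cho_solve(cho, b)
    z = rng.standard_normal(mean.size)
    # A = R^T R with R upper triangular -> cov = A^-1 = R^-1 R^-T
    draw = mean + sla.solve_triangular(cho[0], z, lower=False)
    if return_mean:
        return draw, mean
    return draw


def sample_alpha_conditional(
    t: np.ndarray,
    reg: RegularizerOperator,
    hyper: HyperPriors,
    n_windows: int,
    rng: np.random.Generator,
) -> float:
    """Gamma draw for alpha: shape Nw + theta_a, rate |Lt|^2/2 + phi_a."""
    if not np.all(np.isfinite(t)):
        raise ValueError("traction draw contains non-finite values")
    shape = n_windows + hyper.theta_alpha
    rate = 0.5 * reg.energy(t) + hyper.phi_alpha
    return float(rng.gamma(shape, 1.0 / rate))


def _beta_logpdf_terms(
    beta: np.ndarray, r2: np.ndarray, sigma2: np.ndarray, hyper: HyperPriors
) -> np.ndarray:
    """Unnormalized log conditional of beta evaluated on a vector of
    beta values; r2 are squared residual components."""
    beta = np.atleast_1d(beta)
    lam = 1.0 / beta[:, None] + sigma2[None, :]
    return (
        -0.5 * np.sum(np.log(lam), axis=1)
        - 0.5 * np.sum(r2[None, :] / lam, axis=1)
        + (hyper.theta_beta - 1.0) * np.log(beta)
        - hyper.phi_beta * beta
    )


def sample_beta_conditional(
    t: np.ndarray,
    obs: ObservationModel,
    hyper: HyperPriors,
    rng: np.random.Generator,
    grid_points: int = 400,
    grid_decades: float = 4.0,
) -> float:
    """Numerical inverse-transform draw for beta.

    The conditional density has no closed form when ``Sigma_PIV`` is
    non-uniform.  A coarse log-grid brackets the conditional MAP, a
    fine log-grid spanning ``grid_decades`` decades around it resolves
    the density, and the numerical (trapezoid) CDF is inverted against
    a uniform draw by interpolation.  The grid is widened once if the
    mass piles up on an edge.
    """
    r = obs.uh - obs.operator.M @ t
    if not np.all(np.isfinite(r)):
        raise ValueError("residual contains non-finite values")
    r2 = r * r
    sigma2 = obs.sigma2

    # coarse bracket of the MAP around a moment-matched scale
    scale = 1.0 / max(np.mean(r2), 1e-300)
    coarse = scale * np.logspace(-8, 8, 80)
    lp = _beta_logpdf_terms(coarse, r2, sigma2, hyper)
    b_map = coarse[int(np.argmax(lp))]

    half = grid_decades / 2.0
    for attempt in range(2):
        grid = b_map * np.logspace(-half, half, grid_points)
        lp = _beta_logpdf_terms(grid, r2, sigma2, hyper)
        lp -= lp.max()
        pdf = np.exp(lp)
        cdf = np.concatenate(
            [[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(grid))]
        )
        if cdf[-1] <= 0:
            raise RuntimeError("beta conditional has no mass on the grid")
        interior = pdf.argmax() not in (0, len(grid) - 1)
        if interior or attempt == 1:
            if not interior:
                raise RuntimeError(
                    "beta conditional unbounded on the widened grid"
                )
            cdf /= cdf[-1]
            u = rng.uniform()
            return float(np.interp(u, cdf, grid))
        b_map = grid[int(np.argmax(pdf))]
        half *= 2.0
    raise AssertionError("unreachable")


def _default_init(
    obs: ObservationModel, reg: RegularizerOperator, cfg: GibbsConfig
) -> tuple[float, float]:
    """Initialize (alpha0, beta0) from the Tikhonov fit at lambda0.

    beta0 moment-matches the residual of the lambda0 Tikhonov solution
    (the model-error precision a maximum-likelihood fit would report)
    and alpha0 = lambda0 * beta0.  Initializing beta from the PIV
    variance floor instead badly overweights the data on high-quality
    images and can collapse alpha into an overfitting trap before the
    chain can react.
    """
    if cfg.alpha0 is not None and cfg.beta0 is not None:
        return cfg.alpha0, cfg.beta0
    lam0 = cfg.lambda0
    if lam0 is None:
        from .tikhonov import TikhonovConfig, l_curve

        variant = reg.variant if reg.variant in ("laplacian", "identity") else "laplacian"
        curve = l_curve(obs, TikhonovConfig(regularizer=variant, n_lambdas=25))
        lam0 = curve.corner_lambda
    M = obs.operator.M
    A = M.T @ M + lam0 * reg.P
    t0 = sla.cho_solve(sla.cho_factor(A), M.T @ obs.uh)
    r = obs.uh - M @ t0
    beta0 = cfg.beta0
    if beta0 is None:
        beta0 = 1.0 / max(np.mean(r * r), 1e-300)
    alpha0 = cfg.alpha0 if cfg.alpha0 is not None else lam0 * beta0
    return float(alpha0), float(beta0)


def run_gibbs(
    obs: ObservationModel,
    reg: RegularizerOperator,
    hyper: HyperPriors | None = None,
    config: GibbsConfig | None = None,
) -> TractionPosterior:
    """Run the hybrid Gibbs sampler and summarize the traction posterior.

    Each iteration draws t from its Gaussian conditional, alpha from its
    Gamma conditional and beta by numerical inverse-transform; summaries
    are over the post-burn-in draws.  With
    ``fixed_hyperparameters=True`` the (alpha, beta) chain stays at its
    initialization, which reproduces a classical Tikhonov solution in
    the mean when ``Sigma_PIV = 0``.
    """
    hyper = hyper or HyperPriors()
    config = config or GibbsConfig()
    rng = np.random.default_rng(config.seed)
    alpha, beta = _default_init(obs, reg, config)
    nw = obs.n_windows
    n2 = 2 * nw

    n_keep = config.n_draws - config.burn_in
    alpha_chain = np.empty(config.n_draws)
    beta_chain = np.empty(config.n_draws)
    kept = np.empty((n_keep, n2)) if config.keep_t_draws else None
    mean_acc = np.zeros(n2)
    m2_acc = np.zeros(n2)
    cosang = np.zeros(nw)
    sinang = np.zeros(nw)
    cache: dict = {}

    for it in range(config.n_draws):
        t = sample_t_conditional(alpha, beta, obs, reg, rng, _cache=cache)
        if not np.all(np.isfinite(t)):
            raise RuntimeError(
                f"divergent chain at iteration {it}: non-finite traction draw "
                f"(alpha={alpha:.3g}, beta={beta:.3g})"
            )
        if not config.fixed_hyperparameters:
            alpha = sample_alpha_conditional(t, reg, hyper, nw, rng)
            beta = sample_beta_conditional(
                t, obs, hyper, rng,
                config.beta_grid_points, config.beta_grid_decades,
            )
        alpha_chain[it] = alpha
        beta_chain[it] = beta
        if it >= config.burn_in:
            k = it - config.burn_in
            if kept is not None:
                kept[k] = t
            mean_acc += t
            m2_acc += t * t
            ang = np.arctan2(t[nw:], t[:nw])
            cosang += np.cos(ang)
            sinang += np.sin(ang)

    t_hat = mean_acc / n_keep
    var = np.maximum(m2_acc / n_keep - t_hat**2, 0.0)
    # small-sample (ddof=1) correction
    var *= n_keep / max(n_keep - 1, 1)
    sd = np.sqrt(var)
    sigma_tx, sigma_ty = sd[:nw], sd[nw:]
    R = np.hypot(cosang / n_keep, sinang / n_keep)
    R = np.clip(R, np.finfo(float).tiny, 1.0)
    angular = np.sqrt(-2.0 * np.log(R))
    return TractionPosterior(
        t_hat=t_hat,
        sigma_tx=sigma_tx,
        sigma_ty=sigma_ty,
        sigma_t=np.sqrt(sigma_tx**2 + sigma_ty**2),
        angular_std=angular,
        alpha_chain=alpha_chain,
        beta_chain=beta_chain,
        grid_shape=obs.grid_shape,
        draws=kept,
    )
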