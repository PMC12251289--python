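"""Classical global Tikhonov regularization with L-curve selection.

Solves ``t = argmin ||uh - M t||^2 + lambda |L t|^2`` through the
symmetric positive-definite normal equations, with ``L`` either the
discrete Laplacian (smoothness penalty) or the identity (ridge).  The
regularization weight is chosen at the corner -- the point of maximum
curvature -- of the L-curve, the log-log trade-off curve of prior
seminorm against data residual.  This is the homoskedastic baseline the
hierarchical sampler is compared against: one global lambda for the
whole field, no use of the spatially resolved PIV uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from scipy.interpolate import UnivariateSpline

from .bayes import ObservationModel, RegularizerOperator, build_laplacian

__all__ = [
    "TikhonovConfig",
    "LCurve",
    "solve_tikhonov",
    "l_curve",
    "match_percentile_lambda",
]


@dataclass(frozen=True)
class TikhonovConfig:
    """Regularizer choice and lambda grid for the L-curve.

    When ``lambda_grid`` is omitted, ``n_lambdas`` points are log-spaced
    over ``decades`` decades centered on a scale heuristic
    ``trace(M M^T) / trace(P)`` that balances the two quadratic forms.
    """

    regularizer: str = "laplacian"
    lambda_grid: np.ndarray | None = None
    n_lambdas: int = 40
    decades: float = 8.0

    def grid_for(self, obs: ObservationModel, reg: RegularizerOperator) -> np.ndarray:
        if self.lambda_grid is not None:
            g = np.asarray(self.lambda_grid, dtype=float)
            if np.any(np.diff(g) <= 0):
                raise ValueError("lambda_grid must be strictly increasing")
            return g
        M = obs.operator.M
        center = np.trace(M @ M.T) / max(np.trace(reg.P), 1e-300)
        half = self.decades / 2.0
        return center * np.logspace(-half, half, self.n_lambdas)


@dataclass
class LCurve:
    """L-curve samples and the maximum-curvature corner."""

    lambdas: np.ndarray
    residual_norm2: np.ndarray  # ||uh - M t||^2
    seminorm2: np.ndarray       # |t^T L t|
    curvature: np.ndarray
    corner_index: int
    corner_lambda: float = field(init=False)

    def __post_init__(self) -> None:
        self.corner_lambda = float(self.lambdas[self.corner_index])


def _regularizer(obs: ObservationModel, config: TikhonovConfig) -> RegularizerOperator:
    return build_laplacian(obs.grid_shape, variant=config.regularizer)


def solve_tikhonov(
    obs: ObservationModel,
    lam: float,
    config: TikhonovConfig | None = None,
    reg: RegularizerOperator | None = None,
) -> np.ndarray:
    """Tikhonov traction estimate at a fixed regularization weight.

    Solves ``(M^T M + lambda P) t = M^T uh`` with ``P = L^T L``;
    returns the stacked traction vector in Pa.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    config = config or TikhonovConfig()
    reg = reg or _regularizer(obs, config)
    M = obs.operator.M
    A = M.T @ M + lam * reg.P
    b = M.T @ obs.uh
    try:
        return sla.cho_solve(sla.cho_factor(A), b)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"normal equations singular at lambda={lam:g}"
        ) from err


def l_curve(
    obs: ObservationModel, config: TikhonovConfig | None = None
) -> LCurve:
    """Sample the L-curve and locate its maximum-curvature corner.

    The curve (log residual^2, log |t^T L t|) is smoothed with cubic
    splines parameterized by log lambda and the analytic curvature of
    the spline pair is evaluated at the grid points; the corner is the
    curvature maximum over the descending branch.  A degenerate,
    cornerless curve yields a warning and the grid midpoint.
    """
    config = config or TikhonovConfig()
    reg = _regularizer(obs, config)
    lambdas = config.grid_for(obs, reg)
    if len(lambdas) < 10:
        raise ValueError("need at least 10 lambda grid points")
    M = obs.operator.M
    MtM = M.T @ M
    b = M.T @ obs.uh
    res2 = np.empty(len(lambdas))
    semi2 = np.empty(len(lambdas))
    for i, lam in enumerate(lambdas):
        t = sla.cho_solve(sla.cho_factor(MtM + lam * reg.P), b)
        r = obs.uh - M @ t
        res2[i] = r @ r
        semi2[i] = abs(t @ (reg.L @ t))

    x = np.log10(lambdas)
    eps = np.finfo(float).tiny
    rho = np.log10(res2 + eps)
    eta = np.log10(semi2 + eps)
    if np.ptp(eta) < 1e-12 or np.ptp(rho) < 1e-12:
        import warnings

        warnings.warn("degenerate L-curve without a corner; using midpoint")
        mid = len(lambdas) // 2
        return LCurve(lambdas, res2, semi2, np.zeros_like(res2), mid)

    k = min(3, len(x) - 1)
    s_rho = UnivariateSpline(x, rho, k=k, s=len(x) * 1e-6)
    s_eta = UnivariateSpline(x, eta, k=k, s=len(x) * 1e-6)
    d_rho, dd_rho = s_rho.derivative(1)(x), s_rho.derivative(2)(x)
    d_eta, dd_eta = s_eta.derivative(1)(x), s_eta.derivative(2)(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        curv = (d_rho * dd_eta - dd_rho * d_eta) / (
            d_rho**2 + d_eta**2
        ) ** 1.5
    curv = np.nan_to_num(curv, nan=0.0)
    # Traversed with increasing lambda (residual rising, seminorm
    # falling) the corner -- where the noise-fitting branch meets the
    # smoothing branch -- is the sharpest counterclockwise bend, i.e.
    # the maximum of the signed curvature.  With a square, mildly
    # conditioned response matrix the sampled curve is S-shaped: the
    # overfit end adds a clockwise (negative-curvature) bend that must
    # not be picked.  Spline end effects are excluded from candidacy.
    guard = max(2, len(x) // 13)
    candidates = np.zeros(len(x), dtype=bool)
    candidates[guard : len(x) - guard] = True
    # exclude the deep-overfit tail, where the residual still sits near
    # its exact-fit minimum and the curve carries no corner information
    candidates &= (rho - rho.min()) > 0.1 * np.ptp(rho)
    if not candidates.any():
        candidates[guard : len(x) - guard] = True
    masked = np.where(candidates, curv, -np.inf)
    corner = int(np.argmax(masked))
    if curv[corner] <= 0:
        # no counterclockwise bend resolved: fall back to the point
        # farthest from the endpoint chord
        p0 = np.array([rho[0], eta[0]])
        chord = np.array([rho[-1], eta[-1]]) - p0
        chord /= np.linalg.norm(chord)
        rel = np.column_stack([rho - p0[0], eta - p0[1]])
        dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
        corner = int(np.argmax(dist))
    return LCurve(lambdas, res2, semi2, curv, corner)


def match_percentile_lambda(
    obs: ObservationModel,
    target_percentile_value: float,
    percentile: float = 95.0,
    config: TikhonovConfig | None = None,
    rtol: float = 0.01,
    max_iter: int = 60,
) -> float:
    """Find lambda (identity regularizer by default) whose solution's
    traction-magnitude percentile matches a target value.

    Used to pair ridge solutions with Laplacian-regularized ones at
    equal 95th-percentile traction magnitude.  The percentile decreases
    monotonically in lambda, so bisection on log lambda applies.
    """
    config = config or TikhonovConfig(regularizer="identity")
    reg = _regularizer(obs, config)

    def perc(lam: float) -> float:
        t = solve_tikhonov(obs, lam, config, reg)
        nw = obs.n_windows
        mag = np.hypot(t[:nw], t[nw:])
        return float(np.percentile(mag, percentile))

    grid = config.grid_for(obs, reg)
    lo, hi = grid[0], grid[-1]
    f_lo, f_hi = perc(lo), perc(hi)
    # enlarge until the target is bracketed (perc decreasing in lambda)
    for _ in range(30):
        if f_lo >= target_percentile_value:
            break
        lo /= 10.0
        f_lo = perc(lo)
    for _ in range(30):
        if f_hi <= target_percentile_value:
            break
        hi *= 10.0
        f_hi = perc(hi)
    if not (f_lo >= target_percentile_value >= f_hi):
        raise ValueError(
            "could not bracket the target percentile with any lambda"
        )
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)
        f_mid = perc(mid)
        if abs(f_mid - target_percentile_value) <= rtol * target_percentile_value:
            return float(mid)
        if f_mid > target_percentile_value:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))
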