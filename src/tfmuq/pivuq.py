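"""Non-parametric bootstrap uncertainty quantification for PIV.

Each interrogation-window pair is resampled by drawing ``n^2`` pixel
indices uniformly with replacement; a pixel's intensity is weighted by
its sampled multiplicity and unsampled pixels are zeroed.  The same
index multiset perturbs both windows of a pair, so it is the
contribution of individual pixels to the cross-correlation functional
-- not the imaged scene -- that is perturbed.  Repeating this ``n_B``
times and re-running PIV yields an empirical distribution of
displacement draws per window, whose spread estimates the local
measurement uncertainty.

Draw sets are screened with DBSCAN: noise points are outliers, and a
window is invalidated when the draws are multi-modal (two clusters
whose closest points are at least 20% of the window spacing apart) or
when no cluster forms at all.  Invalid windows get their displacement
filled by iterated 3x3 median filtering of valid neighbors and their
standard deviation set to ``bad_sigma_factor`` times the maximum valid
value, so the downstream inversion treats them as nearly uninformative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN

from .piv import PIVConfig, DeformationField, extract_windows, displacements_from_windows, run_piv

__all__ = [
    "PIVUQConfig",
    "PIVUncertainty",
    "bootstrap_weights",
    "bootstrap_window_pair",
    "bootstrap_distribution",
    "cluster_validate",
    "circular_std",
    "run_piv_uq",
    "cov_convergence",
]


@dataclass(frozen=True)
class PIVUQConfig:
    """Bootstrap and cluster-validation parameters.

    n_B : bootstrap iterations per window.
    dbscan_eps : cluster radius in px (default WS/5 of the PIV run).
    dbscan_minpts : minimum cluster size (default ceil(n_B/10)).
    separation_frac : multimodality threshold as a fraction of WS.
    bad_sigma_factor : sigma inflation for invalidated windows.
    binary_mask : if True, resampled pixels keep their plain intensity
        (membership mask) instead of being weighted by multiplicity.
    """

    n_B: int = 50
    dbscan_eps: float | None = None
    dbscan_minpts: int | None = None
    separation_frac: float = 0.2
    bad_sigma_factor: float = 5.0
    binary_mask: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_B < 2:
            raise ValueError("n_B must be at least 2")
        if self.dbscan_eps is not None and self.dbscan_eps <= 0:
            raise ValueError("dbscan_eps must be positive")
        if self.dbscan_minpts is not None and self.dbscan_minpts < 1:
            raise ValueError("dbscan_minpts must be >= 1")

    def eps(self, WS: int) -> float:
        return self.dbscan_eps if self.dbscan_eps is not None else WS / 5.0

    def minpts(self) -> int:
        if self.dbscan_minpts is not None:
            return self.dbscan_minpts
        return int(np.ceil(self.n_B / 10.0))


@dataclass
class PIVUncertainty:
    """Per-window bootstrap uncertainty companion to a DeformationField.

    sigma_u : (ny, nx, 2) componentwise std of the main-cluster draws, px.
    valid : windows that passed cluster validation.
    angular_std : circular std (rad) of draw directions.
    draws : retained bootstrap draws, (ny, nx, n_B, 2) px, or None.
    """

    sigma_u: np.ndarray
    valid: np.ndarray
    angular_std: np.ndarray
    draws: np.ndarray | None = None

    @property
    def sigma_total(self) -> np.ndarray:
        """Total uncertainty sqrt(sigma_ux^2 + sigma_uy^2) per window."""
        return np.sqrt((self.sigma_u**2).sum(axis=-1))


def bootstrap_weights(
    n_pixels: int, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Multiplicity of each pixel index after drawing ``n_pixels``
    uniform samples with replacement (a multinomial count vector)."""
    p = np.full(n_pixels, 1.0 / n_pixels)
    if size is None:
        return rng.multinomial(n_pixels, p)
    return rng.multinomial(n_pixels, p, size=size)


def bootstrap_window_pair(
    w_ref: np.ndarray, w_session: np.ndarray, rng: np.random.Generator,
    binary_mask: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """One bootstrap perturbation of a window pair.

    Pixel indices are sampled with replacement; each pixel's intensity
    is multiplied by its sampled count (or by mere membership when
    ``binary_mask``), zeroing unsampled pixels.  The same index multiset
    applies to both windows.
    """
    if w_ref.shape != w_session.shape:
        raise ValueError("windows must have identical shapes")
    counts = bootstrap_weights(w_ref.size, rng).reshape(w_ref.shape)
    w = (counts > 0).astype(float) if binary_mask else counts.astype(float)
    # weights act on the mean-centered windows: a pixel's contribution
    # to the (mean-subtracted) correlation metric is what is resampled.
    # Weighting the raw intensities instead lets the shared weight
    # pattern correlate with itself at zero lag through the nonzero
    # image mean, silently validating even bead-free windows.
    return (w_ref - w_ref.mean()) * w, (w_session - w_session.mean()) * w


def bootstrap_distribution(
    w_ref: np.ndarray,
    w_session: np.ndarray,
    n_B: int,
    rng: np.random.Generator,
    binary_mask: bool = False,
    mode: str = "linear",
    search_frac: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap displacement draws for a single window pair.

    Returns ``(draws, ok)`` with ``draws`` shaped (n_B, 2) in px and
    ``ok`` flagging draws whose perturbed correlation was usable.
    """
    n = w_ref.shape[-1]
    counts = bootstrap_weights(n * n, rng, size=n_B).reshape(n_B, n, n)
    w = (counts > 0).astype(float) if binary_mask else counts.astype(float)
    wr = (w_ref - w_ref.mean())[None] * w
    ws = (w_session - w_session.mean())[None] * w
    return displacements_from_windows(wr, ws, mode=mode, search_frac=search_frac)


def cluster_validate(
    draws: np.ndarray, eps: float, minpts: int, WS: int,
    separation_frac: float = 0.2,
) -> tuple[np.ndarray, bool]:
    """Screen a window's bootstrap draws with density-based clustering.

    DBSCAN labels outliers as noise.  The window is invalid when no
    cluster forms, or when at least two clusters have a minimum
    edge-to-edge (closest-point) distance of ``separation_frac * WS``
    or more -- a multi-modal displacement distribution meaning more
    than one registration is plausible.  Otherwise statistics are taken
    over the largest cluster; returns (mask of retained draws, valid).
    """
    draws = np.atleast_2d(draws)
    if len(draws) < minpts:
        return np.zeros(len(draws), dtype=bool), False
    labels = DBSCAN(eps=eps, min_samples=minpts).fit_predict(draws)
    clusters = [lab for lab in np.unique(labels) if lab != -1]
    if not clusters:
        return np.zeros(len(draws), dtype=bool), False
    if len(clusters) > 1:
        pts = [draws[labels == lab] for lab in clusters]
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                d2 = (
                    (pts[i][:, None, :] - pts[j][None, :, :]) ** 2
                ).sum(axis=-1)
                if np.sqrt(d2.min()) >= separation_frac * WS:
                    return np.zeros(len(draws), dtype=bool), False
    sizes = [(labels == lab).sum() for lab in clusters]
    main = clusters[int(np.argmax(sizes))]
    return labels == main, True


def circular_std(angles: np.ndarray) -> float:
    """Circular standard deviation sqrt(-2 ln R) of angles in radians,
    with R the mean resultant length."""
    if angles.size == 0:
        return float("nan")
    R = np.hypot(np.mean(np.cos(angles)), np.mean(np.sin(angles)))
    R = min(R, 1.0)
    if R <= 0:
        return float(np.sqrt(-2.0 * np.log(np.finfo(float).tiny)))
    return float(np.sqrt(-2.0 * np.log(R)))


def _median_fill(u: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Fill invalid vectors with the 3x3 median of valid neighbors,
    iterating until every window is filled (or no progress is possible)."""
    u = u.copy()
    filled = valid.copy()
    ny, nx = filled.shape
    while not filled.all():
        progress = False
        newly = np.zeros_like(filled)
        newu = u.copy()
        for i, j in zip(*np.nonzero(~filled)):
            ilo, ihi = max(i - 1, 0), min(i + 2, ny)
            jlo, jhi = max(j - 1, 0), min(j + 2, nx)
            nb = filled[ilo:ihi, jlo:jhi]
            if nb.any():
                patch = u[ilo:ihi, jlo:jhi][nb]
                newu[i, j] = np.median(patch, axis=0)
                newly[i, j] = True
                progress = True
        u = newu
        filled |= newly
        if not progress:
            break
    return u


def run_piv_uq(
    ref: np.ndarray,
    session: np.ndarray,
    piv_config: PIVConfig,
    uq_config: PIVUQConfig | None = None,
    keep_draws: bool = False,
) -> tuple[DeformationField, PIVUncertainty]:
    """Nominal PIV followed by per-window bootstrap uncertainty.

    Returns the deformation field (invalid windows median-filled) and
    the per-window uncertainty.  Invalid windows carry
    ``bad_sigma_factor`` times the maximum valid sigma so they stay in
    the grid but carry almost no weight downstream.
    """
    uq_config = uq_config or PIVUQConfig()
    field = run_piv(ref, session, piv_config)
    wr, _, _ = extract_windows(np.asarray(ref, dtype=float), piv_config)
    ws, _, _ = extract_windows(np.asarray(session, dtype=float), piv_config)
    ny, nx = field.grid_shape
    n_B = uq_config.n_B
    eps = uq_config.eps(field.WS)
    minpts = uq_config.minpts()
    rng = np.random.default_rng(uq_config.seed)

    sigma = np.zeros((ny, nx, 2))
    ang = np.full((ny, nx), np.nan)
    valid = np.zeros((ny, nx), dtype=bool)
    draws_out = np.full((ny, nx, n_B, 2), np.nan) if keep_draws else None

    n = piv_config.WL
    p = np.full(n * n, 1.0 / (n * n))
    # chunk windows to bound the bootstrap weight array in memory;
    # single precision suffices for correlation-peak location.
    # windows are mean-centered BEFORE weighting (see
    # bootstrap_window_pair for why)
    flat_r = wr.reshape(ny * nx, n, n).astype(np.float32)
    flat_s = ws.reshape(ny * nx, n, n).astype(np.float32)
    flat_r = flat_r - flat_r.mean(axis=(1, 2), keepdims=True)
    flat_s = flat_s - flat_s.mean(axis=(1, 2), keepdims=True)
    chunk = max(1, int(1e8 / (n_B * n * n * 8)))
    draws_all = np.empty((ny * nx, n_B, 2))
    ok_all = np.empty((ny * nx, n_B), dtype=bool)
    for lo in range(0, ny * nx, chunk):
        hi = min(lo + chunk, ny * nx)
        counts = rng.multinomial(n * n, p, size=(hi - lo, n_B))
        w = counts.reshape(hi - lo, n_B, n, n).astype(np.float32)
        if uq_config.binary_mask:
            w = (w > 0).astype(np.float32)
        pr = flat_r[lo:hi, None] * w
        ps = flat_s[lo:hi, None] * w
        u, ok = displacements_from_windows(
            pr, ps, mode=piv_config.correlation,
            search_frac=piv_config.search_frac,
        )
        draws_all[lo:hi] = u
        ok_all[lo:hi] = ok

    for idx in range(ny * nx):
        i, j = divmod(idx, nx)
        if not field.valid[i, j]:
            continue
        d = draws_all[idx][ok_all[idx]]
        if draws_out is not None and len(d):
            draws_out[i, j, : len(d)] = d
        mask, is_valid = cluster_validate(
            d, eps, minpts, field.WS, uq_config.separation_frac
        )
        if not is_valid or mask.sum() < 2:
            continue
        kept = d[mask]
        sigma[i, j] = kept.std(axis=0, ddof=1)
        ang[i, j] = circular_std(np.arctan2(kept[:, 1], kept[:, 0]))
        valid[i, j] = True

    if not valid.any():
        raise RuntimeError(
            "every interrogation window failed bootstrap validation; "
            "the image pair is unusable at this window size"
        )
    sig_max = sigma[valid].max(axis=0)
    sigma[~valid] = uq_config.bad_sigma_factor * sig_max
    ang[~valid] = np.nanmax(ang[valid]) if np.isfinite(ang[valid]).any() else np.pi
    u_filled = _median_fill(field.u, valid)
    out_field = DeformationField(
        x_px=field.x_px, y_px=field.y_px, u=u_filled,
        WL=field.WL, WS=field.WS, valid=valid,
    )
    unc = PIVUncertainty(
        sigma_u=sigma, valid=valid, angular_std=ang, draws=draws_out
    )
    return out_field, unc


def cov_convergence(
    ref: np.ndarray,
    session: np.ndarray,
    piv_config: PIVConfig,
    n_B_list: list[int],
    repeats: int = 4,
    seed: int = 0,
) -> dict[int, float]:
    """Median per-window coefficient of variation of sigma vs n_B.

    For each ``n_B`` the bootstrap is repeated with fresh seeds; the CoV
    per window is Std/Mean of the sigma estimates across repeats, and
    the median over windows is reported.  Decreasing CoV with n_B
    indicates the bootstrap sigma estimator has converged.
    """
    if repeats < 2:
        raise ValueError("repeats must be >= 2")
    ss = np.random.SeedSequence(seed)
    out: dict[int, float] = {}
    for n_B in n_B_list:
        sigmas = []
        for child in ss.spawn(repeats):
            cfg = PIVUQConfig(n_B=n_B, seed=int(child.generate_state(1)[0] % 2**31))
            _, unc = run_piv_uq(ref, session, piv_config, cfg)
            s = unc.sigma_total
            s[~unc.valid] = np.nan
            sigmas.append(s)
        arr = np.stack(sigmas)  # (repeats, ny, nx)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = np.nanstd(arr, axis=0, ddof=1) / np.nanmean(arr, axis=0)
        out[n_B] = float(np.nanmedian(cov))
    return out
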