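"""Single-pass FFT cross-correlation particle image velocimetry.

Overlapping square interrogation windows of side ``WL`` px spaced
``WS`` px (default ``WL/2``) are cross-correlated between the reference
and session images; the correlation peak plus a three-point Gaussian
sub-pixel fit gives one displacement vector per window.  The sign
convention is that ``u`` maps reference coordinates to session
coordinates: a bead at ``x`` in the reference appears at ``x + u`` in
the session image.

Two correlation estimators are available.  The default, ``linear``,
zero-pads the mean-subtracted windows and divides the correlation by
the overlap area at each lag; this removes the systematic bias toward
zero lag that plain circular correlation suffers when particles leave
the window footprint (the bias scales like ``|u|/WL`` and is the
dominant PIV error for well-resolved images).  ``circular`` is the
unpadded wrap-around estimator, kept for comparison.  In both cases
the peak search is restricted to lags within ``search_frac * WL``
(default a quarter window) per component.

The engine is deliberately simple and swappable: any callable with the
``run_piv`` signature can replace it upstream (e.g. iterative
window-deformation PIV).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as fft

__all__ = [
    "PIVConfig",
    "DeformationField",
    "extract_windows",
    "cross_correlate",
    "subpixel_peak",
    "displacements_from_windows",
    "run_piv",
]


@dataclass(frozen=True)
class PIVConfig:
    """Interrogation-window geometry and correlation options.

    WL : window side in px.  WS : window spacing in px (default WL/2).
    correlation : ``linear`` (zero-padded, overlap-normalized; default)
        or ``circular`` (unpadded wrap-around).
    search_frac : peak-search range as a fraction of WL per component
        (default 0.25, the PIV quarter rule; lags beyond it are prone
        to spurious matches in sparse windows).
    subpixel : peak interpolation method tag (only ``gauss3``).
    """

    WL: int
    WS: int | None = None
    correlation: str = "linear"
    search_frac: float = 0.25
    subpixel: str = "gauss3"

    def __post_init__(self) -> None:
        if self.WS is None:
            object.__setattr__(self, "WS", self.WL // 2)
        if not (0 < self.WS <= self.WL):
            raise ValueError(f"require 0 < WS <= WL, got WS={self.WS}, WL={self.WL}")
        if self.correlation not in ("linear", "circular"):
            raise ValueError(f"unknown correlation mode {self.correlation!r}")
        if not (0 < self.search_frac <= 0.5):
            raise ValueError("search_frac must lie in (0, 0.5]")
        if self.subpixel != "gauss3":
            raise ValueError(f"unknown subpixel method {self.subpixel!r}")


@dataclass
class DeformationField:
    """Displacement vectors on the regular window-center grid.

    ``u`` has shape (ny, nx, 2) in px with components (ux, uy);
    ``x_px``/``y_px`` are 1-D center coordinate vectors.  ``valid``
    flags windows whose correlation produced a usable peak.
    """

    x_px: np.ndarray
    y_px: np.ndarray
    u: np.ndarray
    WL: int
    WS: int
    valid: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.u.shape[:2], dtype=bool)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.u.shape[:2]

    @property
    def n_windows(self) -> int:
        return self.u.shape[0] * self.u.shape[1]

    def centers_um(self, pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
        return self.x_px * pixel_size, self.y_px * pixel_size


def extract_windows(
    image: np.ndarray, config: PIVConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Section an image into a row-major grid of WL x WL windows.

    Returns ``(windows, x_px, y_px)`` where ``windows`` has shape
    (ny, nx, WL, WL) and the center vectors give each window's center
    pixel coordinate.  Windows lie fully inside the image; trailing
    edges without a full window are dropped.
    """
    WL, WS = config.WL, config.WS
    H, W = image.shape
    if WL > min(H, W):
        raise ValueError(f"window size {WL} exceeds image extent {image.shape}")
    ny = (H - WL) // WS + 1
    nx = (W - WL) // WS + 1
    s0, s1 = image.strides
    windows = np.lib.stride_tricks.as_strided(
        image,
        shape=(ny, nx, WL, WL),
        strides=(WS * s0, WS * s1, s0, s1),
        writeable=False,
    )
    x_px = np.arange(nx) * WS + WL / 2.0
    y_px = np.arange(ny) * WS + WL / 2.0
    return windows, x_px, y_px


def cross_correlate(
    w_ref: np.ndarray,
    w_session: np.ndarray,
    mode: str = "linear",
    search_frac: float = 0.25,
) -> np.ndarray:
    """Mean-subtracted cross-correlation search surface via FFT.

    Works on single windows or batches (..., WL, WL).  The returned
    surface spans lags ``-h..h`` per component, ``h = search_frac*WL``,
    with zero lag at the central index; ``C[dy, dx]`` measures the
    similarity of the session content displaced by ``(dx, dy)``
    relative to the reference.  ``linear`` zero-pads and normalizes
    each lag by its overlap area (unbiased estimator); ``circular``
    wraps.
    """
    if w_ref.shape != w_session.shape:
        raise ValueError("windows must have identical shapes")
    a = w_ref - w_ref.mean(axis=(-2, -1), keepdims=True)
    b = w_session - w_session.mean(axis=(-2, -1), keepdims=True)
    n = a.shape[-1]
    h = max(1, int(round(search_frac * n)))
    if mode == "circular":
        fa = fft.rfft2(a, s=(n, n))
        fb = fft.rfft2(b, s=(n, n))
        corr = fft.fftshift(fft.irfft2(np.conj(fa) * fb, s=(n, n)), axes=(-2, -1))
        c0 = n // 2
        return corr[..., c0 - h : c0 + h + 1, c0 - h : c0 + h + 1]
    if mode != "linear":
        raise ValueError(f"unknown correlation mode {mode!r}")
    # padding by the search range h suffices for exact linear
    # correlation at lags |l| <= h; keeps the FFT small
    m = n + h + ((n + h) % 2)
    fa = fft.rfft2(a, s=(m, m))
    fb = fft.rfft2(b, s=(m, m))
    corr = fft.fftshift(fft.irfft2(np.conj(fa) * fb, s=(m, m)), axes=(-2, -1))
    lag = np.arange(-h, h + 1)
    overlap = np.maximum(n - np.abs(lag), 1).astype(a.dtype)
    c0 = m // 2
    block = corr[..., c0 - h : c0 + h + 1, c0 - h : c0 + h + 1]
    return block / (overlap[:, None] * overlap[None, :])


def subpixel_peak(corr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Locate the correlation peak with 3-point Gaussian interpolation.

    Works on a single surface or a batch (..., ny, nx); zero lag is
    taken at index ``ny//2``/``nx//2``.  Returns ``(u, valid)`` where
    ``u[..., :] = (ux, uy)`` in px and ``valid`` is False where the
    integer peak touches the surface border (sub-pixel fit impossible,
    displacement at the search-range limit).  The Gaussian correction
    for an axis keeps the integer peak when any of the three stencil
    values is non-positive.
    """
    c = np.asarray(corr, dtype=float)
    batch = c.shape[:-2]
    n0, n1 = c.shape[-2:]
    flat = c.reshape(-1, n0, n1)
    idx = flat.reshape(flat.shape[0], -1).argmax(axis=1)
    iy, ix = np.unravel_index(idx, (n0, n1))
    valid = (iy > 0) & (iy < n0 - 1) & (ix > 0) & (ix < n1 - 1)

    m = np.arange(flat.shape[0])
    iyc = np.clip(iy, 1, n0 - 2)
    ixc = np.clip(ix, 1, n1 - 2)
    c0 = flat[m, iyc, ixc]
    cxm = flat[m, iyc, ixc - 1]
    cxp = flat[m, iyc, ixc + 1]
    cym = flat[m, iyc - 1, ixc]
    cyp = flat[m, iyc + 1, ixc]

    def gauss_delta(cm, cc, cp):
        ok = (cm > 0) & (cc > 0) & (cp > 0)
        delta = np.zeros_like(cc)
        lm, lc, lp = (np.log(np.where(ok, v, 1.0)) for v in (cm, cc, cp))
        den = 2.0 * lm - 4.0 * lc + 2.0 * lp
        fit = ok & (den < 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (lm - lp) / den
        delta[fit] = np.clip(d[fit], -1.0, 1.0)
        return delta

    ux = ixc - n1 // 2 + gauss_delta(cxm, c0, cxp)
    uy = iyc - n0 // 2 + gauss_delta(cym, c0, cyp)
    u = np.stack([ux, uy], axis=-1).reshape(*batch, 2)
    return u, valid.reshape(batch)


def displacements_from_windows(
    w_ref: np.ndarray,
    w_session: np.ndarray,
    mode: str = "linear",
    search_frac: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlate window batches and return (u, valid) per window.

    Degenerate windows (zero contrast in either member, e.g. bead-free
    regions) are flagged invalid with zero displacement.
    """
    corr = cross_correlate(w_ref, w_session, mode=mode, search_frac=search_frac)
    u, valid = subpixel_peak(corr)
    flat_r = w_ref.reshape(*w_ref.shape[:-2], -1)
    flat_s = w_session.reshape(*w_session.shape[:-2], -1)
    degenerate = (flat_r.std(axis=-1) == 0) | (flat_s.std(axis=-1) == 0)
    valid = valid & ~degenerate
    u[degenerate] = 0.0
    return u, valid


def run_piv(
    ref: np.ndarray, session: np.ndarray, config: PIVConfig
) -> DeformationField:
    """Nominal single-pass PIV of an image pair.

    Returns per-window displacement in px (argmax of the mean-subtracted
    cross-correlation plus sub-pixel Gaussian correction).
    """
    if ref.shape != session.shape:
        raise ValueError("reference and session images must share a shape")
    wr, x_px, y_px = extract_windows(np.asarray(ref, dtype=float), config)
    ws, _, _ = extract_windows(np.asarray(session, dtype=float), config)
    u, valid = displacements_from_windows(
        wr, ws, mode=config.correlation, search_frac=config.search_frac
    )
    return DeformationField(
        x_px=x_px, y_px=y_px, u=u, WL=config.WL, WS=config.WS, valid=valid
    )
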