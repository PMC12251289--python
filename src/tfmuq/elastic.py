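"""Elastostatic response of a finite-thickness linear elastic substrate.

A flat, inertia-less, linearly elastic layer of Young's modulus ``E``,
Poisson ratio ``nu`` and thickness ``h`` is bonded to a rigid support at
its base and loaded by tangential traction stresses on its free surface.
In Fourier space the surface displacement responds to the surface
traction through a 2x2 block per wavenumber ``k = (kx, ky)``::

    M~(k) = g1(k) * I + g2(k) * [[kx^2, kx*ky], [kx*ky, ky^2]]

``g1`` is the transverse (antiplane-shear) compliance and
``g1 + g2 k^2`` the longitudinal one.  For a bonded layer with a
traction-loaded, normally-stress-free surface these are

    g1       = tanh(kh) / (mu * k)
    g1+g2k^2 = (1-nu) [(3-4nu) s c + kh] /
               (mu k [(3-4nu) s^2 + (kh)^2 + 4 (1-nu)^2])

with ``s = sinh(kh)``, ``c = cosh(kh)`` and shear modulus
``mu = E / (2 (1 + nu))``.  Both expressions follow from solving the
plane-strain Navier equations for a single Fourier mode; they reduce to
the pure-shear response ``(h/mu) I`` when ``kh -> 0`` and to the
Boussinesq half-space kernel ``g1 = 2(1+nu)/(E k)``,
``g2 = -2 nu (1+nu)/(E k^3)`` when ``kh -> infinity``.  The DC mode
(``k = 0``) uses the pure-shear limit.

Units: lengths in micrometers, tractions in Pa, displacements in
micrometers, wavenumbers in rad/um.  The compliances then carry um/Pa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as fft

__all__ = [
    "SubstrateModel",
    "SpectralKernel",
    "DenseOperator",
    "build_spectral_kernel",
    "apply_forward",
    "apply_inverse_unregularized",
    "assemble_dense_operator",
]

# beyond this kh every term sits at its half-space asymptote to < 1e-25
_KH_SATURATION = 30.0

# dense assembly guard: 2*Nw x 2*Nw float64 stays below ~1 GiB
_MAX_DENSE_WINDOWS = 4000


@dataclass(frozen=True)
class SubstrateModel:
    """Linear elastic substrate parameters.

    Parameters
    ----------
    E : float
        Young's modulus in Pa.
    nu : float
        Poisson ratio, ``0 <= nu < 0.5``.  The incompressible limit is
        excluded because ``1 - 2 nu`` factors degenerate.
    h : float
        Substrate thickness in micrometers.
    """

    E: float
    nu: float
    h: float

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError(f"Young's modulus must be positive, got {self.E}")
        if not (0 <= self.nu < 0.5):
            raise ValueError(
                f"Poisson ratio must lie in [0, 0.5), got {self.nu}; "
                "the incompressible limit nu=0.5 is singular"
            )
        if self.h <= 0:
            raise ValueError(f"thickness must be positive, got {self.h}")

    @property
    def mu(self) -> float:
        """Shear modulus ``E / (2 (1 + nu))`` in Pa."""
        return self.E / (2.0 * (1.0 + self.nu))


@dataclass
class SpectralKernel:
    """Per-wavenumber elastic response blocks on a periodic grid.

    Attributes
    ----------
    kx, ky : ndarray
        Wavenumber component grids (rad/um), FFT layout, shape (ny, nx).
    g1, g2 : ndarray
        Scalar compliance functions of the response blocks
        ``g1 I + g2 [[kx^2, kx ky], [kx ky, ky^2]]``; ``g1`` in um/Pa,
        ``g2`` in um^3/Pa.
    substrate : SubstrateModel
    shape : tuple of int
        Grid shape (ny, nx).
    spacing : float
        Grid spacing in um.
    """

    kx: np.ndarray
    ky: np.ndarray
    g1: np.ndarray
    g2: np.ndarray
    substrate: SubstrateModel
    shape: tuple[int, int]
    spacing: float
    k: np.ndarray = field(init=False)
    m11: np.ndarray = field(init=False)
    m22: np.ndarray = field(init=False)
    m12: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.k = np.hypot(self.kx, self.ky)
        self.m11 = self.g1 + self.g2 * self.kx**2
        self.m22 = self.g1 + self.g2 * self.ky**2
        # the off-diagonal coupling is odd in each wavenumber component;
        # on Nyquist lines the sign of k is ambiguous and conjugate
        # symmetry would break, so the coupling is zeroed there (the
        # diagonal terms, even in k, are unaffected)
        ny, nx = self.shape
        m12 = self.g2 * self.kx * self.ky
        if ny % 2 == 0:
            m12[ny // 2, :] = 0.0
        if nx % 2 == 0:
            m12[:, nx // 2] = 0.0
        self.m12 = m12

    def block(self, kx: float, ky: float) -> np.ndarray:
        """Evaluate the 2x2 response block at one wavenumber (rad/um)."""
        g1, g2 = _compliances(np.atleast_1d(np.hypot(kx, ky)), self.substrate)
        return g1[0] * np.eye(2) + g2[0] * np.array(
            [[kx * kx, kx * ky], [kx * ky, ky * ky]]
        )


def _compliances(k: np.ndarray, substrate: SubstrateModel):
    """Scalar compliances (g1, g2) for wavenumber magnitudes ``k``.

    ``k = 0`` entries receive the pure-shear DC response
    ``g1 = h / mu``, ``g2 = 0``.
    """
    mu, nu, h = substrate.mu, substrate.nu, substrate.h
    k = np.asarray(k, dtype=float)
    g1 = np.empty_like(k)
    g2 = np.empty_like(k)

    zero = k == 0
    g1[zero] = h / mu
    g2[zero] = 0.0

    kk = k[~zero]
    x = np.minimum(kk * h, _KH_SATURATION)  # saturate: asymptote reached
    s = np.sinh(x)
    c = np.cosh(x)
    a = 3.0 - 4.0 * nu
    ct = np.tanh(x) / (mu * kk)  # transverse compliance 1/f1
    cl = (1.0 - nu) * (a * s * c + x) / (
        mu * kk * (a * s * s + x * x + 4.0 * (1.0 - nu) ** 2)
    )
    g1[~zero] = ct
    g2[~zero] = (cl - ct) / kk**2
    return g1, g2


def build_spectral_kernel(
    substrate: SubstrateModel, shape: tuple[int, int], spacing: float
) -> SpectralKernel:
    """Build the spectral response kernel on a periodic (ny, nx) grid.

    Parameters
    ----------
    substrate : SubstrateModel
    shape : (ny, nx)
        Number of grid nodes per dimension.
    spacing : float
        Node spacing in micrometers (equal in x and y).
    """
    if spacing <= 0:
        raise ValueError(f"grid spacing must be positive, got {spacing}")
    ny, nx = shape
    kx1 = 2.0 * np.pi * fft.fftfreq(nx, d=spacing)
    ky1 = 2.0 * np.pi * fft.fftfreq(ny, d=spacing)
    kx, ky = np.meshgrid(kx1, ky1)
    g1, g2 = _compliances(np.hypot(kx, ky), substrate)
    return SpectralKernel(
        kx=kx, ky=ky, g1=g1, g2=g2, substrate=substrate,
        shape=(ny, nx), spacing=spacing,
    )


def _check_grid(tx: np.ndarray, kernel: SpectralKernel) -> None:
    if tx.shape != kernel.shape:
        raise ValueError(
            f"field shape {tx.shape} does not match kernel grid {kernel.shape}"
        )


def apply_forward(
    tx: np.ndarray, ty: np.ndarray, kernel: SpectralKernel
) -> tuple[np.ndarray, np.ndarray]:
    """Surface displacement (um) produced by a surface traction field (Pa).

    Multiplies the traction transform by the 2x2 response block at each
    wavenumber and transforms back; output is real.
    """
    _check_grid(tx, kernel)
    _check_grid(ty, kernel)
    txh = fft.fft2(tx)
    tyh = fft.fft2(ty)
    m11, m22, m12 = kernel.m11, kernel.m22, kernel.m12
    uxh = m11 * txh + m12 * tyh
    uyh = m12 * txh + m22 * tyh
    return fft.ifft2(uxh).real, fft.ifft2(uyh).real


def apply_inverse_unregularized(
    ux: np.ndarray, uy: np.ndarray, kernel: SpectralKernel
) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-mode inversion of the elastic response (no regularization).

    Amplifies high-wavenumber noise roughly like ``mu k``; intended for
    round-trip checks and for demonstrating why regularization is needed.
    """
    _check_grid(ux, kernel)
    _check_grid(uy, kernel)
    m11, m22, m12 = kernel.m11, kernel.m22, kernel.m12
    det = m11 * m22 - m12 * m12
    if np.any(det == 0):
        raise np.linalg.LinAlgError("singular spectral block; cannot invert")
    uxh = fft.fft2(ux)
    uyh = fft.fft2(uy)
    txh = (m22 * uxh - m12 * uyh) / det
    tyh = (-m12 * uxh + m11 * uyh) / det
    return fft.ifft2(txh).real, fft.ifft2(tyh).real


@dataclass
class DenseOperator:
    """Dense real-space elastic response matrix.

    ``M`` maps a stacked traction vector ``(tx_1..tx_Nw, ty_1..ty_Nw)``
    in Pa to the stacked displacement vector in um, with row-major grid
    ordering.  Symmetric by reciprocity of the elastic response.
    """

    M: np.ndarray
    shape: tuple[int, int]
    spacing: float
    substrate: SubstrateModel

    @property
    def n_windows(self) -> int:
        return self.shape[0] * self.shape[1]


def assemble_dense_operator(kernel: SpectralKernel) -> DenseOperator:
    """Assemble the dense 2Nw x 2Nw matrix equivalent of the FFT response.

    Exploits periodic translation invariance: the response to a unit
    impulse at the grid origin gives one column of each block, and all
    other columns are circular shifts of it (block-circulant structure).
    Symmetry is enforced to round-off at the end.
    """
    ny, nx = kernel.shape
    nw = ny * nx
    if nw > _MAX_DENSE_WINDOWS:
        raise ValueError(
            f"dense operator with {nw} windows exceeds the {_MAX_DENSE_WINDOWS}"
            " window guard; use a coarser grid or the FFT path"
        )
    zero = np.zeros((ny, nx))
    imp = np.zeros((ny, nx))
    imp[0, 0] = 1.0
    # impulse responses: columns of the four Nw x Nw blocks
    rxx, ryx = apply_forward(imp, zero, kernel)
    rxy, ryy = apply_forward(zero, imp, kernel)

    iy, ix = np.indices((ny, nx))
    flat = (iy * nx + ix).ravel()
    # block[i, j] = response at node i to impulse at node j
    #            = r[(yi - yj) mod ny, (xi - xj) mod nx]
    dy = (iy.ravel()[:, None] - iy.ravel()[None, :]) % ny
    dx = (ix.ravel()[:, None] - ix.ravel()[None, :]) % nx

    M = np.empty((2 * nw, 2 * nw))
    M[:nw, :nw] = rxx[dy, dx]
    M[:nw, nw:] = rxy[dy, dx]
    M[nw:, :nw] = ryx[dy, dx]
    M[nw:, nw:] = ryy[dy, dx]
    del dy, dx
    assert flat.size == nw
    M = 0.5 * (M + M.T)
    return DenseOperator(
        M=M, shape=kernel.shape, spacing=kernel.spacing,
        substrate=kernel.substrate,
    )
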