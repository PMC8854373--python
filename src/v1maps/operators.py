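"""Orientation-preference operators: anisotropic Laplacian, receptive field, and their combination.

A V1 simple cell's local orientation sensitivity is modelled as an
anisotropic Laplacian (AL): a weighted sum of second derivatives taken in
a frame rotated to the cell's preferred orientation,

    P = a^2 d^2/dx'^2 + b^2 d^2/dy'^2,    b^2 >= a^2 >= 0.

The spatial pooling of inputs is an anisotropic Gaussian receptive-field
(RF) weight G with long axis sigma_x along the preferred orientation and
short axis sigma_y across it.  Because both operations are linear and
shift invariant they commute under convolution, so the cell's response to
a stimulus S is S convolved with a single combined kernel P{G} - a
Gaussian second-derivative kernel with an elongated three-lobe ON/OFF
structure.  The kernel here is evaluated in closed form (no numerical
differentiation).

Sign convention: the returned kernel has a positive (ON) central lobe and
negative (OFF) flanks, matching the plotted receptive-field convention;
overall amplitude is arbitrary and downstream tuning curves are
normalization invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .grid import GridConfigError, GridSpec


@dataclass(frozen=True)
class ALParams:
    """Anisotropic-Laplacian weights and orientation.

    ``a2`` weighs the second derivative along the preferred orientation,
    ``b2`` the derivative across it; ``b2 >= a2 >= 0``.  ``phi`` is the
    preferred orientation in degrees.
    """

    a2: float
    b2: float
    phi: float = 0.0

    def __post_init__(self) -> None:
        if self.a2 < 0 or self.b2 < self.a2:
            raise ValueError(f"AL weights need b2 >= a2 >= 0, got a2={self.a2}, b2={self.b2}")

    @classmethod
    def from_psi(cls, psi: float, phi: float = 0.0) -> "ALParams":
        """Unit-sum parameterization a2 = sin^2(psi), b2 = cos^2(psi), psi in [0, pi/4]."""
        if not 0.0 <= psi <= np.pi / 4 + 1e-12:
            raise ValueError(f"psi must lie in [0, pi/4], got {psi}")
        return cls(a2=float(np.sin(psi) ** 2), b2=float(np.cos(psi) ** 2), phi=phi)

    @classmethod
    def from_ratio(cls, b2_over_a2: float, phi: float = 0.0) -> "ALParams":
        """Unit-sum weights with a given ratio b2/a2 >= 1."""
        if b2_over_a2 < 1.0:
            raise ValueError(f"b2/a2 must be >= 1, got {b2_over_a2}")
        a2 = 1.0 / (1.0 + b2_over_a2)
        return cls(a2=a2, b2=1.0 - a2, phi=phi)

    def with_phi(self, phi: float) -> "ALParams":
        return ALParams(a2=self.a2, b2=self.b2, phi=phi)


@dataclass(frozen=True)
class RFParams:
    """Anisotropic Gaussian receptive-field weight: long axis sigma_x (mm) at angle phi."""

    sigma_x: float = 0.18
    sigma_y: float = 0.09
    phi: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma_y > 0 or self.sigma_x < self.sigma_y:
            raise ValueError(
                f"RF widths need sigma_x >= sigma_y > 0, got {self.sigma_x}, {self.sigma_y}"
            )

    @classmethod
    def from_aspect(cls, aspect: float, sigma_x: float = 0.18, phi: float = 0.0) -> "RFParams":
        if aspect < 1.0:
            raise ValueError(f"aspect ratio sigma_x/sigma_y must be >= 1, got {aspect}")
        return cls(sigma_x=sigma_x, sigma_y=sigma_x / aspect, phi=phi)

    @property
    def aspect(self) -> float:
        return self.sigma_x / self.sigma_y

    def with_phi(self, phi: float) -> "RFParams":
        return RFParams(sigma_x=self.sigma_x, sigma_y=self.sigma_y, phi=phi)


@dataclass(frozen=True)
class CombinedKernel:
    """Sampled combined operator P{G} on its own support grid."""

    grid: GridSpec
    values: NDArray[np.float64]
    al: ALParams
    rf: RFParams

    @property
    def half_width(self) -> int:
        return self.grid.nx // 2


def al_coefficients(params: ALParams) -> tuple[float, float, float]:
    """Fixed-frame coefficients (c_xx, c_xy, c_yy) of the rotated AL operator.

    Expanding P into unrotated derivatives gives
    ``c_xx = a2 cos^2 phi + b2 sin^2 phi``,
    ``c_xy = (a2 - b2) sin 2 phi`` (coefficient of d^2/dxdy), and
    ``c_yy = a2 sin^2 phi + b2 cos^2 phi``.
    """
    ph = np.deg2rad(params.phi)
    c, s = np.cos(ph), np.sin(ph)
    return (
        params.a2 * c * c + params.b2 * s * s,
        (params.a2 - params.b2) * np.sin(2 * ph),
        params.a2 * s * s + params.b2 * c * c,
    )


def rf_weight(
    delta: tuple[NDArray | float, NDArray | float], params: RFParams
) -> NDArray[np.float64] | float:
    """Receptive-field weight G at cortical offset ``delta`` = (dx, dy) in mm.

    An anisotropic Gaussian, unit continuous integral, with long axis at
    ``params.phi``; the peak value is ``1 / (2 pi sigma_x sigma_y)``.
    """
    ph = np.deg2rad(params.phi)
    dxv = np.asarray(delta[0], dtype=float)
    dyv = np.asarray(delta[1], dtype=float)
    xg = dxv * np.cos(ph) + dyv * np.sin(ph)
    yg = -dxv * np.sin(ph) + dyv * np.cos(ph)
    g = np.exp(-0.5 * (xg**2 / params.sigma_x**2 + yg**2 / params.sigma_y**2))
    g = g / (2.0 * np.pi * params.sigma_x * params.sigma_y)
    if np.ndim(delta[0]) == 0 and np.ndim(delta[1]) == 0:
        return float(g)
    return g


def kernel_grid(rf: RFParams, dx: float, n_sigma: float = 4.0) -> GridSpec:
    """Square support grid for a combined kernel, spanning +- ``n_sigma * sigma_x``.

    The grid is centred on the origin with an odd pixel count so the
    kernel peak falls on the central pixel centre.
    """
    half = int(np.ceil(n_sigma * rf.sigma_x / dx))
    n = 2 * half + 1
    # the hypercolumn scale is irrelevant for a kernel support; pick one
    # that satisfies the pixel-tiling invariant exactly
    return GridSpec(
        nx=n, ny=n, dx=dx, a=n * dx / 2.0, origin=(-(half + 0.5) * dx, -(half + 0.5) * dx)
    )


def _gaussian_second_derivs(
    X: NDArray, Y: NDArray, rf: RFParams
) -> tuple[NDArray, NDArray, NDArray]:
    """Closed-form (G_xx, G_xy, G_yy) of the anisotropic Gaussian in the fixed frame."""
    ph = np.deg2rad(rf.phi)
    c, s = np.cos(ph), np.sin(ph)
    xg = X * c + Y * s
    yg = -X * s + Y * c
    sx2, sy2 = rf.sigma_x**2, rf.sigma_y**2
    G = np.exp(-0.5 * (xg**2 / sx2 + yg**2 / sy2)) / (2.0 * np.pi * rf.sigma_x * rf.sigma_y)
    p = xg / sx2
    m = yg / sy2
    u = p * c - m * s  # -d(ln G)/dx
    v = p * s + m * c  # -d(ln G)/dy
    gxx = G * (u * u - (c * c / sx2 + s * s / sy2))
    gyy = G * (v * v - (s * s / sx2 + c * c / sy2))
    gxy = G * (u * v - s * c * (1.0 / sx2 - 1.0 / sy2))
    return gxx, gxy, gyy


def combined_kernel(
    al: ALParams,
    rf: RFParams,
    dx: float = 0.0125,
    grid: GridSpec | None = None,
    n_sigma: float = 4.0,
) -> CombinedKernel:
    """Sampled combined OP operator P{G} with an ON centre.

    Evaluates the anisotropic Laplacian of the receptive-field Gaussian
    analytically on a square support grid (default +-4 sigma_x, beyond
    which the truncated mass is negligible; the kernel is not
    renormalized).  With ``b2 == a2`` this reduces to ``a2`` times the
    isotropic Laplacian of G regardless of the AL orientation.
    """
    if grid is None:
        grid = kernel_grid(rf, dx, n_sigma=n_sigma)
    else:
        lx, ly = grid.extent
        need = 2 * n_sigma * rf.sigma_x
        if lx < need - grid.dx or ly < need - grid.dx:
            raise GridConfigError(
                f"kernel support {lx:.3f} x {ly:.3f} mm too small; needs >= "
                f"{need:.3f} mm (+-{n_sigma} sigma_x) in each direction"
            )
    X, Y = grid.meshgrid()
    cxx, cxy, cyy = al_coefficients(al)
    gxx, gxy, gyy = _gaussian_second_derivs(X, Y, rf)
    values = -(cxx * gxx + cxy * gxy + cyy * gyy)  # ON-centre sign
    return CombinedKernel(grid=grid, values=values, al=al, rf=rf)


def cortical_magnification(eccentricity_deg: float) -> float:
    """Cortical magnification M = 12 / (E + 0.75) in mm per visual degree.

    Monkey V1 fit; ``E`` is eccentricity in degrees, ``E >= 0``.
    """
    if eccentricity_deg < 0:
        raise ValueError(f"eccentricity must be non-negative, got {eccentricity_deg}")
    return 12.0 / (eccentricity_deg + 0.75)
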