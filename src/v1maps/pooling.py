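"""Measurement-site spatial averaging and pinwheel-distance profiles.

Optical-imaging and multi-unit measurements pool the responses of all
neurons within a small neighbourhood of the electrode or pixel.  This is
modelled as a weighted average of the linear responses,

    I_w(r0) = integral I(r) W(r - r0) dr,

with W either a normalized Gaussian of width sigma_r (default 40 um, the
characteristic width of an OP microcolumn) or a zero-mean Mexican-hat
(Laplacian-of-Gaussian style) profile of the same width.  Near a pinwheel
centre the average mixes neurons of all preferred orientations, which
broadens and weakens the pooled tuning curve even though each individual
neuron remains sharply tuned.

Because the average is linear, the pooled tuning curve equals the
response of a single effective kernel: the weighted superposition of the
local combined kernels of every site in the window.  The implementation
builds that effective kernel once per measurement site (with local
orientations quantized to a 1-degree kernel bank) and then sweeps the
stimulus orientation, which makes distance profiles cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from numpy.typing import NDArray

from .grid import GridConfigError, GridSpec
from .operators import ALParams, RFParams, combined_kernel
from .synth import HypercolumnLattice, OPMap
from .tuning import BarStimulusParams, TuningCurve, bar_field, default_angles

WeightKind = Literal["gaussian", "mexican_hat"]
DEFAULT_SIGMA_R = 0.040  # mm (40 um)


@dataclass(frozen=True)
class SiteWeight:
    """Spatial pooling weight around a measurement site."""

    kind: WeightKind = "gaussian"
    sigma_r: float = DEFAULT_SIGMA_R
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.sigma_r > 0:
            raise ValueError(f"sigma_r must be positive, got {self.sigma_r}")
        if self.kind not in ("gaussian", "mexican_hat"):
            raise ValueError(f"unknown weight kind {self.kind!r}")

    def profile(self, dist2: NDArray[np.float64]) -> NDArray[np.float64]:
        """Weight as a function of squared distance (mm^2) from the centre.

        The Gaussian carries its unit-integral normalization; the
        Mexican hat is the plain zero-integral profile
        ``(1 - d^2/2 sigma^2) exp(-d^2/2 sigma^2)``.
        """
        u = dist2 / (2.0 * self.sigma_r**2)
        if self.kind == "gaussian":
            return np.exp(-u) / (2.0 * np.pi * self.sigma_r**2)
        return (1.0 - u) * np.exp(-u)


@dataclass(frozen=True)
class DistanceProfile:
    """Pooled tuning width and strength vs. distance from a pinwheel centre."""

    distances: NDArray[np.float64]  # mm
    hwhm: NDArray[np.float64]  # degrees
    strength: NDArray[np.float64]  # arbitrary units (peak pooled response)
    kind: WeightKind = "gaussian"

    def __post_init__(self) -> None:
        if np.any(self.distances < 0) or np.any(np.diff(self.distances) <= 0):
            raise ValueError("distances must be non-negative and increasing")


def averaged_response(
    site: SiteWeight, field: NDArray[np.float64], grid: GridSpec, n_sigma: float = 4.0
) -> float:
    """Discrete weighted integral of a response field against the site weight.

    Integrates over a +- ``n_sigma * sigma_r`` window; the window must fit
    inside the grid.  Gaussian weights are renormalized to unit discrete
    mass so that pooling a constant field returns that constant exactly.
    """
    if field.shape != (grid.ny, grid.nx):
        raise GridConfigError("field shape does not match grid")
    x0, y0 = site.center
    half = n_sigma * site.sigma_r
    if not grid.contains(x0 - half, y0 - half) or not grid.contains(x0 + half, y0 + half):
        raise GridConfigError(
            f"pooling window (+-{half:.3f} mm) around {site.center} exceeds the grid"
        )
    iy0, ix0 = grid.index_of(x0, y0)
    hw = max(1, int(np.ceil(half / grid.dx)))
    sl = np.s_[iy0 - hw : iy0 + hw + 1, ix0 - hw : ix0 + hw + 1]
    X, Y = grid.meshgrid()
    w = site.profile((X[sl] - x0) ** 2 + (Y[sl] - y0) ** 2)
    if site.kind == "gaussian":
        return float(np.sum(w * field[sl]) / np.sum(w))
    return float(np.sum(w * field[sl]) * grid.pixel_area)


def _effective_site_kernel(
    site: SiteWeight,
    op_map: OPMap,
    al: ALParams,
    rf: RFParams,
    bin_width: float = 1.0,
    n_sigma: float = 4.0,
) -> tuple[NDArray[np.float64], NDArray[np.float64], NDArray[np.float64]]:
    """Pooled kernel H(R) = sum_r W(r - r0) K_{phi(r)}(r - R) and its coordinates.

    Returns (H, X, Y) with X, Y the physical stimulus coordinates of H's
    samples relative to the bar centre (the measurement site).
    """
    grid = op_map.grid
    dx = grid.dx
    x0, y0 = site.center
    half = n_sigma * site.sigma_r
    iy0, ix0 = grid.index_of(x0, y0)
    hw = max(1, int(np.ceil(half / dx)))
    if not (
        hw <= ix0 < grid.nx - hw and hw <= iy0 < grid.ny - hw
    ):
        raise GridConfigError(
            f"pooling window (+-{half:.3f} mm) around {site.center} exceeds the map"
        )
    xs = grid.x_coords()[ix0 - hw : ix0 + hw + 1]
    ys = grid.y_coords()[iy0 - hw : iy0 + hw + 1]
    Xw, Yw = np.meshgrid(xs, ys)
    w = site.profile((Xw - x0) ** 2 + (Yw - y0) ** 2)
    if site.kind == "gaussian":
        w = w / np.sum(w)
    else:
        w = w * grid.pixel_area
    phis = op_map.values[iy0 - hw : iy0 + hw + 1, ix0 - hw : ix0 + hw + 1]
    bins = (np.round(phis / bin_width) * bin_width) % 180.0

    bank: dict[float, NDArray[np.float64]] = {}
    nk = None
    for b in np.unique(bins):
        k = combined_kernel(al.with_phi(float(b)), rf.with_phi(float(b)), dx=dx)
        bank[float(b)] = k.values
        nk = k.values.shape[0]
    assert nk is not None
    kh = nk // 2

    nw = 2 * hw + 1
    H = np.zeros((nw + nk - 1, nw + nk - 1))
    for iy in range(nw):
        for ix in range(nw):
            H[iy : iy + nk, ix : ix + nk] += w[iy, ix] * bank[float(bins[iy, ix])]
    # physical coordinates of H samples relative to the site centre:
    # window pixel offset + kernel sample offset
    off = (np.arange(nw + nk - 1) - (hw + kh)) * dx
    dx_off = (xs[hw] - x0) if nw else 0.0  # site may sit off pixel centre
    dy_off = (ys[hw] - y0) if nw else 0.0
    XH, YH = np.meshgrid(off + dx_off, off + dy_off)
    return H, XH, YH


def averaged_tuning_curve(
    r0: tuple[float, float],
    lattice: HypercolumnLattice | OPMap,
    al: ALParams,
    rf: RFParams,
    kind: WeightKind = "gaussian",
    sigma_r: float = DEFAULT_SIGMA_R,
    stim: BarStimulusParams | None = None,
    angles: NDArray[np.float64] | None = None,
) -> TuningCurve:
    """Pooled tuning curve at site ``r0``: bar centred on the site, responses
    of all neighbouring pixels averaged under the site weight."""
    op_map = lattice.op if isinstance(lattice, HypercolumnLattice) else lattice
    stim = stim or BarStimulusParams()
    angles = default_angles() if angles is None else np.asarray(angles, dtype=float)
    site = SiteWeight(kind=kind, sigma_r=sigma_r, center=r0)
    H, XH, YH = _effective_site_kernel(site, op_map, al, rf)
    area = op_map.grid.pixel_area
    resp = np.empty(angles.shape)
    for i, th in enumerate(angles):
        resp[i] = np.sum(H * bar_field(XH, YH, th, (0.0, 0.0), stim)) * area
    return TuningCurve(angles=angles, responses=resp)


def distance_profile(
    center: tuple[float, float],
    direction: tuple[float, float],
    distances: NDArray[np.float64] | list,
    lattice: HypercolumnLattice,
    al: ALParams,
    rf: RFParams,
    kind: WeightKind = "gaussian",
    sigma_r: float = DEFAULT_SIGMA_R,
    stim: BarStimulusParams | None = None,
    angles: NDArray[np.float64] | None = None,
) -> DistanceProfile:
    """Pooled tuning width (HWHM) and peak strength along a path from a pinwheel centre.

    ``direction`` is normalized internally; ``distances`` are mm from the
    centre.  Strength is the peak of the raw pooled curve (arbitrary
    units); HWHM is measured on the affinely normalized curve.
    """
    from .tuning import fwhm as _fwhm  # local import to avoid cycle at module load

    d = np.asarray(distances, dtype=float)
    norm = float(np.hypot(*direction))
    if norm == 0:
        raise ValueError("direction must be a nonzero vector")
    ux, uy = direction[0] / norm, direction[1] / norm
    hw = np.empty(d.shape)
    strength = np.empty(d.shape)
    for i, dist in enumerate(d):
        r0 = (center[0] + ux * dist, center[1] + uy * dist)
        curve = averaged_tuning_curve(
            r0, lattice, al, rf, kind=kind, sigma_r=sigma_r, stim=stim, angles=angles
        )
        hw[i] = _fwhm(curve) / 2.0
        strength[i] = curve.peak_response
    return DistanceProfile(distances=d, hwhm=hw, strength=strength, kind=kind)
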