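"""Oriented-bar stimuli, orientation tuning curves, and FWHM extraction.

A tuning curve is obtained by sweeping the orientation of a bar stimulus
centred on a measurement point and recording the linear response of the
combined operator there.  Curves are normalized affinely (baseline
subtracted, peak scaled to 1), the convention under which experimental
curves are fitted with a von Mises bump on a baseline, and the full width
at half maximum (FWHM) is read off the normalized curve by linear
interpolation on the circular 0-180 degree domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy import signal

from .grid import GridConfigError, GridSpec
from .operators import ALParams, CombinedKernel, RFParams, combined_kernel
from .synth import OPMap

DEFAULT_BAR_LENGTH = 1.2  # mm; spans the full RF envelope (~6.7 sigma_x)
DEFAULT_BAR_WIDTH = 0.05  # mm; about one OP microcolumn, thin vs. 0.1 mm lobe spacing


@dataclass(frozen=True)
class BarStimulusParams:
    """Geometry of the oriented-bar stimulus (lengths in mm)."""

    length: float = DEFAULT_BAR_LENGTH
    width: float = DEFAULT_BAR_WIDTH
    amplitude: float = 1.0
    edge_scale: float | None = None  # logistic end-cap scale; default width/2

    def __post_init__(self) -> None:
        if not self.length > self.width > 0:
            raise ValueError(
                f"bar needs length > width > 0, got length={self.length}, width={self.width}"
            )

    @property
    def edge(self) -> float:
        return self.edge_scale if self.edge_scale is not None else self.width / 2.0


@dataclass(frozen=True)
class BarStimulus:
    """A smooth oriented-bar luminance field sampled on a grid."""

    grid: GridSpec
    theta: float  # bar orientation, degrees
    center: tuple[float, float]
    params: BarStimulusParams
    values: NDArray[np.float64]


def bar_field(
    X: NDArray, Y: NDArray, theta: float, center: tuple[float, float],
    params: BarStimulusParams,
) -> NDArray[np.float64]:
    """Evaluate the bar luminance profile at physical coordinates (X, Y).

    The bar is the product of a logistic plateau of half-length
    ``length/2`` along its axis and a Gaussian cross profile of standard
    deviation ``width/2``; orientation is 180-degree periodic by
    construction.
    """
    th = np.deg2rad(theta)
    t = (X - center[0]) * np.cos(th) + (Y - center[1]) * np.sin(th)
    s = -(X - center[0]) * np.sin(th) + (Y - center[1]) * np.cos(th)
    arg = np.clip((np.abs(t) - params.length / 2.0) / params.edge, -60.0, 60.0)
    axial = 1.0 / (1.0 + np.exp(arg))
    cross = np.exp(-(s**2) / (2.0 * (params.width / 2.0) ** 2))
    return params.amplitude * axial * cross


def make_bar_stimulus(
    grid: GridSpec,
    theta: float,
    center: tuple[float, float],
    params: BarStimulusParams | None = None,
) -> BarStimulus:
    """Sample an oriented bar on ``grid``; errors if its support leaves the grid."""
    params = params or BarStimulusParams()
    reach = params.length / 2.0 + 4.0 * params.edge
    half_w = 3.0 * params.width / 2.0
    radius = float(np.hypot(reach, half_w))
    if not grid.contains(center[0] - radius, center[1] - radius) or not grid.contains(
        center[0] + radius, center[1] + radius
    ):
        raise GridConfigError(
            f"bar of length {params.length} mm centred at {center} exceeds the grid"
        )
    X, Y = grid.meshgrid()
    return BarStimulus(
        grid=grid, theta=theta % 180.0, center=center, params=params,
        values=bar_field(X, Y, theta, center, params),
    )


@dataclass(frozen=True)
class TuningCurve:
    """Response amplitude vs. stimulus orientation over [0, 180) degrees."""

    angles: NDArray[np.float64]
    responses: NDArray[np.float64]
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.angles.ndim != 1 or self.angles.shape != self.responses.shape:
            raise ValueError("angles and responses must be matching 1-D arrays")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.angles[0] < 0 or self.angles[-1] >= 180.0:
            raise ValueError("angles must lie in [0, 180)")

    def normalize(self) -> "TuningCurve":
        """Affine normalization: subtract the baseline (minimum), scale peak to 1."""
        lo, hi = float(self.responses.min()), float(self.responses.max())
        if hi - lo <= 0:
            raise FlatCurveError("cannot normalize a flat tuning curve")
        return TuningCurve(
            angles=self.angles, responses=(self.responses - lo) / (hi - lo), normalized=True
        )

    @property
    def peak_angle(self) -> float:
        return float(self.angles[int(np.argmax(self.responses))])

    @property
    def peak_response(self) -> float:
        return float(self.responses.max())


class FlatCurveError(ValueError):
    """Raised when a tuning width is requested for a featureless curve."""


def default_angles(step: float = 1.0) -> NDArray[np.float64]:
    return np.arange(0.0, 180.0, step)


def orientation_tuning(
    phi0: float,
    al: ALParams,
    rf: RFParams,
    stim: BarStimulusParams | None = None,
    angles: NDArray[np.float64] | None = None,
    dx: float = 0.0125,
    kernel: CombinedKernel | None = None,
) -> TuningCurve:
    """Single-site tuning curve for a cell with preferred orientation ``phi0``.

    The combined kernel (AL and RF both oriented at ``phi0``) is applied
    to a bar centred on the measurement point for each stimulus angle;
    the raw linear response is recorded.
    """
    stim = stim or BarStimulusParams()
    angles = default_angles() if angles is None else np.asarray(angles, dtype=float)
    if kernel is None:
        kernel = combined_kernel(al.with_phi(phi0), rf.with_phi(phi0), dx=dx)
    X, Y = kernel.grid.meshgrid()
    area = kernel.grid.pixel_area
    resp = np.empty(angles.shape)
    for i, th in enumerate(angles):
        resp[i] = np.sum(kernel.values * bar_field(X, Y, th, (0.0, 0.0), stim)) * area
    return TuningCurve(angles=angles, responses=resp)


def tuning_curve(
    r0: tuple[float, float],
    op_map: OPMap,
    al: ALParams,
    rf: RFParams,
    stim: BarStimulusParams | None = None,
    angles: NDArray[np.float64] | None = None,
) -> TuningCurve:
    """Tuning curve at map position ``r0``, using the local OP there.

    ``r0`` must sit far enough inside the map that the kernel support
    fits (the map supplies only the local preferred orientation; the
    stimulus is evaluated analytically).
    """
    margin = 4.0 * rf.sigma_x
    if not op_map.grid.contains(r0[0], r0[1], margin=margin):
        raise GridConfigError(
            f"site {r0} closer than the kernel support ({margin:.2f} mm) to the map edge"
        )
    phi0 = op_map.angle_at(r0[0], r0[1])
    return orientation_tuning(phi0, al, rf, stim=stim, angles=angles, dx=op_map.grid.dx)


def response_field(
    stim: BarStimulus,
    op_map: OPMap,
    al: ALParams,
    rf: RFParams,
    bin_width: float = 1.0,
) -> NDArray[np.float64]:
    """Linear response I(r) of every map pixel to one stimulus field.

    Each pixel applies the combined kernel oriented at its own local OP.
    Realized with a bank of kernels quantized at ``bin_width`` degrees:
    the stimulus is convolved once per orientation bin present in the map
    (FFT convolution) and pixels select the response of their bin.
    """
    if stim.grid != op_map.grid:
        raise GridConfigError("stimulus and OP map must share a grid")
    dx = op_map.grid.dx
    bins = (np.round(op_map.values / bin_width).astype(int) * bin_width) % 180.0
    out = np.zeros_like(stim.values)
    for b in np.unique(bins):
        k = combined_kernel(al.with_phi(float(b)), rf.with_phi(float(b)), dx=dx)
        conv = signal.fftconvolve(stim.values, k.values, mode="same") * dx * dx
        mask = bins == b
        out[mask] = conv[mask]
    return out


def fwhm(curve: TuningCurve) -> float:
    """Full width at half maximum, in degrees, of a tuning curve.

    The curve is affinely normalized, shifted so its peak sits mid-array
    on the circular domain, and the outermost half-maximum crossings on
    each side are located by linear interpolation.  Raises
    :class:`FlatCurveError` for curves with no modulation.
    """
    n = len(curve.angles)
    if n < 8:
        raise ValueError("tuning curve too coarsely sampled for a width estimate")
    norm = curve if curve.normalized else curve.normalize()
    r = norm.responses
    if r.max() - r.min() < 1e-12:
        raise FlatCurveError("flat tuning curve has no defined width")
    # centre the peak; ties broken by the circular centroid of the peak set
    peaks = np.flatnonzero(r >= r.max() - 1e-12)
    if len(peaks) == 1:
        i0 = int(peaks[0])
    else:
        ang2 = np.deg2rad(2.0 * curve.angles[peaks])
        mean = np.degrees(np.arctan2(np.sin(ang2).sum(), np.cos(ang2).sum())) / 2.0 % 180.0
        i0 = int(np.argmin(np.abs(curve.angles - mean)))
    shifted = np.roll(r, n // 2 - i0)
    half = 0.5
    left = None
    for i in range(n // 2, 0, -1):  # outermost rising crossing on the left
        if shifted[i - 1] < half <= shifted[i]:
            left = (i - 1) + (half - shifted[i - 1]) / (shifted[i] - shifted[i - 1])
    right = None
    for i in range(n // 2, n - 1):  # outermost falling crossing on the right
        if shifted[i] >= half > shifted[i + 1]:
            right = i + (shifted[i] - half) / (shifted[i] - shifted[i + 1])
    if left is None or right is None:
        raise FlatCurveError("curve never falls below half maximum")
    step = float(curve.angles[1] - curve.angles[0])
    return float((right - left) * step)


def hwhm(curve: TuningCurve) -> float:
    """Half width at half maximum: fwhm / 2."""
    return fwhm(curve) / 2.0


def sweep_fwhm(
    b2_over_a2: NDArray | list,
    aspects: NDArray | list,
    sigma_x: float = 0.18,
    phi0: float = 135.0,
    stim: BarStimulusParams | None = None,
    angles: NDArray[np.float64] | None = None,
    dx: float = 0.0125,
) -> NDArray[np.float64]:
    """FWHM (degrees) on the grid of AL ratios x RF aspect ratios.

    Rows follow ``b2_over_a2``, columns follow ``aspects``; each cell is
    the single-site FWHM at preferred orientation ``phi0``.
    """
    ratios = np.asarray(b2_over_a2, dtype=float)
    asp = np.asarray(aspects, dtype=float)
    if np.any(asp < 1.0):
        raise ValueError("aspect ratios must be >= 1")
    out = np.empty((len(ratios), len(asp)))
    for i, rho in enumerate(ratios):
        al = ALParams.from_ratio(float(rho), phi=phi0)
        for j, aspect in enumerate(asp):
            rf = RFParams.from_aspect(float(aspect), sigma_x=sigma_x, phi=phi0)
            out[i, j] = fwhm(orientation_tuning(phi0, al, rf, stim=stim, angles=angles, dx=dx))
    return out
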