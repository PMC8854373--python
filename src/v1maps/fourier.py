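"""Compact Fourier representation of OP-OD maps.

Orientation is a circular variable with period 180 degrees, so an OP map
is made continuous for spectral analysis by phase doubling,
``z = exp(i 2 phi)``; the 0/180 identification disappears and a pinwheel
becomes a simple phase vortex.  The idealized hypercolumn lattice then
has an extremely sparse spectrum: the OD sinusoid carries two modes at
``k = (+-K, 0)`` with ``K = pi / a``, and the phase-doubled OP lattice is
dominated by four modes at ``(+-K, 0)`` and ``(0, +-K)``.  Keeping only
those modes and inverting reproduces the lattice to within a few degrees.

Irregular, biologically realistic maps are synthesized by spreading
random-phase modes around the dominant ones under a Gaussian envelope in
radial wavenumber and azimuth, with the OD spectrum tied to the
left/right OP lobes so the two maps stay mutually consistent.

All wavenumber axes are angular (rad/mm) and fftshift-centred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from numpy.typing import NDArray
from scipy import ndimage

from .grid import GridConfigError, GridSpec
from .synth import ODMap, OPMap

SourceKind = Literal["od", "op_phase_doubled", "generic"]

DEFAULT_DTHETA_DEG = 20.0  # azimuthal envelope width
DEFAULT_DK_FRAC = 0.5  # radial envelope width as a fraction of K0


@dataclass(frozen=True)
class SpectrumMap:
    """Centred 2-D Fourier coefficients of a map with physical k axes.

    ``coeffs[iy, ix]`` corresponds to wavevector ``(kx[ix], ky[iy])`` in
    rad/mm.  ``source`` records what was transformed; OD spectra of real
    fields are Hermitian-symmetric.
    """

    coeffs: NDArray[np.complex128]
    kx: NDArray[np.float64]
    ky: NDArray[np.float64]
    grid: GridSpec
    source: SourceKind = "generic"
    dc_removed: bool = False
    selection: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.coeffs.shape != (len(self.ky), len(self.kx)):
            raise ValueError("coefficient array does not match k axes")

    @property
    def magnitude(self) -> NDArray[np.float64]:
        return np.abs(self.coeffs)

    def dc_index(self) -> tuple[int, int]:
        return (len(self.ky) // 2, len(self.kx) // 2)


@dataclass(frozen=True)
class EnvelopeSpec:
    """Gaussian spectral envelope around dominant modes.

    Magnitude of a mode at radius ``|k|`` and azimuth ``Theta`` is
    ``exp(-(|k| - K0)^2 / 2 dK^2) * exp(-dTheta(Theta)^2 / 2 dTheta^2)``
    maximized over the listed lobe azimuths ``theta0`` (degrees), with
    circular azimuthal distance.
    """

    k0: float  # rad/mm
    theta0: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0)
    delta_k: float | None = None  # default k0/2
    delta_theta: float = DEFAULT_DTHETA_DEG  # degrees

    def __post_init__(self) -> None:
        if not self.k0 > 0:
            raise ValueError("K0 must be positive")
        dk = self.dk
        if not (dk > 0 and self.delta_theta > 0):
            raise ValueError("envelope widths must be positive")

    @property
    def dk(self) -> float:
        return self.delta_k if self.delta_k is not None else DEFAULT_DK_FRAC * self.k0


def apply_phase_doubling(op_map: OPMap) -> NDArray[np.complex128]:
    """Unit-modulus complex field exp(i 2 phi) of an OP map."""
    return np.exp(2j * np.deg2rad(op_map.values))


def decompose(
    values: NDArray, grid: GridSpec, source: SourceKind = "generic"
) -> SpectrumMap:
    """Centred discrete Fourier transform with angular-wavenumber axes.

    ``kx = 2 pi * fftfreq(nx, dx)`` (rad/mm), fftshifted so k = 0 sits at
    index (ny//2, nx//2).  Parseval's identity holds with the plain
    numpy FFT normalization: sum |f|^2 = (1/N) sum |F|^2.
    """
    values = np.asarray(values)
    if values.shape != (grid.ny, grid.nx):
        raise GridConfigError("field shape does not match grid")
    coeffs = np.fft.fftshift(np.fft.fft2(values))
    kx = 2.0 * np.pi * np.fft.fftshift(np.fft.fftfreq(grid.nx, grid.dx))
    ky = 2.0 * np.pi * np.fft.fftshift(np.fft.fftfreq(grid.ny, grid.dx))
    return SpectrumMap(coeffs=coeffs, kx=kx, ky=ky, grid=grid, source=source)


def decompose_od(od: ODMap) -> SpectrumMap:
    return decompose(od.values, od.grid, source="od")


def decompose_op(op_map: OPMap) -> SpectrumMap:
    return decompose(apply_phase_doubling(op_map), op_map.grid, source="op_phase_doubled")


def dominant_modes(
    spec: SpectrumMap, threshold_frac: float = 0.5
) -> list[tuple[int, int]]:
    """Indices (iy, ix) of modes whose magnitude exceeds ``threshold_frac``
    of the largest non-DC magnitude; the DC term is excluded."""
    mag = spec.magnitude.copy()
    mag[spec.dc_index()] = 0.0
    cut = threshold_frac * mag.max()
    iy, ix = np.nonzero(mag >= cut)
    order = np.argsort(-mag[iy, ix], kind="stable")
    return [(int(iy[i]), int(ix[i])) for i in order]


def truncate_modes(
    spec: SpectrumMap,
    top_n: int | None = None,
    threshold_frac: float | None = None,
    explicit: Sequence[tuple[int, int]] | None = None,
) -> SpectrumMap:
    """Zero every coefficient except the selected modes (DC always zeroed).

    Exactly one selector must be given: ``top_n`` keeps the n largest
    non-DC modes, ``threshold_frac`` keeps modes above a fraction of the
    non-DC maximum, ``explicit`` keeps the listed (iy, ix) indices.  For
    real-source (OD) spectra the selection is symmetrized (k and -k kept
    together) so the truncated spectrum stays Hermitian.
    """
    given = [s is not None for s in (top_n, threshold_frac, explicit)]
    if sum(given) != 1:
        raise ValueError("give exactly one of top_n, threshold_frac, explicit")
    mag = spec.magnitude.copy()
    mag[spec.dc_index()] = 0.0
    if explicit is not None:
        sel = [tuple(map(int, s)) for s in explicit]
    elif top_n is not None:
        flat = np.argsort(-mag, axis=None, kind="stable")[:top_n]
        sel = [tuple(map(int, np.unravel_index(i, mag.shape))) for i in flat]
    else:
        sel = dominant_modes(spec, threshold_frac=threshold_frac)
    if spec.source == "od":
        sel = _symmetrize_selection(sel, spec.coeffs.shape)
    sel = [s for s in sel if s != spec.dc_index()]
    if not sel:
        raise ValueError("mode selection is empty after symmetrization/DC removal")
    keep = np.zeros(spec.coeffs.shape, dtype=bool)
    for iy, ix in sel:
        keep[iy, ix] = True
    return SpectrumMap(
        coeffs=np.where(keep, spec.coeffs, 0.0),
        kx=spec.kx,
        ky=spec.ky,
        grid=spec.grid,
        source=spec.source,
        dc_removed=True,
        selection=tuple(sorted(set(sel))),
    )


def _neg_index(i: int, n: int) -> int | None:
    """Index of -k for a centred axis of length n; None for the unpaired Nyquist row."""
    c = n // 2
    j = 2 * c - i
    return j if 0 <= j < n else None


def _symmetrize_selection(
    sel: Sequence[tuple[int, int]], shape: tuple[int, int]
) -> list[tuple[int, int]]:
    ny, nx = shape
    out = set()
    for iy, ix in sel:
        jy, jx = _neg_index(iy, ny), _neg_index(ix, nx)
        if jy is None or jx is None:
            continue  # unpaired Nyquist mode cannot stay Hermitian
        out.add((iy, ix))
        out.add((jy, jx))
    return sorted(out)


def inverse_transform(spec: SpectrumMap) -> NDArray[np.complex128]:
    return np.fft.ifft2(np.fft.ifftshift(spec.coeffs))


def reconstruct_od(spec: SpectrumMap) -> ODMap:
    """Inverse transform of an OD spectrum back to a real stripe field."""
    if spec.source != "od":
        raise ValueError("reconstruct_od needs an 'od' source spectrum")
    z = inverse_transform(spec)
    vals = np.clip(z.real, -1.0, 1.0)
    return ODMap(grid=spec.grid, values=vals)


def reconstruct_op(spec: SpectrumMap) -> OPMap:
    """Recover OP angles from a (possibly truncated) phase-doubled spectrum.

    The inverse transform gives a complex field z; the angle is half its
    argument, wrapped to [0, 180).  Pixels where |z| collapses to ~0
    (angle undefined) take the angle of their nearest valid neighbour.
    """
    if spec.source != "op_phase_doubled":
        raise ValueError("reconstruct_op needs an 'op_phase_doubled' source spectrum")
    z = inverse_transform(spec)
    phi = (np.degrees(np.angle(z)) / 2.0) % 180.0
    bad = np.abs(z) < 1e-12 * np.abs(z).max()
    if bad.any():
        # nearest-neighbour fill via a distance transform
        idx = ndimage.distance_transform_edt(
            bad, return_distances=False, return_indices=True
        )
        phi = phi[tuple(idx)]
    return OPMap(grid=spec.grid, values=phi)


def envelope_magnitude(
    kx: NDArray | float, ky: NDArray | float, env: EnvelopeSpec
) -> NDArray[np.float64]:
    """Gaussian spectral envelope evaluated at wavevector(s) (kx, ky)."""
    kxv = np.asarray(kx, dtype=float)
    kyv = np.asarray(ky, dtype=float)
    r = np.hypot(kxv, kyv)
    theta = np.degrees(np.arctan2(kyv, kxv))
    radial = np.exp(-((r - env.k0) ** 2) / (2.0 * env.dk**2))
    best = np.zeros(np.broadcast(kxv, kyv).shape)
    for t0 in env.theta0:
        d = np.abs((theta - t0 + 180.0) % 360.0 - 180.0)
        best = np.maximum(best, np.exp(-(d**2) / (2.0 * env.delta_theta**2)))
    out = radial * best
    return out


def synthesize_irregular_map(
    grid: GridSpec,
    seed: int,
    delta_k: float | None = None,
    delta_theta: float = DEFAULT_DTHETA_DEG,
    mode_floor: float = 1e-6,
) -> tuple[OPMap, ODMap, SpectrumMap, SpectrumMap]:
    """Random OP-OD map pair with Gaussian-envelope spectra around the lattice modes.

    The construction generalizes the mode structure of the idealized
    lattice, whose phase-doubled field is ``z = F(x) + i F(y)`` with F a
    real stripe wave: the right lobe (azimuth 0 at ``K0 = pi/a``) gets
    random phases under the envelope, the left lobe is its Hermitian
    mirror (so the left/right pair alone transforms to a real field F),
    the top/bottom pair is the left/right pair rotated 90 degrees
    counterclockwise in k space times i (contributing the imaginary part
    i G with G the 90-degree-rotated copy of F), and the OD spectrum is
    the left/right pair phase-advanced by 90 degrees (modes times +-i),
    which in the lattice limit puts every pinwheel centre on an OD
    stripe mid-line.  The OD field is rescaled to unit peak.

    Returns (op, od, op_spectrum, od_spectrum); fully deterministic for
    a given seed.
    """
    if grid.nx != grid.ny:
        raise GridConfigError("irregular-map synthesis expects a square grid")
    k0 = np.pi / grid.a
    env = EnvelopeSpec(k0=k0, theta0=(0.0,), delta_k=delta_k, delta_theta=delta_theta)
    kx = 2.0 * np.pi * np.fft.fftshift(np.fft.fftfreq(grid.nx, grid.dx))
    ky = 2.0 * np.pi * np.fft.fftshift(np.fft.fftfreq(grid.ny, grid.dx))
    KX, KY = np.meshgrid(kx, ky)
    mag = envelope_magnitude(KX, KY, env)
    mag[KX <= 0.0] = 0.0  # right half-plane only; the mirror lobe is added below
    mag[mag < mode_floor * np.max(mag if mag.any() else [1.0])] = 0.0
    if not np.any(mag > 0):
        raise ValueError("spectral envelope has negligible mass on this grid")

    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=mag.shape)
    c_right = mag * np.exp(1j * phases)
    c_right[mag == 0.0] = 0.0

    c_lr = c_right + _conjugate_reflect(c_right)  # Hermitian pair -> real field F
    c_tb = 1j * _rotate_spectrum_ccw(c_lr)  # i G with G = F rotated 90 deg
    c_op = c_lr + c_tb
    c_od = 1j * c_right + _conjugate_reflect(1j * c_right)  # quadrature of F

    z = np.fft.ifft2(np.fft.ifftshift(c_op))
    phi = (np.degrees(np.angle(z)) / 2.0) % 180.0
    om = np.fft.ifft2(np.fft.ifftshift(c_od)).real
    peak = np.abs(om).max()
    if peak > 0:
        om = om / peak
        c_od = c_od / peak
    op = OPMap(grid=grid, values=phi)
    od = ODMap(grid=grid, values=om)
    spec_op = SpectrumMap(coeffs=c_op, kx=kx, ky=ky, grid=grid, source="op_phase_doubled")
    spec_od = SpectrumMap(coeffs=c_od, kx=kx, ky=ky, grid=grid, source="od")
    return op, od, spec_op, spec_od


def _rotate_spectrum_ccw(c: NDArray[np.complex128]) -> NDArray[np.complex128]:
    """Rotate a centred spectrum 90 degrees counterclockwise in k space.

    new(kx, ky) = old(ky, -kx).  The unpaired Nyquist row/column of an
    even-length axis has no rotated partner and is left at zero.
    """
    ny, nx = c.shape
    out = np.zeros_like(c)
    cy, cx = ny // 2, nx // 2
    # target (kx, ky) reads the source at the backward-rotated wavevector (ky, -kx)
    iy, ix = np.mgrid[0:ny, 0:nx]
    src_ix = (iy - cy) + cx  # source kx equals target ky
    src_iy = cy - (ix - cx)  # source ky equals -target kx
    ok = (src_ix >= 0) & (src_ix < nx) & (src_iy >= 0) & (src_iy < ny)
    out[iy[ok], ix[ok]] = c[src_iy[ok], src_ix[ok]]
    return out


def _conjugate_reflect(c: NDArray[np.complex128]) -> NDArray[np.complex128]:
    """conj(c(-k)) on the centred grid; unpaired Nyquist entries drop to zero."""
    ny, nx = c.shape
    out = np.zeros_like(c)
    cy, cx = ny // 2, nx // 2
    iy, ix = np.mgrid[0:ny, 0:nx]
    jy = 2 * cy - iy
    jx = 2 * cx - ix
    ok = (jx >= 0) & (jx < nx) & (jy >= 0) & (jy < ny)
    out[iy[ok], ix[ok]] = np.conj(c[jy[ok], jx[ok]])
    return out


def synthesize_annulus_map(
    grid: GridSpec,
    seed: int,
    delta_k: float | None = None,
    mode_floor: float = 1e-6,
) -> tuple[OPMap, ODMap, SpectrumMap]:
    """OP map from a nearly isotropic annular spectrum at radius K0 = pi/a.

    The azimuthal envelope is flat (every direction equally weighted), as
    observed when Fourier transforming large areas of cortex where the
    stripe direction wanders; only the radial Gaussian remains.  The
    construction is otherwise the one of
    :func:`synthesize_irregular_map` in the wide-azimuth limit.
    """
    op, od, spec, _ = synthesize_irregular_map(
        grid, seed=seed, delta_k=delta_k, delta_theta=1e9, mode_floor=mode_floor
    )
    return op, od, spec


def preprocess_external_map(
    op_map: OPMap,
    pad_factor: int = 2,
    window_sigma: float | None = None,
) -> tuple[NDArray[np.complex128], GridSpec]:
    """Prepare an arbitrary OP map for spectral analysis.

    Phase-doubles the map, applies a centred Gaussian window (default
    sigma = a quarter of the smaller map dimension) to soften the
    non-periodic edges, and embeds the result in a zero array whose
    linear dimensions are ``pad_factor`` times larger.  Returns the
    padded complex field and its grid (same pixel pitch).
    """
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    z = apply_phase_doubling(op_map)
    grid = op_map.grid
    if window_sigma is None:
        window_sigma = 0.25 * min(grid.extent)
    if np.isfinite(window_sigma):
        X, Y = grid.meshgrid()
        cx = grid.origin[0] + grid.extent[0] / 2.0
        cy = grid.origin[1] + grid.extent[1] / 2.0
        z = z * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2.0 * window_sigma**2))
    ny, nx = z.shape
    out = np.zeros((pad_factor * ny, pad_factor * nx), dtype=complex)
    oy = (out.shape[0] - ny) // 2
    ox = (out.shape[1] - nx) // 2
    out[oy : oy + ny, ox : ox + nx] = z
    padded_grid = GridSpec(
        nx=out.shape[1], ny=out.shape[0], dx=grid.dx, a=grid.a,
        origin=(grid.origin[0] - ox * grid.dx, grid.origin[1] - oy * grid.dx),
    )
    return out, padded_grid


def mode_wavevector(spec: SpectrumMap, index: tuple[int, int]) -> tuple[float, float]:
    """Physical wavevector (kx, ky) in rad/mm of a coefficient index (iy, ix)."""
    iy, ix = index
    return float(spec.kx[ix]), float(spec.ky[iy])
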