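"""Idealized orientation-preference / ocular-dominance map synthesis.

The model hypercolumn is a ``2a x 2a`` square holding one left-eye and one
right-eye ocular-dominance (OD) stripe and four orientation-preference
(OP) pinwheels, one per quadrant, centred at ``(+-a/2, +-a/2)``.  OD is a
unit-amplitude sinusoid across the stripes; OP is the half polar angle
around each pinwheel centre, so that a full circuit of a centre sweeps
orientation once through 0-180 degrees.  Tiling hypercolumns yields a
periodic lattice whose pinwheel charges alternate in a checkerboard and
whose centres sit on the OD stripe mid-lines.

Angles at module boundaries are degrees; OP values live in [0, 180).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from numpy.typing import NDArray

from .grid import GridConfigError, GridSpec, hypercolumn_grid, lattice_grid

Arrangement = Literal["I", "II"]


@dataclass(frozen=True)
class ODMap:
    """Ocular-dominance field: signed selectivity in [-1, 1] (right eye positive)."""

    grid: GridSpec
    values: NDArray[np.float64]
    stripe_angle: float = 90.0

    def __post_init__(self) -> None:
        if self.values.shape != (self.grid.ny, self.grid.nx):
            raise GridConfigError(
                f"OD field shape {self.values.shape} does not match grid "
                f"({self.grid.ny}, {self.grid.nx})"
            )
        if np.max(np.abs(self.values)) > 1.0 + 1e-9:
            raise ValueError("OD values must lie in [-1, 1]")


@dataclass(frozen=True)
class OPMap:
    """Orientation-preference field: angles in degrees, [0, 180)."""

    grid: GridSpec
    values: NDArray[np.float64]

    def __post_init__(self) -> None:
        if self.values.shape != (self.grid.ny, self.grid.nx):
            raise GridConfigError(
                f"OP field shape {self.values.shape} does not match grid "
                f"({self.grid.ny}, {self.grid.nx})"
            )
        if np.min(self.values) < 0.0 or np.max(self.values) >= 180.0:
            raise ValueError("OP angles must lie in [0, 180) degrees")

    def angle_at(self, x: float, y: float) -> float:
        """OP angle (degrees) of the pixel containing physical point (x, y)."""
        iy, ix = self.grid.index_of(x, y)
        return float(self.values[iy, ix])


@dataclass(frozen=True)
class HypercolumnLattice:
    """A tiled array of idealized hypercolumns with matching OP and OD fields."""

    op: OPMap
    od: ODMap
    n_cols: int
    n_rows: int
    arrangement: Arrangement = "I"

    def __post_init__(self) -> None:
        if self.op.grid != self.od.grid:
            raise GridConfigError("OP and OD maps of a lattice must share one grid")

    @property
    def grid(self) -> GridSpec:
        return self.op.grid

    def pinwheel_centers(self) -> NDArray[np.float64]:
        """Physical (x, y) positions of all pinwheel centres, shape (N, 2).

        Centres sit at ``(+-a/2, +-a/2)`` within each hypercolumn; the
        first hypercolumn is centred on the origin.
        """
        a = self.grid.a
        xs = []
        for c in range(self.n_cols):
            for r in range(self.n_rows):
                cx, cy = 2 * a * c, 2 * a * r
                for sx in (-0.5, 0.5):
                    for sy in (-0.5, 0.5):
                        xs.append((cx + sx * a, cy + sy * a))
        return np.array(xs)


def generate_od_map(grid: GridSpec, stripe_angle: float = 90.0) -> ODMap:
    """Sinusoidal OD stripes: ``sin(u x + v y)`` with wavevector ``pi/a``.

    ``stripe_angle`` (degrees, in [0, 180)) is the stripe direction
    measured from the x axis; the default 90 gives stripes parallel to
    the y axis.  Stripe mid-lines (full monocular dominance, +-1) lie
    half a stripe width from the zero-crossing borders.
    """
    if not 0.0 <= stripe_angle < 180.0:
        raise ValueError(f"stripe angle must be in [0, 180) degrees, got {stripe_angle}")
    xi = np.deg2rad(stripe_angle)
    u = (np.pi / grid.a) * np.sin(xi)
    v = (np.pi / grid.a) * np.cos(xi)
    X, Y = grid.meshgrid()
    return ODMap(grid=grid, values=np.sin(u * X + v * Y), stripe_angle=stripe_angle)


def pinwheel_angle(
    p: tuple[float, float] | NDArray,
    center: tuple[float, float],
    sign: int = 1,
) -> float | NDArray[np.float64]:
    """OP angle (degrees, [0, 180)) at point(s) ``p`` around a pinwheel centre.

    The angle is half the polar angle of ``p - center``: a counterclockwise
    circuit of the centre sweeps orientation once through 0-180 degrees
    (a positive pinwheel).  ``sign=-1`` mirrors the field across the y axis
    through the centre, reversing the winding (a negative pinwheel).

    Vectorized: ``p`` may be a pair of arrays ``(x, y)``.
    """
    if sign not in (1, -1):
        raise ValueError("pinwheel sign must be +1 or -1")
    px = np.asarray(p[0], dtype=float) - center[0]
    py = np.asarray(p[1], dtype=float) - center[1]
    if np.any((px == 0) & (py == 0)):
        raise ValueError("pinwheel angle is singular at the centre")
    if sign == -1:
        px = -px
    theta = np.degrees(np.arctan2(py, px)) % 360.0
    phi = (0.5 * theta) % 180.0
    if np.ndim(p[0]) == 0:
        return float(phi)
    return phi


def generate_hypercolumn(grid: GridSpec, arrangement: Arrangement = "I") -> OPMap:
    """OP map of a single ``2a x 2a`` hypercolumn.

    The top-right quadrant is the half-polar-angle pinwheel centred at
    ``(a/2, a/2)``; the other three quadrants are its mirror images
    across the x axis, the y axis, and both, which makes the field
    continuous across quadrant boundaries and across the (periodic)
    hypercolumn border, and gives adjacent pinwheels opposite winding.

    Arrangement "II" swaps the left and right OD columns of arrangement
    "I" (a half-period roll along x).
    """
    lx, ly = grid.extent
    if abs(lx - 2 * grid.a) > grid.dx / 2 or abs(ly - 2 * grid.a) > grid.dx / 2:
        raise GridConfigError(
            f"hypercolumn grid must span 2a x 2a = {2 * grid.a} mm square; "
            f"got {lx} x {ly} mm"
        )
    if abs(lx - ly) > grid.dx:
        raise GridConfigError("hypercolumn grid must be square to within one pixel")
    cx = grid.origin[0] + lx / 2.0
    cy = grid.origin[1] + ly / 2.0
    X, Y = grid.meshgrid()
    # mirror symmetry: the field in every quadrant is the top-right
    # pinwheel evaluated at (|x|, |y|) relative to the hypercolumn centre
    phi = pinwheel_angle(
        (np.abs(X - cx), np.abs(Y - cy)), (grid.a / 2.0, grid.a / 2.0), sign=1
    )
    if arrangement == "II":
        phi = np.roll(phi, grid.nx // 2, axis=1)
    elif arrangement != "I":
        raise ValueError(f"arrangement must be 'I' or 'II', got {arrangement!r}")
    return OPMap(grid=grid, values=np.asarray(phi))


def tile_lattice(
    n_cols: int,
    n_rows: int,
    a: float = 1.0,
    dx: float = 0.0125,
    arrangement: Arrangement = "I",
    stripe_angle: float = 90.0,
) -> HypercolumnLattice:
    """Periodic ``n_cols x n_rows`` array of hypercolumns with matched OD stripes.

    OP and OD are ``2a``-periodic in both axes; pinwheel centres fall on
    the OD stripe mid-lines (OD = +-1 columns for the default vertical
    stripes).
    """
    unit = generate_hypercolumn(hypercolumn_grid(a=a, dx=dx), arrangement=arrangement)
    grid = lattice_grid(n_cols, n_rows, a=a, dx=dx)
    op_values = np.tile(unit.values, (n_rows, n_cols))
    op = OPMap(grid=grid, values=op_values)
    od = generate_od_map(grid, stripe_angle=stripe_angle)
    return HypercolumnLattice(
        op=op, od=od, n_cols=n_cols, n_rows=n_rows, arrangement=arrangement
    )


def circular_op_difference(m1: OPMap | NDArray, m2: OPMap | NDArray) -> NDArray[np.float64]:
    """Per-pixel circular OP distance in degrees, in [0, 90].

    Orientation is 180-degree periodic, so the distance between two
    angles is ``min(|d|, 180 - |d|)``.
    """
    v1 = m1.values if isinstance(m1, OPMap) else np.asarray(m1, dtype=float)
    v2 = m2.values if isinstance(m2, OPMap) else np.asarray(m2, dtype=float)
    if isinstance(m1, OPMap) and isinstance(m2, OPMap) and m1.grid != m2.grid:
        raise GridConfigError("OP maps must share a grid to be compared")
    if v1.shape != v2.shape:
        raise GridConfigError(f"shape mismatch: {v1.shape} vs {v2.shape}")
    d = np.abs(v1 - v2) % 180.0
    return np.minimum(d, 180.0 - d)


def find_iso_orientation_site(
    lattice: HypercolumnLattice,
    target_deg: float = 60.0,
    tol_deg: float = 2.0,
    edge_margin: float = 0.9,
) -> tuple[float, float]:
    """Locate a measurement site inside an iso-orientation domain.

    Returns the pixel-centre position whose OP is within ``tol_deg`` of
    ``target_deg`` and which maximizes the distance to the nearest
    pinwheel centre and OD stripe border, excluding pixels within
    ``edge_margin`` mm of the map boundary (so kernel supports and
    pooling windows fit).  Deterministic (first argmax in row-major
    order).
    """
    op = lattice.op
    X, Y = op.grid.meshgrid()
    centers = lattice.pinwheel_centers()
    d_center = np.full(X.shape, np.inf)
    for cx, cy in centers:
        d_center = np.minimum(d_center, np.hypot(X - cx, Y - cy))
    # OD borders are the zero crossings of the sinusoid: for vertical
    # stripes they are the lines x = k*a
    a = op.grid.a
    if lattice.od.stripe_angle == 90.0:
        d_border = np.abs(((X + a / 2.0) % a) - a / 2.0)
    else:  # generic stripes: distance along the stripe normal
        xi = np.deg2rad(lattice.od.stripe_angle)
        s = X * np.sin(xi) + Y * np.cos(xi)
        d_border = np.abs(((s + a / 2.0) % a) - a / 2.0)
    score = np.minimum(d_center, d_border)
    d = np.abs(op.values - target_deg) % 180.0
    mask = np.minimum(d, 180.0 - d) <= tol_deg
    x0, y0 = op.grid.origin
    lx, ly = op.grid.extent
    mask &= (X > x0 + edge_margin) & (X < x0 + lx - edge_margin)
    mask &= (Y > y0 + edge_margin) & (Y < y0 + ly - edge_margin)
    if not mask.any():
        raise ValueError(f"no pixel within {tol_deg} deg of OP {target_deg}")
    score = np.where(mask, score, -np.inf)
    iy, ix = np.unravel_index(np.argmax(score), score.shape)
    return float(X[iy, ix]), float(Y[iy, ix])
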