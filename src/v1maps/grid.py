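"""Shared grid geometry for cortical map and kernel fields.

All fields in this package live on uniform square-pixel grids measured in
millimetres of cortex.  A :class:`GridSpec` records the pixel counts, the
pixel pitch ``dx``, the hypercolumn half-width ``a`` (one ocular-dominance
stripe is ``a`` wide, the full hypercolumn ``2a``), and the physical
position of the grid origin.

Pixel-centre convention: pixel ``(ix, iy)`` sits at
``origin + (ix + 0.5, iy + 0.5) * dx``.  Arrays are indexed ``[iy, ix]``
with ``y`` increasing with the row index.  The half-pixel offset keeps
pinwheel singularities (which sit on half-integer multiples of ``a``) off
the sample points on any grid whose pixels tile a hypercolumn evenly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray


class GridConfigError(ValueError):
    """Raised when a grid specification is geometrically inconsistent."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a rectangular field of square pixels.

    Parameters
    ----------
    nx, ny:
        Pixel counts along x and y.  Must be at least 2.
    dx:
        Pixel pitch in mm.
    a:
        Hypercolumn half-width in mm; ``2a`` is the ocular-dominance
        stripe period.  An integer number of pixels must span ``2a``.
    origin:
        Physical (x, y) position, in mm, of the lower-left corner of
        pixel (0, 0) (the pixel centre is half a pixel further).
    """

    nx: int
    ny: int
    dx: float
    a: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise GridConfigError(f"grid needs nx, ny >= 2, got {self.nx}x{self.ny}")
        if not self.dx > 0:
            raise GridConfigError(f"pixel pitch dx must be positive, got {self.dx}")
        if not self.a > 0:
            raise GridConfigError(f"hypercolumn half-width a must be positive, got {self.a}")
        per = 2.0 * self.a / self.dx
        if abs(per - round(per)) > 1e-9 * per:
            raise GridConfigError(
                f"pixels do not tile one hypercolumn: 2a/dx = {2 * self.a}/{self.dx} "
                f"= {per} is not an integer"
            )

    # -- derived geometry -------------------------------------------------

    @property
    def pixels_per_hypercolumn(self) -> int:
        """Number of pixels spanning one hypercolumn width ``2a``."""
        return round(2.0 * self.a / self.dx)

    @property
    def extent(self) -> tuple[float, float]:
        """Physical size (Lx, Ly) in mm."""
        return (self.nx * self.dx, self.ny * self.dx)

    def x_coords(self) -> NDArray[np.float64]:
        """Pixel-centre x coordinates, shape (nx,)."""
        return self.origin[0] + (np.arange(self.nx) + 0.5) * self.dx

    def y_coords(self) -> NDArray[np.float64]:
        """Pixel-centre y coordinates, shape (ny,)."""
        return self.origin[1] + (np.arange(self.ny) + 0.5) * self.dx

    def meshgrid(self) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
        """(X, Y) pixel-centre coordinate arrays of shape (ny, nx)."""
        return np.meshgrid(self.x_coords(), self.y_coords())

    @property
    def pixel_area(self) -> float:
        return self.dx * self.dx

    def contains(self, x: float, y: float, margin: float = 0.0) -> bool:
        """Whether physical point (x, y) lies inside the grid with ``margin`` mm to spare."""
        x0, y0 = self.origin
        lx, ly = self.extent
        return (
            x0 + margin <= x <= x0 + lx - margin
            and y0 + margin <= y <= y0 + ly - margin
        )

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(iy, ix) index of the pixel containing physical point (x, y)."""
        ix = int(np.floor((x - self.origin[0]) / self.dx))
        iy = int(np.floor((y - self.origin[1]) / self.dx))
        if not (0 <= ix < self.nx and 0 <= iy < self.ny):
            raise GridConfigError(f"point ({x}, {y}) mm lies outside the grid")
        return iy, ix


def hypercolumn_grid(a: float = 1.0, dx: float = 0.0125) -> GridSpec:
    """Grid spanning exactly one hypercolumn, centred on the origin.

    The hypercolumn occupies ``[-a, a] x [-a, a]`` with its four pinwheel
    centres at ``(+-a/2, +-a/2)``.
    """
    n = round(2.0 * a / dx)
    return GridSpec(nx=n, ny=n, dx=dx, a=a, origin=(-a, -a))


def lattice_grid(
    n_cols: int, n_rows: int, a: float = 1.0, dx: float = 0.0125
) -> GridSpec:
    """Grid for an ``n_cols x n_rows`` array of hypercolumns.

    The first hypercolumn is centred on the origin, so the grid spans
    ``[-a, (2 n_cols - 1) a]`` in x and likewise in y.
    """
    if n_cols < 1 or n_rows < 1:
        raise GridConfigError("lattice needs n_cols, n_rows >= 1")
    n = round(2.0 * a / dx)
    return GridSpec(nx=n * n_cols, ny=n * n_rows, dx=dx, a=a, origin=(-a, -a))
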