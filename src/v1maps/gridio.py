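"""Dense-grid file I/O for maps and kernels.

Two interchangeable containers:

* a self-describing text format — a short ``key value`` header followed
  by whitespace-separated rows (9 significant digits), round-tripping to
  printed precision;
* a binary ``.npz`` container holding the same metadata plus the raw
  array, round-tripping bit exactly.

The ``quantity`` tag declares what the field is and switches on value
validation at read time: ``op_deg`` (angles in [0, 180)), ``od``
(selectivity in [-1, 1]), ``kernel`` or ``generic`` (unconstrained).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from numpy.typing import NDArray

from .grid import GridSpec

_MAGIC = "v1maps-grid"
_QUANTITIES = ("op_deg", "od", "kernel", "generic")


class GridParseError(ValueError):
    """Malformed grid file; message carries the offending line number."""


def _validate(values: NDArray[np.float64], quantity: str, where: str) -> None:
    if quantity == "op_deg":
        if values.min() < 0.0 or values.max() >= 180.0:
            raise GridParseError(
                f"{where}: quantity op_deg requires values in [0, 180), "
                f"found range [{values.min():g}, {values.max():g}]"
            )
    elif quantity == "od":
        if np.abs(values).max() > 1.0 + 1e-9:
            raise GridParseError(
                f"{where}: quantity od requires values in [-1, 1], "
                f"found |max| = {np.abs(values).max():g}"
            )


def write_grid(
    path: str | Path,
    grid: GridSpec,
    values: NDArray[np.float64],
    quantity: str = "generic",
) -> None:
    """Write a field either as text (any extension) or binary (``.npz``)."""
    if quantity not in _QUANTITIES:
        raise ValueError(f"quantity must be one of {_QUANTITIES}, got {quantity!r}")
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.ny, grid.nx):
        raise ValueError(f"field shape {values.shape} does not match grid")
    _validate(values, quantity, str(path))
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(
            path,
            magic=np.array(_MAGIC),
            values=values,
            dx=np.array(grid.dx),
            a=np.array(grid.a),
            origin=np.array(grid.origin),
            quantity=np.array(quantity),
        )
        return
    with open(path, "w") as fh:
        fh.write(f"# {_MAGIC} 1\n")
        fh.write(f"nx {grid.nx}\n")
        fh.write(f"ny {grid.ny}\n")
        fh.write(f"dx_mm {grid.dx!r}\n")
        fh.write(f"a_mm {grid.a!r}\n")
        fh.write(f"origin_x_mm {grid.origin[0]!r}\n")
        fh.write(f"origin_y_mm {grid.origin[1]!r}\n")
        fh.write(f"quantity {quantity}\n")
        for row in values:
            fh.write(" ".join(f"{v:.9g}" for v in row) + "\n")


def read_grid(path: str | Path) -> tuple[GridSpec, NDArray[np.float64], str]:
    """Read a grid file (text or ``.npz``); returns (grid, values, quantity)."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as dat:
            if "magic" not in dat or str(dat["magic"]) != _MAGIC:
                raise GridParseError(f"{path}: not a {_MAGIC} container")
            values = dat["values"]
            grid = GridSpec(
                nx=values.shape[1],
                ny=values.shape[0],
                dx=float(dat["dx"]),
                a=float(dat["a"]),
                origin=(float(dat["origin"][0]), float(dat["origin"][1])),
            )
            quantity = str(dat["quantity"])
        _validate(values, quantity, str(path))
        return grid, values, quantity

    header: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(f"# {_MAGIC}"):
            raise GridParseError(f"{path}:1: missing '{_MAGIC}' signature line")
        needed = {"nx", "ny", "dx_mm", "a_mm", "origin_x_mm", "origin_y_mm", "quantity"}
        lineno = 1
        for line in fh:
            lineno += 1
            parts = line.split()
            if not parts:
                continue
            if needed - header.keys():
                if len(parts) != 2:
                    raise GridParseError(
                        f"{path}:{lineno}: expected 'key value' header line, got {line!r}"
                    )
                header[parts[0]] = parts[1]
            else:
                try:
                    rows.append([float(v) for v in parts])
                except ValueError as exc:
                    raise GridParseError(f"{path}:{lineno}: bad data value ({exc})") from exc
        missing = needed - header.keys()
        if missing:
            raise GridParseError(f"{path}: header missing keys {sorted(missing)}")
    quantity = header["quantity"]
    if quantity not in _QUANTITIES:
        raise GridParseError(f"{path}: unknown quantity {quantity!r}")
    nx, ny = int(header["nx"]), int(header["ny"])
    values = np.array(rows, dtype=float)
    if values.shape != (ny, nx):
        raise GridParseError(
            f"{path}: data shape {values.shape} does not match header ({ny}, {nx})"
        )
    grid = GridSpec(
        nx=nx,
        ny=ny,
        dx=float(header["dx_mm"]),
        a=float(header["a_mm"]),
        origin=(float(header["origin_x_mm"]), float(header["origin_y_mm"])),
    )
    _validate(values, quantity, str(path))
    return grid, values, quantity
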