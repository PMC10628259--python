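"""Text raster I/O (ESRI ASCII grid) and stack read/write helpers.

The ASCII grid format carries the grid origin, cell size and nodata value in
a six-line header, which is all the georeferencing the pipeline needs. Multi-
band stacks are written as one ``.asc`` per species plus a ``bands.csv``
sidecar mapping file name to species id.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional

import numpy as np

from .core import Grid, SuitabilityStack

_DEFAULT_NODATA = -9999.0


def write_ascii_grid(path, array: np.ndarray, grid: Optional[Grid] = None,
                     nodata: float = _DEFAULT_NODATA) -> None:
    """Write a 2-D array as an ESRI ASCII grid; NaN becomes the nodata value.

    Row 0 of the array is the southernmost row, so it is written last
    (ASCII grids store north-up).
    """
    array = np.asarray(array, dtype=float)
    if array.ndim != 2:
        raise ValueError("ASCII grid arrays must be 2-D")
    nrow, ncol = array.shape
    if grid is None:
        grid = Grid(nrow, ncol)
    if grid.shape != array.shape:
        raise ValueError("grid shape does not match array")
    out = np.where(np.isfinite(array), array, nodata)
    header = (
        f"ncols {ncol}\nnrows {nrow}\n"
        f"xllcorner {grid.x0}\nyllcorner {grid.y0}\n"
        f"cellsize {grid.cellsize}\nNODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for r in range(nrow - 1, -1, -1):
            fh.write(" ".join(repr(float(v)) for v in out[r]))
            fh.write("\n")


def read_ascii_grid(path) -> tuple[np.ndarray, Grid]:
    """Read an ESRI ASCII grid; nodata cells become NaN. Returns (array, grid)."""
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        ncol, nrow = int(header["ncols"]), int(header["nrows"])
        nodata = header.get("nodata_value", _DEFAULT_NODATA)
        data = np.loadtxt(fh, dtype=float, ndmin=2)
    if data.shape != (nrow, ncol):
        raise ValueError(f"grid body shape {data.shape} does not match header")
    data = data[::-1].copy()  # back to south-up row order
    data[data == nodata] = np.nan
    grid = Grid(nrow, ncol, x0=header["xllcorner"], y0=header["yllcorner"],
                cellsize=header["cellsize"])
    return data, grid


def write_stack(directory, stack: SuitabilityStack, grid: Optional[Grid] = None) -> None:
    """Write a suitability stack as a directory of .asc files + bands.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sid in enumerate(stack.species_ids):
        fname = f"band_{i:05d}.asc"
        write_ascii_grid(directory / fname, stack.values[i], grid)
        rows.append({"band": i, "file": fname, "species_id": sid})
    with open(directory / "bands.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["band", "file", "species_id"])
        writer.writeheader()
        writer.writerows(rows)


def read_stack(directory) -> tuple[SuitabilityStack, Grid]:
    directory = Path(directory)
    with open(directory / "bands.csv", newline="") as fh:
        rows = sorted(csv.DictReader(fh), key=lambda r: int(r["band"]))
    arrays, ids, grid = [], [], None
    for row in rows:
        arr, grid = read_ascii_grid(directory / row["file"])
        arrays.append(np.nan_to_num(arr, nan=0.0))
        ids.append(row["species_id"])
    return SuitabilityStack(np.stack(arrays), ids), grid
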