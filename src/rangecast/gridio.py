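"""Reading and writing gridded layers as ESRI ASCII rasters.

All grids in this package are 2-D numpy arrays of shape ``(ny, nx)`` with
row index increasing *northward* (row 0 is the southernmost row) and column
index increasing eastward.  The ESRI ASCII format stores rows top-down, so
arrays are flipped on write and on read.
"""

from __future__ import annotations

import numpy as np

NODATA = -9999.0


def write_ascii_grid(path, grid, cell_size, xll=0.0, yll=0.0, nodata=NODATA):
    """Write a 2-D array to an ESRI ASCII grid file.

    ``cell_size`` and the lower-left corner are in the same linear units the
    landscape uses (km here; the format itself is unit-agnostic).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise ValueError(f"expected a 2-D grid, got shape {grid.shape}")
    ny, nx = grid.shape
    out = np.where(np.isfinite(grid), grid, nodata)
    header = (
        f"ncols {nx}\n"
        f"nrows {ny}\n"
        f"xllcorner {xll}\n"
        f"yllcorner {yll}\n"
        f"cellsize {cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, np.flipud(out), fmt="%.8g")


def read_ascii_grid(path):
    """Read an ESRI ASCII grid. Returns ``(grid, cell_size)``.

    NODATA cells come back as NaN.
    """
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            parts = fh.readline().split()
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    ny, nx = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(ny, nx)
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return np.flipud(data).copy(), header["cellsize"]


def _is_number(token):
    try:
        float(token)
    except ValueError:
        return False
    return True
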