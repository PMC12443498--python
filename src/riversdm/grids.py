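"""Grid conventions and plain-text raster I/O.

Rasters are row-major numpy arrays indexed 0-based as (row, col), row 0 at
the top.  The accompanying abstract coordinate reference is an equal-area
Cartesian plane in kilometres with the origin at the bottom-left grid
corner and y increasing upward, so cell (row, col) has its center at

    x = (col + 0.5) * cell_size_km
    y = (n_rows - row - 0.5) * cell_size_km

Rasters are persisted as ESRI ASCII grids (plain text, nodata -9999),
which round-trip float64 exactly via repr formatting.
"""

from __future__ import annotations

import numpy as np

NODATA = -9999.0


def cell_center(row: int, col: int, n_rows: int, cell_size_km: float) -> tuple[float, float]:
    """Return (x, y) km coordinates of a cell center."""
    return ((col + 0.5) * cell_size_km, (n_rows - row - 0.5) * cell_size_km)


def cell_centers(cells, n_rows: int, cell_size_km: float) -> np.ndarray:
    """Vectorized cell centers; ``cells`` is an (n, 2) array-like of (row, col)."""
    cells = np.asarray(cells, dtype=float).reshape(-1, 2)
    x = (cells[:, 1] + 0.5) * cell_size_km
    y = (n_rows - cells[:, 0] - 0.5) * cell_size_km
    return np.column_stack([x, y])


def point_to_cell(x: float, y: float, n_rows: int, cell_size_km: float) -> tuple[int, int]:
    """Containing cell of a point; points on cell edges go to the higher index."""
    col = int(np.floor(x / cell_size_km))
    row = int(n_rows - 1 - np.floor(y / cell_size_km))
    return (row, col)


def write_ascii_grid(path, grid: np.ndarray, cell_size_km: float, nodata: float = NODATA) -> None:
    arr = np.asarray(grid, dtype=float)
    out = np.where(np.isfinite(arr), arr, nodata)
    n_rows, n_cols = arr.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {n_cols}\n")
        fh.write(f"nrows {n_rows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {cell_size_km!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for r in range(n_rows):
            fh.write(" ".join(repr(float(v)) for v in out[r]) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, float]:
    """Read an ESRI ASCII grid; nodata cells become NaN. Returns (grid, cellsize)."""
    header: dict[str, float] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    grid = np.array(rows, dtype=float)
    nodata = header.get("nodata_value", NODATA)
    grid[grid == nodata] = np.nan
    return grid, header.get("cellsize", 1.0)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False
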