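"""Priority river areas from the committee-averaged suitability map.

Cells with EMca strictly above a probability threshold (default 0.9) are
grouped into clumps — connected components under 8-directional adjacency
— and clumps with more than 10 cells are retained.  Clumps are clipped
to river polygons (cell centers falling outside all river polygons are
discarded; a clump losing every cell is dropped and logged), and the
surviving priority cells are accounted per region as total area and the
split inside/outside protected-area polygons, by cell-center-in-polygon
membership so the additivity inside + outside = total is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.ops import unary_union

from .errors import PriorityError
from .grids import cell_centers


@dataclass
class Clump:
    clump_id: int
    cells: list[tuple[int, int]]
    cell_count: int
    area_km2: float


def threshold_map(emca_map: np.ndarray, p: float = 0.9) -> np.ndarray:
    """Boolean grid: True iff EMca > p strictly; nodata counts False."""
    with np.errstate(invalid="ignore"):
        return np.isfinite(emca_map) & (emca_map > p)


_STRUCTURE_8 = np.ones((3, 3), dtype=int)
_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def detect_clumps(
    binary_grid: np.ndarray,
    adjacency: int = 8,
    min_cells: int = 11,
    cell_area_km2: float = 1.0,
) -> list[Clump]:
    """Connected components of the binary grid, size-filtered.

    Components with at least ``min_cells`` cells (default 11, i.e. cell
    frequency strictly greater than 10) are kept.  Clump ids are assigned
    in raster-scan order of each component's first cell, starting at 1.
    """
    if adjacency not in (4, 8):
        raise PriorityError("adjacency must be 4 or 8")
    structure = _STRUCTURE_8 if adjacency == 8 else _STRUCTURE_4
    labeled, n = ndimage.label(np.asarray(binary_grid, dtype=bool), structure=structure)
    clumps = []
    for lab in range(1, n + 1):
        cells = np.argwhere(labeled == lab)
        if len(cells) < min_cells:
            continue
        cell_list = [tuple(map(int, c)) for c in cells]  # argwhere is scan-ordered
        clumps.append(
            Clump(
                clump_id=0,
                cells=cell_list,
                cell_count=len(cell_list),
                area_km2=len(cell_list) * cell_area_km2,
            )
        )
    clumps.sort(key=lambda c: c.cells[0])
    for i, clump in enumerate(clumps, start=1):
        clump.clump_id = i
    return clumps


def clip_to_rivers(
    clumps: list[Clump],
    river_polygons,
    cell_size_km: float,
    n_rows: int,
) -> tuple[list[Clump], list[dict]]:
    """Trim clumps to cells whose centers fall inside the river polygons.

    Clumps left with no covered cell are dropped and logged — the model
    can flag habitat where no river polygon exists to receive it.
    Returns (clipped clumps, drop log).
    """
    geoms = getattr(river_polygons, "geoms", [river_polygons])
    for g in geoms:
        if not g.is_valid:
            raise PriorityError("invalid river polygon")
    union = unary_union(list(geoms))
    kept: list[Clump] = []
    log: list[dict] = []
    for clump in clumps:
        centers = cell_centers(clump.cells, n_rows, cell_size_km)
        inside = shapely.intersects_xy(union, centers[:, 0], centers[:, 1])
        cells = [c for c, ok in zip(clump.cells, inside) if ok]
        if not cells:
            log.append(
                {
                    "clump_id": clump.clump_id,
                    "event": "dropped",
                    "reason": "no_river_polygon_coverage",
                    "cell_count": clump.cell_count,
                }
            )
            continue
        if len(cells) < clump.cell_count:
            log.append(
                {
                    "clump_id": clump.clump_id,
                    "event": "trimmed",
                    "reason": "partial_river_polygon_coverage",
                    "cell_count": len(cells),
                }
            )
        area = len(cells) * cell_size_km**2
        kept.append(Clump(clump.clump_id, cells, len(cells), area))
    return kept, log


def overlay_protected(
    priority_cells: list[tuple[int, int]],
    pa_set,
    region_layer: list[tuple[str, "shapely.Polygon"]],
    cell_size_km: float,
    n_rows: int,
) -> pd.DataFrame:
    """Per-region priority-area accounting.

    A cell is inside protection when its center falls in the union of
    protected polygons (overlaps are unioned first — no double counting).
    Cells outside every region polygon are tallied under "unassigned".
    The "all" row sums the region rows.
    """
    cell_area = cell_size_km**2
    regions = [label for label, _ in region_layer] + ["unassigned"]
    table = pd.DataFrame(
        0.0,
        index=regions + ["all"],
        columns=["total_km2", "inside_pa_km2", "outside_pa_km2"],
    )
    if priority_cells:
        centers = cell_centers(priority_cells, n_rows, cell_size_km)
        pa_union = pa_set.union() if pa_set is not None else None
        if pa_union is None or pa_union.is_empty:
            inside_pa = np.zeros(len(centers), dtype=bool)
        else:
            inside_pa = shapely.intersects_xy(pa_union, centers[:, 0], centers[:, 1])
        assigned = np.full(len(centers), "unassigned", dtype=object)
        unclaimed = np.ones(len(centers), dtype=bool)
        for label, poly in region_layer:
            hit = unclaimed & shapely.intersects_xy(poly, centers[:, 0], centers[:, 1])
            assigned[hit] = label
            unclaimed &= ~hit
        for region in regions:
            sel = assigned == region
            total = sel.sum() * cell_area
            inside = (sel & inside_pa).sum() * cell_area
            table.loc[region] = [total, inside, total - inside]
    table.loc["all"] = table.loc[regions].sum(axis=0)
    return table


def percent_unprotected(table: pd.DataFrame, region: str = "all") -> float:
    """100 x outside / total for one region row; errors on a zero total."""
    if region not in table.index:
        raise PriorityError(f"unknown region {region!r}")
    total = float(table.loc[region, "total_km2"])
    if total <= 0:
        raise PriorityError(f"region {region!r} has zero total priority area")
    return 100.0 * float(table.loc[region, "outside_pa_km2"]) / total
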