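"""Thresholding, clump detection, river clipping, protected-area accounting."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import MultiPolygon, box

from riversdm.errors import PriorityError
from riversdm.priority import (
    Clump,
    clip_to_rivers,
    detect_clumps,
    overlay_protected,
    percent_unprotected,
    threshold_map,
)
from riversdm.synthetic import ProtectedAreaSet


# --- independent flood-fill oracle ---------------------------------------------


def flood_fill_components(grid):
    """8-connected components by explicit stack-based flood fill."""
    grid = np.asarray(grid, dtype=bool)
    seen = np.zeros_like(grid)
    comps = []
    rows, cols = grid.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if not grid[r0, c0] or seen[r0, c0]:
                continue
            stack = [(r0, c0)]
            seen[r0, c0] = True
            comp = []
            while stack:
                r, c = stack.pop()
                comp.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < rows and 0 <= cc < cols
                            and grid[rr, cc] and not seen[rr, cc]
                        ):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            comps.append(frozenset(comp))
    return set(comps)


# --- thresholding ----------------------------------------------------------------


def test_threshold_is_strict_and_nodata_safe():
    emca = np.array([[0.9, 0.91], [np.nan, 1.0]])
    binary = threshold_map(emca, 0.9)
    assert binary.tolist() == [[False, True], [False, True]]


def test_threshold_all_zero_map_is_empty():
    assert not threshold_map(np.zeros((5, 5)), 0.9).any()


# --- clump detection --------------------------------------------------------------


def test_small_blob_is_filtered():
    grid = np.zeros((10, 10), dtype=bool)
    grid[2:3, 2:7] = True  # 5 cells
    assert detect_clumps(grid) == []


def test_diagonal_chain_is_one_clump():
    grid = np.zeros((15, 15), dtype=bool)
    for i in range(12):
        grid[i, i] = True
    clumps = detect_clumps(grid)
    assert len(clumps) == 1
    assert clumps[0].cell_count == 12


def test_exactly_eleven_cells_is_retained():
    grid = np.zeros((5, 12), dtype=bool)
    grid[1, 0:11] = True
    clumps = detect_clumps(grid, min_cells=11)
    assert len(clumps) == 1 and clumps[0].cell_count == 11


def test_clump_ids_follow_raster_scan_order():
    grid = np.zeros((30, 30), dtype=bool)
    grid[20:24, 1:5] = True   # later in scan order
    grid[1:5, 20:24] = True   # earlier (row 1)
    clumps = detect_clumps(grid)
    assert [c.clump_id for c in clumps] == [1, 2]
    assert clumps[0].cells[0][0] < clumps[1].cells[0][0]


def test_area_is_cell_count_times_cell_area():
    grid = np.zeros((10, 10), dtype=bool)
    grid[0:4, 0:4] = True
    (clump,) = detect_clumps(grid, cell_area_km2=0.2025)
    assert clump.area_km2 == pytest.approx(16 * 0.2025)


def test_clumps_match_flood_fill_oracle_on_random_grids():
    rng = np.random.default_rng(123)
    for _ in range(30):
        grid = rng.random((50, 50)) < rng.uniform(0.2, 0.6)
        clumps = detect_clumps(grid, min_cells=1)
        ours = {frozenset(c.cells) for c in clumps}
        assert ours == flood_fill_components(grid)
        big_ours = {frozenset(c.cells) for c in detect_clumps(grid, min_cells=11)}
        big_oracle = {c for c in flood_fill_components(grid) if len(c) >= 11}
        assert big_ours == big_oracle


# --- river clipping -----------------------------------------------------------------


def _clump_from_block(r0, r1, c0, c1, cell=1.0):
    cells = [(r, c) for r in range(r0, r1) for c in range(c0, c1)]
    return Clump(1, cells, len(cells), len(cells) * cell**2)


def test_clip_identity_when_fully_covered():
    clump = _clump_from_block(0, 3, 0, 4)
    rivers = MultiPolygon([box(-1, 0, 10, 20)])
    kept, log = clip_to_rivers([clump], rivers, 1.0, n_rows=10)
    assert kept[0].cell_count == 12
    assert log == []


def test_clip_drops_and_logs_uncovered_clump():
    clump = _clump_from_block(0, 3, 0, 4)
    rivers = MultiPolygon([box(100, 100, 110, 110)])
    kept, log = clip_to_rivers([clump], rivers, 1.0, n_rows=10)
    assert kept == []
    assert log[0]["reason"] == "no_river_polygon_coverage"


def test_clip_halves_partially_covered_clump():
    # 4 x 10 block of cells; river polygon covers the left half exactly
    clump = _clump_from_block(0, 4, 0, 10)
    n_rows = 10
    rivers = MultiPolygon([box(0, 0, 5.0, n_rows)])  # columns 0..4 of 10
    kept, log = clip_to_rivers([clump], rivers, 1.0, n_rows=n_rows)
    assert abs(kept[0].cell_count - 20) <= 4  # half, within one cell per row
    assert log[0]["event"] == "trimmed"


def test_clip_invalid_polygon_raises():
    from shapely.geometry import Polygon

    invalid = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])  # self-intersecting bowtie
    clump = _clump_from_block(0, 2, 0, 2)
    with pytest.raises(PriorityError):
        clip_to_rivers([clump], MultiPolygon([invalid]), 1.0, n_rows=10)


# --- protected-area overlay -----------------------------------------------------------


REGIONS = [("west", box(0, 0, 15, 30)), ("east", box(15, 0, 30, 30))]


def test_full_protection_means_zero_outside():
    cells = [(r, c) for r in range(5) for c in range(6)]
    pa = ProtectedAreaSet([box(0, 0, 30, 30)], ["west"])
    table = overlay_protected(cells, pa, REGIONS, 1.0, n_rows=30)
    assert (table["outside_pa_km2"] == 0).all()
    assert table.loc["all", "total_km2"] == pytest.approx(30.0)


def test_empty_protection_means_zero_inside():
    cells = [(r, c) for r in range(5) for c in range(6)]
    pa = ProtectedAreaSet([], [])
    table = overlay_protected(cells, pa, REGIONS, 1.0, n_rows=30)
    assert (table["inside_pa_km2"] == 0).all()


def test_constructed_overlay_areas():
    # 30 priority cells at 0.45 km cells; PA covers exactly 12 cell centers
    cell = 0.45
    cells = [(10, c) for c in range(30)]
    pa = ProtectedAreaSet([box(0.0, 0.0, 12 * cell, 100.0)], ["west"])
    regions = [("west", box(0, 0, 100, 100))]
    table = overlay_protected(cells, pa, regions, cell, n_rows=30)
    assert table.loc["west", "inside_pa_km2"] == pytest.approx(12 * 0.2025)
    assert table.loc["west", "outside_pa_km2"] == pytest.approx(18 * 0.2025)
    assert table.loc["west", "total_km2"] == pytest.approx(30 * 0.2025)


def test_overlapping_protected_polygons_not_double_counted():
    cells = [(5, c) for c in range(10)]
    pa = ProtectedAreaSet([box(0, 0, 50, 50), box(0, 0, 50, 50)], ["west", "west"])
    table = overlay_protected(cells, pa, [("west", box(0, 0, 50, 50))], 1.0, n_rows=20)
    assert table.loc["west", "inside_pa_km2"] == pytest.approx(10.0)


def test_cells_outside_regions_are_logged_unassigned():
    cells = [(0, 28), (0, 29)]  # x ~ 28.5, 29.5 beyond both strips? no: east covers to 30
    regions = [("west", box(0, 0, 10, 30))]
    table = overlay_protected(cells, ProtectedAreaSet([], []), regions, 1.0, n_rows=30)
    assert table.loc["unassigned", "total_km2"] == pytest.approx(2.0)


def test_additivity_invariant():
    rng = np.random.default_rng(5)
    cells = [tuple(map(int, rc)) for rc in rng.integers(0, 30, size=(40, 2))]
    pa = ProtectedAreaSet([box(3, 3, 18, 21)], ["west"])
    table = overlay_protected(cells, pa, REGIONS, 0.45, n_rows=30)
    assert np.allclose(
        table["inside_pa_km2"] + table["outside_pa_km2"], table["total_km2"], rtol=1e-9
    )
    region_sum = table.drop(index="all").sum(axis=0)
    assert np.allclose(region_sum, table.loc["all"], rtol=1e-9)


# --- percent unprotected ----------------------------------------------------------------


def _table(total, outside, region="all"):
    return pd.DataFrame(
        {"total_km2": [total], "inside_pa_km2": [total - outside], "outside_pa_km2": [outside]},
        index=[region],
    )


def test_percent_unprotected_extremes():
    assert percent_unprotected(_table(10.0, 10.0)) == pytest.approx(100.0)
    assert percent_unprotected(_table(10.0, 0.0)) == pytest.approx(0.0)


def test_percent_unprotected_zero_total_raises():
    with pytest.raises(PriorityError):
        percent_unprotected(_table(0.0, 0.0))


def test_percent_unprotected_reference_regional_table():
    """The published whole-range accounting: 1174.56 of 1319.12 km2 outside
    protection, i.e. 89.04% — 'about 90%' of priority habitat unprotected."""
    import importlib.resources

    path = importlib.resources.files("riversdm") / "data" / "reference_priority_areas.csv"
    table = pd.read_csv(path, index_col="region")
    pct = percent_unprotected(table, region="entire_range")
    assert pct == pytest.approx(100.0 * 1174.56 / 1319.12, abs=1e-9)
    assert round(pct, 2) == 89.04
    assert round(pct, -1) == 90.0
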