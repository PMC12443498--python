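"""Occurrence curation: filters, early-life classification, snapping,
grid sampling, pseudoabsences."""

import datetime as dt
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riversdm.curation import (
    CurationConfig,
    OccurrenceRecord,
    classify_early_life,
    filter_records,
    generate_pseudoabsences,
    grid_sample,
    snap_to_river,
)
from riversdm.errors import CurationError
from riversdm.fixtures import toy_occurrence_table
from riversdm.network import generate_stream_network
from riversdm.synthetic import generate_env_stack

from conftest import build_network


def make_record(i=0, lon=5.0, lat=5.0, date=dt.date(2005, 6, 1), unc=100.0,
                wb="river", evidence="none", source="S01"):
    return OccurrenceRecord(
        record_id=i, lon=lon, lat=lat, event_date=date,
        coord_uncertainty_m=unc, waterbody_class=wb,
        life_stage_evidence=evidence, source_id=source,
    )


CFG = CurationConfig()


# --- filter_records ------------------------------------------------------------


@pytest.mark.parametrize(
    "unc,year,wb,expect_kept,expect_reason",
    [
        (1500.0, 2005, "river", False, "uncertainty"),
        (1000.0, 1995, "river", True, ""),          # strictly greater-than rule
        (None, 1989, "river", False, "date"),
        (500.0, 1990, "river", True, ""),            # year boundary kept
        (200.0, 2000, "reservoir", False, "waterbody"),
        (200.0, 2000, "dam", False, "waterbody"),
        (200.0, 2000, "lake", True, ""),
        (None, None, "river", True, ""),              # missing metadata kept
        (2000.0, 1980, "reservoir", False, "uncertainty"),  # primary reason order
    ],
)
def test_filter_rules(unc, year, wb, expect_kept, expect_reason):
    rec = make_record(unc=unc, date=dt.date(year, 7, 1) if year else None, wb=wb)
    kept, audit = filter_records([rec], CFG)
    assert (len(kept) == 1) == expect_kept
    assert audit[0]["reason"] == expect_reason


def test_toy_table_counts_and_audit_partition():
    records, expected = toy_occurrence_table()
    kept, audit = filter_records(records, CFG)
    assert len(kept) == expected["kept"]
    reasons = [a["reason"] for a in audit if a["disposition"] == "dropped"]
    for reason in ("uncertainty", "date", "waterbody"):
        assert reasons.count(reason) == expected[reason]
    assert len(kept) + len(reasons) == len(records)
    assert {a["record_id"] for a in audit} == {r.record_id for r in records}


@settings(derandomize=True, max_examples=150)
@given(
    unc=st.one_of(st.none(), st.floats(0, 5000)),
    year=st.one_of(st.none(), st.integers(1950, 2023)),
    wb=st.sampled_from(["river", "reservoir", "dam", "lake", "unknown"]),
)
def test_filter_membership_depends_only_on_violations(unc, year, wb):
    """A record is dropped iff it violates at least one stated rule."""
    rec = make_record(unc=unc, date=dt.date(year, 1, 15) if year else None, wb=wb)
    kept, audit = filter_records([rec], CFG)
    violates = (
        (unc is not None and unc > 1000)
        or (year is not None and year < 1990)
        or wb in ("reservoir", "dam")
    )
    assert (len(kept) == 0) == violates
    assert len(audit) == 1 and (audit[0]["disposition"] == "dropped") == violates


# --- classify_early_life ---------------------------------------------------------


@pytest.fixture(scope="module")
def ordered_network():
    # stem of orders 1..3 plus a second-order side; cell size 1 km
    specs = [
        (0, [(0, 0)], 4), (1, [(0, 2)], 4),
        (2, [(0, 4)], 5), (3, [(0, 6)], 5),
        (4, [(1, 1), (2, 2)], 6), (5, [(1, 5), (2, 4)], 6),
        (6, [(3, 3), (4, 3), (5, 3)], None),
    ]
    return build_network(specs, grid_shape=(12, 12), cell_size_km=1.0)


def _record_at_cell(net, cell, **kw):
    rows = net.grid_shape[0]
    s = net.cell_size_km
    return make_record(lon=(cell[1] + 0.5) * s, lat=(rows - cell[0] - 0.5) * s, **kw)


def test_low_order_cell_is_early_life(ordered_network):
    rec = _record_at_cell(ordered_network, (3, 3))  # order-3 stem
    out, _ = classify_early_life([rec], ordered_network, CFG)
    assert out[0].early_life is True


def test_high_order_without_evidence_is_not_early_life(ordered_network):
    cfg = CurationConfig(max_strahler=2)
    rec = _record_at_cell(ordered_network, (3, 3))  # order 3 > max 2
    out, audit = classify_early_life([rec], ordered_network, cfg)
    assert out[0].early_life is False
    assert audit[0]["reason"] == "strahler_order"


def test_documented_evidence_overrides_order(ordered_network):
    cfg = CurationConfig(max_strahler=2)
    rec = _record_at_cell(
        ordered_network, (3, 3), evidence="documented_spawning_or_nursing"
    )
    out, _ = classify_early_life([rec], ordered_network, cfg)
    assert out[0].early_life is True


def test_registry_membership_overrides_order(ordered_network):
    cfg = CurationConfig(max_strahler=2, spawning_river_registry=[6])
    rec = _record_at_cell(ordered_network, (4, 3))
    out, _ = classify_early_life([rec], ordered_network, cfg)
    assert out[0].early_life is True


def test_off_river_record_pulls_order_within_500m(ordered_network):
    # 0.4 km from the order-2 cell (1, 1): inside the 500 m pull
    rec = make_record(lon=1.9, lat=ordered_network.grid_shape[0] - 1 - 0.5)
    out, _ = classify_early_life([rec], ordered_network, CFG)
    assert out[0].early_life is True


def test_far_off_river_record_fails_with_reason(ordered_network):
    rec = make_record(lon=11.5, lat=1.0)
    out, audit = classify_early_life([rec], ordered_network, CFG)
    assert out[0].early_life is False
    assert audit[0]["reason"] == "no_order_within_pull"


# --- snapping --------------------------------------------------------------------


@pytest.fixture(scope="module")
def snap_scape():
    net = generate_stream_network((64, 64), 4, seed=2)
    stack = generate_env_stack(net, seed=3)
    return net, stack


def test_snap_identity_on_river_cell(snap_scape):
    net, stack = snap_scape
    cell = net.river_cells()[10]
    rec = _record_at_cell(net, cell)
    assert snap_to_river(rec, net.river_mask, stack, 500.0) == cell


def test_snap_beyond_radius_discards(snap_scape):
    net, stack = snap_scape
    mask = net.river_mask
    rows = net.grid_shape[0]
    s = net.cell_size_km
    from riversdm.grids import cell_centers
    from scipy.spatial import cKDTree

    tree = cKDTree(cell_centers(np.argwhere(mask), rows, s))
    # find a point ~0.6 km from the nearest river cell center
    rng = np.random.default_rng(1)
    for _ in range(1000):
        x, y = rng.uniform(0, 64 * s, size=2)
        d, _ = tree.query([x, y])
        if 0.55 < d < 1.5:
            rec = make_record(lon=float(x), lat=float(y))
            assert snap_to_river(rec, mask, stack, 500.0) is None
            return
    pytest.fail("no suitable off-river test point found")


def test_snap_tie_breaks_lexicographically():
    # two river cells equidistant from a midpoint record
    specs = [(0, [(5, 4), (5, 5), (5, 6)], None), (1, [(7, 4), (7, 5), (7, 6)], None)]
    net = build_network(specs, grid_shape=(16, 16), cell_size_km=0.4)
    stack = generate_env_stack(net, seed=1)
    rows = net.grid_shape[0]
    s = net.cell_size_km
    rec = make_record(lon=(5 + 0.5) * s, lat=(rows - 6 - 0.5) * s)  # between rows 5 and 7
    assert snap_to_river(rec, net.river_mask, stack, 500.0) == (5, 5)


# --- grid sampling ----------------------------------------------------------------


def test_grid_sample_dedupes_per_cell():
    recs = [make_record(i=i, unc=100.0 * (i + 1)) for i in range(3)]
    cells, audit = grid_sample([(r, (4, 4)) for r in recs])
    assert cells == [(4, 4)]
    kept = [a for a in audit if a["disposition"] == "kept"]
    assert len(kept) == 1 and kept[0]["record_id"] == 0  # smallest uncertainty wins


def test_grid_sample_distinct_cells_unchanged():
    pairs = [(make_record(i=i), (i, i)) for i in range(5)]
    cells, _ = grid_sample(pairs)
    assert len(cells) == 5


def test_grid_sample_counts_with_known_duplicates():
    # 120 snapped records over 84 distinct cells (36 surplus duplicates)
    rng = np.random.default_rng(7)
    distinct = [(int(r), int(c)) for r, c in rng.integers(0, 60, size=(84, 2))]
    while len(set(distinct)) < 84:  # ensure distinctness
        distinct.append((int(rng.integers(60)), int(rng.integers(60))))
        distinct = list(dict.fromkeys(distinct))[:84]
    cells = distinct + [distinct[i % 84] for i in range(36)]
    pairs = [(make_record(i=i), cell) for i, cell in enumerate(cells)]
    deduped, _ = grid_sample(pairs)
    assert len(deduped) == 84


def test_grid_sample_tie_break_is_deterministic():
    a = make_record(i=1, unc=100.0, date=dt.date(2000, 1, 1), source="S02")
    b = make_record(i=2, unc=100.0, date=dt.date(2000, 1, 1), source="S01")
    _, audit = grid_sample([(a, (3, 3)), (b, (3, 3))])
    kept = [x["record_id"] for x in audit if x["disposition"] == "kept"]
    assert kept == [2]  # smaller source_id wins the tie


# --- pseudoabsences ----------------------------------------------------------------


def test_pseudoabsence_count_equals_presences():
    eligible = [(r, c) for r in range(20) for c in range(20)]
    presences = [(0, 0), (1, 1), (2, 2)]
    pseudo = generate_pseudoabsences(eligible, presences, seed=5)
    assert len(pseudo) == 3
    assert set(pseudo).isdisjoint(presences)


def test_pseudoabsence_shortfall_raises():
    with pytest.raises(CurationError, match="shortfall"):
        generate_pseudoabsences([(0, 0), (1, 1)], [(0, 0), (1, 1)], seed=5)


def test_pseudoabsence_deterministic():
    eligible = [(r, c) for r in range(30) for c in range(30)]
    presences = [(i, i) for i in range(10)]
    assert generate_pseudoabsences(eligible, presences, seed=9) == generate_pseudoabsences(
        eligible, presences, seed=9
    )
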