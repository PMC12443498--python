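"""Occurrence-record curation for presence/pseudoabsence modeling.

Raw occurrence compilations mix GBIF downloads with literature records of
very uneven quality.  Curation proceeds in stages, each with a full audit
trail (``record_id, disposition, reason``):

1. ``filter_records`` — drop records with coordinate uncertainty above a
   threshold (default 1000 m, strictly greater), an event date before a
   cutoff year (default 1990), or a reservoir/dam waterbody class.
   Records *missing* uncertainty or date are retained: literature records
   rarely carry GBIF-style metadata and only stated violations count.
2. ``classify_early_life`` — keep records attributable to spawning or
   nursing habitat: documented life-stage evidence, occurrence on a
   registered spawning river, or a Strahler order at the record's cell
   (with a 500 m pull when the cell itself carries no order) at most 4.
3. ``snap_to_river`` — move each record to the nearest river cell with
   defined environmental data within a snap radius (default 500 m).
4. ``grid_sample`` — one presence per raster cell, deterministic tie-break.
5. ``generate_pseudoabsences`` — equal count to presences, sampled
   uniformly without replacement from eligible river cells.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .errors import CurationError
from .grids import cell_centers
from .network import StreamNetwork

WATERBODY_CLASSES = ("river", "reservoir", "dam", "lake", "unknown")
EVIDENCE_VALUES = ("documented_spawning_or_nursing", "none")


@dataclass
class OccurrenceRecord:
    """One occurrence record in the abstract km coordinate plane.

    ``truth_reason`` is generator-only ground truth (why the record ought
    to be removed, or None for a clean record); the curation stages never
    read it — it exists solely so tests can verify filter behaviour.
    """

    record_id: int
    lon: float
    lat: float
    event_date: _dt.date | None
    coord_uncertainty_m: float | None
    waterbody_class: str
    life_stage_evidence: str
    source_id: str
    truth_reason: str | None = None
    early_life: bool | None = None

    def __post_init__(self):
        if not (math.isfinite(self.lon) and math.isfinite(self.lat)):
            raise CurationError(f"record {self.record_id}: non-finite coordinates")
        if self.coord_uncertainty_m is not None and self.coord_uncertainty_m < 0:
            raise CurationError(f"record {self.record_id}: negative uncertainty")
        if self.waterbody_class not in WATERBODY_CLASSES:
            raise CurationError(
                f"record {self.record_id}: unknown waterbody class {self.waterbody_class!r}"
            )


@dataclass
class CurationConfig:
    max_uncertainty_m: float = 1000.0
    min_year: int = 1990
    snap_radius_m: float = 500.0
    max_strahler: int = 4
    pull_radius_m: float = 500.0
    spawning_river_registry: list[int] = field(default_factory=list)

    def __post_init__(self):
        for name in ("max_uncertainty_m", "snap_radius_m", "pull_radius_m"):
            if getattr(self, name) <= 0:
                raise CurationError(f"{name} must be positive")
        if self.max_strahler < 1:
            raise CurationError("max_strahler must be >= 1")


@dataclass
class CuratedSet:
    presences: list[tuple[int, int]]
    pseudoabsences: list[tuple[int, int]]
    audit: list[dict]


def parse_event_date(value) -> _dt.date | None:
    """Parse ISO-8601 dates or bare years; empty/None stays None."""
    if value is None or value == "":
        return None
    if isinstance(value, _dt.date):
        return value
    s = str(value).strip()
    if len(s) == 4 and s.isdigit():
        return _dt.date(int(s), 1, 1)
    return _dt.date.fromisoformat(s)


# ---------------------------------------------------------------------------
# Stage 1: metadata filters
# ---------------------------------------------------------------------------


def filter_records(
    records: list[OccurrenceRecord], config: CurationConfig
) -> tuple[list[OccurrenceRecord], list[dict]]:
    """Drop records violating the uncertainty/date/waterbody rules.

    Each drop carries exactly one primary reason, assigned in the fixed
    order uncertainty -> date -> waterbody.  Missing uncertainty or date
    never causes a drop.
    """
    if not records:
        raise CurationError("filter_records requires a non-empty record list")
    kept: list[OccurrenceRecord] = []
    audit: list[dict] = []
    for rec in records:
        reason = None
        if (
            rec.coord_uncertainty_m is not None
            and rec.coord_uncertainty_m > config.max_uncertainty_m
        ):
            reason = "uncertainty"
        elif rec.event_date is not None and rec.event_date.year < config.min_year:
            reason = "date"
        elif rec.waterbody_class in ("reservoir", "dam"):
            reason = "waterbody"
        if reason is None:
            kept.append(rec)
            audit.append({"record_id": rec.record_id, "disposition": "kept", "reason": ""})
        else:
            audit.append(
                {"record_id": rec.record_id, "disposition": "dropped", "reason": reason}
            )
    return kept, audit


# ---------------------------------------------------------------------------
# Stage 2: early-life classification
# ---------------------------------------------------------------------------


def classify_early_life(
    records: list[OccurrenceRecord],
    network: StreamNetwork,
    config: CurationConfig,
    pull_mode: str = "nearest",
) -> tuple[list[OccurrenceRecord], list[dict]]:
    """Flag records as early-life (spawning/nursing) habitat evidence.

    A record qualifies when it has documented spawning or nursing
    evidence, lies on a segment in the spawning-river registry, or sits
    on a cell of Strahler order <= ``max_strahler``.  When the record's
    own cell carries no order, the order is pulled from river cells
    within ``pull_radius_m`` (``pull_mode``: "nearest" cell's order, or
    "max" over the radius).
    """
    if pull_mode not in ("nearest", "max"):
        raise CurationError(f"unknown pull_mode {pull_mode!r}")
    order_grid = network.strahler_grid()
    n_rows = network.grid_shape[0]
    s = network.cell_size_km
    river_cells = np.argwhere(order_grid > 0)
    registry_cells: set[tuple[int, int]] = set()
    for seg in network.segments:
        if seg.id in set(config.spawning_river_registry):
            registry_cells.update(seg.cells)
    tree = cKDTree(cell_centers(river_cells, n_rows, s)) if len(river_cells) else None

    out: list[OccurrenceRecord] = []
    audit: list[dict] = []
    pull_km = config.pull_radius_m / 1000.0
    for rec in records:
        flag = False
        reason = ""
        if rec.life_stage_evidence == "documented_spawning_or_nursing":
            flag = True
        else:
            row = int(n_rows - 1 - math.floor(rec.lat / s))
            col = int(math.floor(rec.lon / s))
            cell = (row, col)
            in_grid = 0 <= row < n_rows and 0 <= col < network.grid_shape[1]
            if in_grid and cell in registry_cells:
                flag = True
            elif in_grid and order_grid[cell] > 0:
                flag = order_grid[cell] <= config.max_strahler
                if not flag:
                    reason = "strahler_order"
            elif tree is not None:
                idx = tree.query_ball_point([rec.lon, rec.lat], r=pull_km)
                if not idx:
                    reason = "no_order_within_pull"
                else:
                    if pull_mode == "max":
                        order = max(order_grid[tuple(river_cells[i])] for i in idx)
                    else:
                        d, i = tree.query([rec.lon, rec.lat])
                        order = order_grid[tuple(river_cells[i])]
                    flag = order <= config.max_strahler
                    if not flag:
                        reason = "strahler_order"
            else:
                reason = "no_order_within_pull"
        flag = bool(flag)
        out.append(replace(rec, early_life=flag))
        audit.append(
            {
                "record_id": rec.record_id,
                "disposition": "kept" if flag else "dropped",
                "reason": reason,
            }
        )
    return out, audit


# ---------------------------------------------------------------------------
# Stage 3: river snapping
# ---------------------------------------------------------------------------


def snap_to_river(
    record: OccurrenceRecord,
    river_mask: np.ndarray,
    env_stack,
    snap_radius_m: float,
) -> tuple[int, int] | None:
    """Nearest river cell with defined environmental data within the radius.

    Returns the (row, col) cell or None (unsnappable).  Distance is
    Euclidean in the equal-area km plane; exact ties break to the
    lexicographically smallest (row, col).
    """
    if snap_radius_m <= 0:
        raise CurationError("snap_radius_m must be positive")
    eligible = river_mask & env_stack.defined_mask()
    cells = np.argwhere(eligible)
    if len(cells) == 0:
        return None
    n_rows = river_mask.shape[0]
    centers = cell_centers(cells, n_rows, env_stack.cell_size_km)
    d = np.hypot(centers[:, 0] - record.lon, centers[:, 1] - record.lat)
    radius_km = snap_radius_m / 1000.0
    within = d <= radius_km + 1e-12
    if not within.any():
        return None
    dmin = d[within].min()
    tied = cells[within][np.abs(d[within] - dmin) <= 1e-9]
    best = min(map(tuple, tied.tolist()))
    return (int(best[0]), int(best[1]))


def snap_records(
    records: list[OccurrenceRecord],
    river_mask: np.ndarray,
    env_stack,
    snap_radius_m: float,
) -> tuple[list[tuple[OccurrenceRecord, tuple[int, int]]], list[dict]]:
    """Snap all records; unsnappable ones are discarded with an audit entry."""
    snapped = []
    audit = []
    for rec in records:
        cell = snap_to_river(rec, river_mask, env_stack, snap_radius_m)
        if cell is None:
            audit.append(
                {"record_id": rec.record_id, "disposition": "dropped", "reason": "unsnappable"}
            )
        else:
            snapped.append((rec, cell))
            audit.append(
                {
                    "record_id": rec.record_id,
                    "disposition": "kept",
                    "reason": "",
                    "snapped_row": cell[0],
                    "snapped_col": cell[1],
                }
            )
    return snapped, audit


# ---------------------------------------------------------------------------
# Stage 4: grid sampling (deduplication to raster resolution)
# ---------------------------------------------------------------------------


def grid_sample(
    snapped: list[tuple[OccurrenceRecord, tuple[int, int]]]
) -> tuple[list[tuple[int, int]], list[dict]]:
    """At most one presence per grid cell.

    The surviving record per cell is the one with the smallest coordinate
    uncertainty (missing sorts last), then the earliest event date
    (missing sorts last), then the smallest source_id, then record_id —
    a total order, so the result is deterministic.
    """

    def sort_key(item):
        rec, _ = item
        unc = rec.coord_uncertainty_m if rec.coord_uncertainty_m is not None else math.inf
        date = rec.event_date.toordinal() if rec.event_date is not None else math.inf
        return (unc, date, rec.source_id, rec.record_id)

    winners: dict[tuple[int, int], OccurrenceRecord] = {}
    for rec, cell in sorted(snapped, key=sort_key):
        winners.setdefault(cell, rec)
    kept_ids = {rec.record_id for rec in winners.values()}
    audit = []
    for rec, cell in snapped:
        kept = rec.record_id in kept_ids
        audit.append(
            {
                "record_id": rec.record_id,
                "disposition": "kept" if kept else "dropped",
                "reason": "" if kept else "duplicate_cell",
            }
        )
    return sorted(winners.keys()), audit


# ---------------------------------------------------------------------------
# Stage 5: pseudoabsences
# ---------------------------------------------------------------------------


def generate_pseudoabsences(
    river_cells_with_env: list[tuple[int, int]],
    presences: list[tuple[int, int]],
    seed: int,
) -> list[tuple[int, int]]:
    """Sample |presences| background cells uniformly without replacement
    from river cells with environmental data, excluding presence cells.
    """
    presence_set = set(map(tuple, presences))
    eligible = sorted(set(map(tuple, river_cells_with_env)) - presence_set)
    n = len(presences)
    if len(eligible) < n:
        raise CurationError(
            f"too few eligible pseudoabsence cells: need {n}, have {len(eligible)} "
            f"(shortfall {n - len(eligible)})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in sorted(idx.tolist())]


# ---------------------------------------------------------------------------
# Full curation pipeline
# ---------------------------------------------------------------------------


def curate(
    records: list[OccurrenceRecord],
    network: StreamNetwork,
    env_stack,
    config: CurationConfig,
    seed: int,
) -> CuratedSet:
    """Run all curation stages and assemble the audit trail."""
    kept, audit = filter_records(records, config)
    for row in audit:
        row["stage"] = "filter"
    classified, a2 = classify_early_life(kept, network, config)
    for row in a2:
        row["stage"] = "classify"
    audit += a2
    early = [r for r in classified if r.early_life]
    snapped, a3 = snap_records(early, network.river_mask, env_stack, config.snap_radius_m)
    for row in a3:
        row["stage"] = "snap"
    audit += a3
    presences, a4 = grid_sample(snapped)
    for row in a4:
        row["stage"] = "grid_sample"
    audit += a4
    eligible = [
        c
        for c in network.river_cells()
        if env_stack.defined_mask()[c]
    ]
    pseudo = generate_pseudoabsences(eligible, presences, seed)
    return CuratedSet(presences=presences, pseudoabsences=pseudo, audit=audit)
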