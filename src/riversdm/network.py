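"""Dendritic stream networks on a raster grid.

A :class:`StreamNetwork` is a forest of :class:`StreamSegment` reaches
directed downstream.  Segments are maximal 8-connected cell paths between
confluences; the confluence cell itself belongs to the receiving
(downstream) segment.  Strahler stream order follows the standard rule:
headwater reaches are order 1, and the order increases by one at a
confluence only when the maximum upstream order arrives at least twice.

The synthetic generator grows each tributary as a persistent-heading
meandering random walk from a headwater source toward the basin outlet,
joining the first existing river cell it touches.  The resulting flow
graph is a tree by construction (every walk either reaches the outlet or
grafts onto cells that already drain to it), which keeps flow-length and
Strahler computations exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import NetworkCycleError, NetworkError

# 8-neighbourhood in (drow, dcol); order fixed for determinism
DIRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

SQRT2 = math.sqrt(2.0)


def step_length_km(a: tuple[int, int], b: tuple[int, int], cell_size_km: float) -> float:
    """Distance between the centers of two 8-adjacent cells."""
    if a[0] != b[0] and a[1] != b[1]:
        return cell_size_km * SQRT2
    return cell_size_km


@dataclass
class StreamSegment:
    """A river reach: an ordered 8-connected cell path between confluences.

    ``cells`` run upstream -> downstream.  ``upstream_ids`` are the ids of
    segments whose last cell flows into this segment's head cell;
    headwater segments have none and carry Strahler order 1.
    """

    id: int
    upstream_ids: list[int]
    cells: list[tuple[int, int]]
    strahler: int | None = None
    length_km: float = 0.0
    downstream_id: int | None = None


@dataclass
class StreamNetwork:
    segments: list[StreamSegment]
    grid_shape: tuple[int, int]
    cell_size_km: float
    river_mask: np.ndarray = field(repr=False)
    flow: dict[tuple[int, int], tuple[int, int]] = field(repr=False)

    @classmethod
    def from_segments(
        cls,
        segments: list[StreamSegment],
        grid_shape: tuple[int, int],
        cell_size_km: float,
    ) -> "StreamNetwork":
        """Rebuild mask and per-cell flow directions from the segment list."""
        mask = np.zeros(grid_shape, dtype=bool)
        flow: dict[tuple[int, int], tuple[int, int]] = {}
        by_id = {s.id: s for s in segments}
        for seg in segments:
            for cell in seg.cells:
                mask[cell] = True
            for a, b in zip(seg.cells[:-1], seg.cells[1:]):
                flow[a] = b
            if seg.downstream_id is not None:
                down = by_id.get(seg.downstream_id)
                if down is None:
                    raise NetworkError(
                        f"segment {seg.id} flows into missing segment {seg.downstream_id}"
                    )
                flow[seg.cells[-1]] = down.cells[0]
        return cls(segments, grid_shape, cell_size_km, mask, flow)

    # -- convenience views -------------------------------------------------

    def segment_by_id(self, seg_id: int) -> StreamSegment:
        for seg in self.segments:
            if seg.id == seg_id:
                return seg
        raise NetworkError(f"no segment with id {seg_id}")

    def strahler_grid(self) -> np.ndarray:
        """Integer grid of Strahler orders per river cell (0 off-river)."""
        grid = np.zeros(self.grid_shape, dtype=int)
        for seg in self.segments:
            if seg.strahler is None:
                raise NetworkError("strahler orders not computed")
            for cell in seg.cells:
                grid[cell] = seg.strahler
        return grid

    def river_cells(self) -> list[tuple[int, int]]:
        """River cells in raster-scan order."""
        rows, cols = np.nonzero(self.river_mask)
        return list(zip(rows.tolist(), cols.tolist()))

    # -- serialization -----------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "grid_shape": list(self.grid_shape),
            "cell_size_km": self.cell_size_km,
            "segments": [
                {
                    "id": s.id,
                    "upstream_ids": s.upstream_ids,
                    "cells": [list(c) for c in s.cells],
                    "strahler": s.strahler,
                    "length_km": s.length_km,
                    "downstream_id": s.downstream_id,
                }
                for s in self.segments
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "StreamNetwork":
        with open(path) as fh:
            payload = json.load(fh)
        segments = [
            StreamSegment(
                id=s["id"],
                upstream_ids=list(s["upstream_ids"]),
                cells=[tuple(c) for c in s["cells"]],
                strahler=s["strahler"],
                length_km=s["length_km"],
                downstream_id=s["downstream_id"],
            )
            for s in payload["segments"]
        ]
        return cls.from_segments(
            segments, tuple(payload["grid_shape"]), payload["cell_size_km"]
        )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate_stream_network(
    grid_shape: tuple[int, int],
    n_sources: int,
    seed: int,
    meander: float = 0.55,
    cell_size_km: float = 0.45,
) -> StreamNetwork:
    """Grow a seed-controlled dendritic network draining to a grid-edge outlet.

    Parameters
    ----------
    grid_shape
        (rows, cols), at least 32 x 32.
    n_sources
        Number of headwater sources; each grows one tributary walk.
    seed
        Seed for all randomness; identical seeds give identical networks.
    meander
        0..1, how strongly walks persist in their heading instead of
        heading straight for the outlet; higher values give longer,
        more sinuous channels (and therefore larger upstream flow lengths).
    cell_size_km
        Grid cell edge length; default 0.45 km (~15 arc-sec at the equator).
    """
    rows, cols = grid_shape
    if rows < 32 or cols < 32:
        raise NetworkError(f"grid_shape must be at least 32x32, got {grid_shape}")
    if n_sources < 1:
        raise NetworkError("n_sources must be >= 1")
    capacity = (rows * cols) // 200
    if n_sources > max(1, capacity):
        raise NetworkError(
            f"infeasible growth: {n_sources} sources exceed capacity "
            f"{max(1, capacity)} for a {rows}x{cols} grid"
        )

    rng = np.random.default_rng(seed)
    outlet = _random_edge_cell(rng, rows, cols)

    flow: dict[tuple[int, int], tuple[int, int]] = {}
    occupied: set[tuple[int, int]] = set()

    diag = math.hypot(rows, cols)
    max_steps = 60 * (rows + cols)

    for i in range(n_sources):
        placed = False
        for _attempt in range(200):
            src = (int(rng.integers(2, rows - 2)), int(rng.integers(2, cols - 2)))
            if i == 0:
                # first channel spans the basin: source far from the outlet
                if math.hypot(src[0] - outlet[0], src[1] - outlet[1]) < 0.55 * diag:
                    continue
                target_set: set[tuple[int, int]] = set()
            else:
                # later sources must start clear of the existing river
                if any(
                    max(abs(src[0] - c[0]), abs(src[1] - c[1])) < 8 for c in occupied
                ):
                    continue
                target_set = occupied
            path = _meander_walk(rng, src, outlet, target_set, grid_shape, meander, max_steps)
            if path is None:
                continue
            for a, b in zip(path[:-1], path[1:]):
                flow[a] = b
            occupied.update(path[:-1])
            occupied.add(path[-1])
            placed = True
            break
        if not placed:
            raise NetworkError(
                f"infeasible growth: could not place source {i + 1} of {n_sources} "
                f"on a {rows}x{cols} grid"
            )

    segments = _segments_from_flow(flow)
    network = StreamNetwork.from_segments(segments, grid_shape, cell_size_km)
    network = compute_strahler_orders(network)
    _set_segment_lengths(network)
    return network


def _random_edge_cell(rng, rows: int, cols: int) -> tuple[int, int]:
    side = int(rng.integers(4))
    if side == 0:
        return (0, int(rng.integers(cols)))
    if side == 1:
        return (rows - 1, int(rng.integers(cols)))
    if side == 2:
        return (int(rng.integers(rows)), 0)
    return (int(rng.integers(rows)), cols - 1)


def _meander_walk(
    rng,
    start: tuple[int, int],
    outlet: tuple[int, int],
    join_cells: set[tuple[int, int]],
    grid_shape: tuple[int, int],
    meander: float,
    max_steps: int,
):
    """Self-avoiding persistent walk from ``start`` toward ``outlet``.

    Terminates on reaching the outlet or the first cell in ``join_cells``
    (an existing river cell — a confluence).  Returns the cell path or
    None if the walk trapped itself or exceeded the step cap.
    """
    rows, cols = grid_shape
    path = [start]
    path_set = {start}
    cur = start
    # initial heading: toward the outlet
    heading = _toward(start, outlet)
    goal0 = 0.25 * (1.0 - meander) + 0.08

    for step in range(max_steps):
        # goal attraction ramps up so the walk cannot wander forever
        goal = goal0 * (1.0 + 3.0 * step / max_steps)
        dist_cur = math.hypot(cur[0] - outlet[0], cur[1] - outlet[1])
        cands = []
        weights = []
        for d in DIRS:
            nxt = (cur[0] + d[0], cur[1] + d[1])
            if not (0 <= nxt[0] < rows and 0 <= nxt[1] < cols):
                continue
            if nxt in path_set:
                continue
            t = _turn_steps(d, heading)
            persist = (3.0, 1.4, 0.35, 0.05, 0.05)[t]
            dn = math.hypot(nxt[0] - outlet[0], nxt[1] - outlet[1])
            w = persist * math.exp(-goal * (dn - dist_cur))
            cands.append((d, nxt))
            weights.append(w)
        if not cands:
            return None
        w = np.asarray(weights)
        idx = int(rng.choice(len(cands), p=w / w.sum()))
        heading, cur = cands[idx]
        path.append(cur)
        path_set.add(cur)
        if cur == outlet or cur in join_cells:
            return path
    return None


_ANGLES = {d: math.atan2(d[0], d[1]) for d in DIRS}


def _turn_steps(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Number of 45-degree steps between two of the 8 headings (0..4)."""
    da = _ANGLES[a] - _ANGLES[b]
    k = round(abs((da + math.pi) % (2 * math.pi) - math.pi) / (math.pi / 4))
    return int(k)


def _toward(a: tuple[int, int], b: tuple[int, int]) -> tuple[int, int]:
    dr = int(np.sign(b[0] - a[0]))
    dc = int(np.sign(b[1] - a[1]))
    if (dr, dc) == (0, 0):
        return (0, 1)
    return (dr, dc)


def _segments_from_flow(
    flow: dict[tuple[int, int], tuple[int, int]]
) -> list[StreamSegment]:
    """Partition a cell-level flow tree into between-confluence segments."""
    cells = set(flow.keys()) | set(flow.values())
    n_up: dict[tuple[int, int], int] = {c: 0 for c in cells}
    for _, d in flow.items():
        n_up[d] += 1
    sources = sorted(c for c in cells if n_up[c] == 0)
    junctions = {c for c in cells if n_up[c] >= 2}
    heads = sorted(set(sources) | junctions)

    segments: list[StreamSegment] = []
    head_to_id = {h: i for i, h in enumerate(heads)}
    for h in heads:
        seg_cells = [h]
        cur = h
        while True:
            nxt = flow.get(cur)
            if nxt is None:
                break
            if nxt in junctions:
                break
            seg_cells.append(nxt)
            cur = nxt
        nxt = flow.get(cur)
        downstream_id = head_to_id[nxt] if nxt is not None else None
        segments.append(
            StreamSegment(
                id=head_to_id[h],
                upstream_ids=[],
                cells=seg_cells,
                downstream_id=downstream_id,
            )
        )
    by_id = {s.id: s for s in segments}
    for seg in segments:
        if seg.downstream_id is not None:
            by_id[seg.downstream_id].upstream_ids.append(seg.id)
    for seg in segments:
        seg.upstream_ids.sort()
    return segments


def _set_segment_lengths(network: StreamNetwork) -> None:
    by_id = {s.id: s for s in network.segments}
    for seg in network.segments:
        length = sum(
            step_length_km(a, b, network.cell_size_km)
            for a, b in zip(seg.cells[:-1], seg.cells[1:])
        )
        if seg.downstream_id is not None:
            down_head = by_id[seg.downstream_id].cells[0]
            length += step_length_km(seg.cells[-1], down_head, network.cell_size_km)
        seg.length_km = length


# ---------------------------------------------------------------------------
# Strahler orders, pruning, flow length
# ---------------------------------------------------------------------------


def compute_strahler_orders(network: StreamNetwork) -> StreamNetwork:
    """Assign Strahler orders over the segment forest (in place; returns it).

    Headwaters get order 1.  At a confluence the receiving segment takes
    the maximum upstream order, plus one when that maximum arrives from
    at least two tributaries.  Raises :class:`NetworkCycleError` if the
    graph is not a downstream-directed forest.
    """
    by_id = {s.id: s for s in network.segments}
    pending = {s.id: len(s.upstream_ids) for s in network.segments}
    ready = [sid for sid, n in pending.items() if n == 0]
    processed = 0
    while ready:
        sid = ready.pop()
        seg = by_id[sid]
        if not seg.upstream_ids:
            seg.strahler = 1
        else:
            ups = [by_id[u].strahler for u in seg.upstream_ids]
            top = max(ups)
            seg.strahler = top + 1 if ups.count(top) >= 2 else top
        processed += 1
        if seg.downstream_id is not None:
            pending[seg.downstream_id] -= 1
            if pending[seg.downstream_id] == 0:
                ready.append(seg.downstream_id)
    if processed != len(network.segments):
        raise NetworkCycleError("cycle detected in segment graph")
    return network


def prune_order1_adjacent(network: StreamNetwork, max_partner_order: int = 2) -> StreamNetwork:
    """Drop order-1 tributaries that feed directly into high-order reaches.

    An order-1 segment is removed when its receiving segment, or any other
    tributary at the same confluence, has Strahler order greater than
    ``max_partner_order`` (default 2).  Orders of surviving segments are
    left untouched.
    """
    by_id = {s.id: s for s in network.segments}
    drop: set[int] = set()
    for seg in network.segments:
        if seg.strahler != 1 or seg.downstream_id is None:
            continue
        down = by_id[seg.downstream_id]
        partners = [by_id[u] for u in down.upstream_ids if u != seg.id]
        if down.strahler > max_partner_order or any(
            p.strahler > max_partner_order for p in partners
        ):
            drop.add(seg.id)
    kept = []
    for seg in network.segments:
        if seg.id in drop:
            continue
        new = StreamSegment(
            id=seg.id,
            upstream_ids=[u for u in seg.upstream_ids if u not in drop],
            cells=list(seg.cells),
            strahler=seg.strahler,
            length_km=seg.length_km,
            downstream_id=seg.downstream_id,
        )
        kept.append(new)
    return StreamNetwork.from_segments(kept, network.grid_shape, network.cell_size_km)


def flow_length_upstream(network: StreamNetwork) -> np.ndarray:
    """Along-network distance (km) from each river cell to its furthest
    upstream source; 0 at headwater source cells, NaN off-river.
    """
    cells = set(network.flow.keys()) | set(network.flow.values())
    for seg in network.segments:
        cells.update(seg.cells)
    n_up: dict[tuple[int, int], int] = {c: 0 for c in cells}
    for _, d in network.flow.items():
        n_up[d] += 1
    hyd = {c: 0.0 for c in cells}
    ready = [c for c in cells if n_up[c] == 0]
    processed = 0
    while ready:
        c = ready.pop()
        processed += 1
        d = network.flow.get(c)
        if d is None:
            continue
        cand = hyd[c] + step_length_km(c, d, network.cell_size_km)
        if cand > hyd[d]:
            hyd[d] = cand
        n_up[d] -= 1
        if n_up[d] == 0:
            ready.append(d)
    if processed != len(cells):
        raise NetworkCycleError("cycle detected in cell flow graph")
    grid = np.full(network.grid_shape, np.nan)
    for c, v in hyd.items():
        grid[c] = v
    return grid
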