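"""Synthetic riverscapes with known ground truth.

This module manufactures everything the pipeline needs — environmental
layers over a dendritic river network, a known trapezoidal suitability
envelope, contaminated occurrence samples, and protected-area context —
so that curation, modeling, prioritization, and accounting can all be
tested against a truth the generator controls.

The environmental stack carries the five predictors used for early-life
habitat modeling of Himalayan river fish:

====== ================================================== ==============
name   meaning                                            units
====== ================================================== ==============
hyd    flow length to the furthest upstream source        km
hft    human footprint in the reach catchment             index 0..~480
sgr    stream gradient (elevation drop over reach length) decimeter/km
bio10  mean temperature of the warmest quarter            deg C
bio16  precipitation of the wettest quarter               mm
====== ================================================== ==============

``hyd`` is computed *exactly* as the along-network distance to the
furthest upstream source.  ``sgr`` derives from a synthetic elevation
field that decreases monotonically downstream (steep lognormal headwater
gradients relaxing toward the outlet).  ``bio10`` follows elevation with
a lapse-like decline plus smooth spatial structure and noise; ``bio16``
and ``hft`` are smooth gradients and clustered hotspots respectively and
are deliberately non-informative for the species, giving a negative
control for variable-importance checks.

True suitability is the product of per-variable trapezoid memberships
over ``hyd``, ``sgr`` and ``bio10`` only, so its >0.9 region has
analytically known bounds.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import MultiPolygon, Point, Polygon, box
from shapely.ops import unary_union

from .curation import OccurrenceRecord
from .errors import SyntheticDataError
from .grids import cell_centers
from .network import StreamNetwork, flow_length_upstream

VARIABLE_NAMES = ("hyd", "hft", "sgr", "bio10", "bio16")

#: Variable ranges the generated stack is confined to (value spans observed
#: across the species' whole range): hyd km, hft index, sgr dm/km,
#: bio10 deg C, bio16 mm.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "hyd": (0.0, 3211.570),
    "hft": (0.0, 482.0),
    "sgr": (0.0, 9108.0),
    "bio10": (-8.93, 34.83),
    "bio16": (85.0, 6051.188),
}


# ---------------------------------------------------------------------------
# Environmental stack
# ---------------------------------------------------------------------------


@dataclass
class EnvStack:
    """Aligned environmental rasters, defined only on river cells (NaN off)."""

    variables: dict[str, np.ndarray]
    grid_shape: tuple[int, int]
    cell_size_km: float
    ranges: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_RANGES))

    def __post_init__(self):
        for name, grid in self.variables.items():
            if grid.shape != tuple(self.grid_shape):
                raise SyntheticDataError(f"variable {name} shape mismatch")

    def defined_mask(self) -> np.ndarray:
        mask = None
        for grid in self.variables.values():
            m = np.isfinite(grid)
            mask = m if mask is None else (mask & m)
        return mask

    def values_at(self, cells) -> dict[str, np.ndarray]:
        cells = np.asarray(cells)
        rows, cols = cells[:, 0], cells[:, 1]
        return {name: grid[rows, cols] for name, grid in self.variables.items()}


def _smooth_field(rng, shape: tuple[int, int], n_waves: int = 4) -> np.ndarray:
    """Smooth random field in [0, 1]: a few random plane sinusoids."""
    rows, cols = shape
    r = np.arange(rows)[:, None] / rows
    c = np.arange(cols)[None, :] / cols
    f = np.zeros(shape)
    for _ in range(n_waves):
        kr, kc = rng.uniform(0.5, 3.0, size=2) * rng.choice([-1, 1], size=2)
        phase = rng.uniform(0, 2 * math.pi)
        f += rng.uniform(0.5, 1.0) * np.sin(2 * math.pi * (kr * r + kc * c) + phase)
    f -= f.min()
    if f.max() > 0:
        f /= f.max()
    return f


def generate_env_stack(
    network: StreamNetwork,
    ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> EnvStack:
    """Generate the five-variable stack on the network's river cells."""
    ranges = dict(DEFAULT_RANGES if ranges is None else ranges)
    for name, (lo, hi) in ranges.items():
        if lo >= hi:
            raise SyntheticDataError(f"range for {name} has lo >= hi: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    shape = network.grid_shape
    mask = network.river_mask
    cells = network.river_cells()
    s = network.cell_size_km

    # hyd: exact along-network distance to the furthest upstream source
    hyd = flow_length_upstream(network)

    # sgr: stationary lognormal gradients, autocorrelated along the network
    # (Ornstein-Uhlenbeck on log sgr, correlation length ~15 km) so reaches
    # are locally smooth but sgr carries no systematic trend with hyd; the
    # median (600 dm/km) sits above the species' preferred gradients, making
    # suitable habitat a scarce resource (<10% of river cells)
    sgr = _sgr_along_network(network, rng, mu=math.log(600.0), sigma=0.8, corr_km=15.0)

    # elevation (dm): integrate gradients upstream from each outlet so the
    # field decreases monotonically downstream
    elev = _integrate_elevation(network, sgr)

    emax = np.nanmax(elev)
    e01 = elev / emax if emax > 0 else elev

    smooth_t = _smooth_field(rng, shape)
    bio10 = np.full(shape, np.nan)
    bio16 = np.full(shape, np.nan)
    for r, c in cells:
        bio10[r, c] = 29.2 - 5.0 * e01[r, c] + 0.8 * (smooth_t[r, c] - 0.5) + rng.normal(0, 0.3)

    smooth_p = _smooth_field(rng, shape)
    for r, c in cells:
        bio16[r, c] = 500.0 + 2200.0 * smooth_p[r, c] + rng.normal(0, 90.0)

    # hft: clustered hotspots (settlement/road pressure), zero baseline
    hft = np.full(shape, np.nan)
    n_spots = max(6, len(cells) // 400)
    centers = rng.integers(0, min(shape), size=(n_spots, 2)).astype(float)
    amps = rng.uniform(40, 260, size=n_spots)
    widths = rng.uniform(4, 14, size=n_spots)
    cells_arr = np.asarray(cells, dtype=float)
    vals = np.zeros(len(cells))
    for k in range(n_spots):
        d2 = ((cells_arr - centers[k]) ** 2).sum(axis=1)
        vals += amps[k] * np.exp(-d2 / (2 * widths[k] ** 2))
    vals += rng.uniform(0, 8, size=len(cells))
    for (r, c), v in zip(cells, vals):
        hft[r, c] = v

    grids = {"hyd": hyd, "hft": hft, "sgr": sgr, "bio10": bio10, "bio16": bio16}
    for name, grid in grids.items():
        lo, hi = ranges[name]
        np.clip(grid, lo, hi, out=grid)
        grid[~mask] = np.nan
    return EnvStack(grids, shape, s, ranges)


def _sgr_along_network(
    network: StreamNetwork,
    rng,
    mu: float,
    sigma: float,
    corr_km: float,
) -> np.ndarray:
    """Stream gradient: exp of an Ornstein-Uhlenbeck process propagated
    downstream cell by cell, so gradients vary smoothly within reaches but
    are stationary over the network (no trend with flow length).

    At a confluence the downstream value continues from the tributary with
    the larger upstream flow length (the main stem).
    """
    from .network import step_length_km

    hyd = flow_length_upstream(network)
    cells = set(network.flow.keys()) | set(network.flow.values())
    for seg in network.segments:
        cells.update(seg.cells)
    n_up: dict[tuple[int, int], int] = {c: 0 for c in cells}
    for _, d in network.flow.items():
        n_up[d] += 1
    # draw per-cell innovations in scan order for determinism
    sorted_cells = sorted(cells)
    z = {c: rng.normal() for c in sorted_cells}
    log_sgr: dict[tuple[int, int], float] = {}
    best_up: dict[tuple[int, int], tuple[int, int]] = {}
    ready = [c for c in sorted_cells if n_up[c] == 0]
    while ready:
        c = ready.pop()
        up = best_up.get(c)
        if up is None:
            log_sgr[c] = mu + sigma * z[c]
        else:
            step = step_length_km(up, c, network.cell_size_km)
            phi = math.exp(-step / corr_km)
            log_sgr[c] = mu + phi * (log_sgr[up] - mu) + sigma * math.sqrt(1 - phi**2) * z[c]
        d = network.flow.get(c)
        if d is not None:
            prev = best_up.get(d)
            if prev is None or hyd[c] > hyd[prev]:
                best_up[d] = c
            n_up[d] -= 1
            if n_up[d] == 0:
                ready.append(d)
    out = np.full(network.grid_shape, np.nan)
    for c, v in log_sgr.items():
        out[c] = math.exp(v)
    return out


def _integrate_elevation(network: StreamNetwork, sgr: np.ndarray) -> np.ndarray:
    """Elevation (dm) rising upstream: outlet at 0, each step adds the cell's
    gradient times the step length, so elevation strictly decreases downstream."""
    from .network import step_length_km

    cells = set()
    for seg in network.segments:
        cells.update(seg.cells)
    downstream = network.flow
    elev_map: dict[tuple[int, int], float] = {}

    def elev_of(c):
        # iterative walk to the outlet, then fill back
        chain = []
        cur = c
        while cur not in elev_map:
            chain.append(cur)
            nxt = downstream.get(cur)
            if nxt is None:
                elev_map[cur] = 0.0
                break
            cur = nxt
        for cell in reversed(chain):
            nxt = downstream.get(cell)
            if nxt is None:
                elev_map[cell] = 0.0
            else:
                step = step_length_km(cell, nxt, network.cell_size_km)
                elev_map[cell] = elev_map[nxt] + sgr[cell] * step
        return elev_map[c]

    out = np.full(network.grid_shape, np.nan)
    for c in cells:
        out[c] = elev_of(c)
    return out


# ---------------------------------------------------------------------------
# Suitability envelope (the ground truth the pipeline must recover)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Trapezoid:
    """Trapezoidal membership: 0 outside [lo_zero, hi_zero], 1 on
    [lo_high, hi_high], linear on the ramps."""

    lo_zero: float
    lo_high: float
    hi_high: float
    hi_zero: float

    def __post_init__(self):
        if not (self.lo_zero <= self.lo_high <= self.hi_high <= self.hi_zero):
            raise SyntheticDataError(f"trapezoid bounds out of order: {self}")

    def membership(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        if self.lo_high > self.lo_zero:
            ramp = (x - self.lo_zero) / (self.lo_high - self.lo_zero)
            out = np.where((x >= self.lo_zero) & (x < self.lo_high), ramp, out)
        out = np.where((x >= self.lo_high) & (x <= self.hi_high), 1.0, out)
        if self.hi_zero > self.hi_high:
            ramp = (self.hi_zero - x) / (self.hi_zero - self.hi_high)
            out = np.where((x > self.hi_high) & (x <= self.hi_zero), ramp, out)
        return float(out) if out.ndim == 0 else out


#: Known high-suitability envelope for early-life habitat: flow length
#: plateau 63-147 km ramping out at 21 and 210 km; stream gradient plateau
#: 120-270 dm/km ramping out at 40 and 320; warmest-quarter temperature
#: plateau 26.9-28.7 degC ramping out at 25.5 and 29.7.  hft and bio16 are
#: intentionally absent (non-informative negative controls).
DEFAULT_ENVELOPE: dict[str, Trapezoid] = {
    "hyd": Trapezoid(21.0, 63.0, 147.0, 210.0),
    "sgr": Trapezoid(40.0, 120.0, 270.0, 320.0),
    "bio10": Trapezoid(25.5, 26.9, 28.7, 29.7),
}


def true_suitability(env_values: dict, envelope: dict[str, Trapezoid] | None = None):
    """Product of per-variable trapezoid memberships (scalar or array)."""
    envelope = DEFAULT_ENVELOPE if envelope is None else envelope
    out = None
    for name, trap in envelope.items():
        if name not in env_values:
            raise SyntheticDataError(f"missing variable {name!r} for suitability")
        m = trap.membership(env_values[name])
        out = m if out is None else out * m
    return out


def suitability_grid(stack: EnvStack, envelope: dict[str, Trapezoid] | None = None) -> np.ndarray:
    """Truth suitability on every river cell (NaN off-river)."""
    envelope = DEFAULT_ENVELOPE if envelope is None else envelope
    values = {name: stack.variables[name] for name in envelope}
    with np.errstate(invalid="ignore"):
        grid = true_suitability(values, envelope)
    return grid


# ---------------------------------------------------------------------------
# Occurrence sampling with controlled contamination
# ---------------------------------------------------------------------------


@dataclass
class Contamination:
    """Fractions of records seeded with each curatable defect.

    ``off_river`` records are displaced beyond the snap radius so the
    snapping stage must discard them; displacement magnitude is drawn in
    [off_river_min_m, off_river_max_m].
    """

    uncertain: float = 0.0
    old_date: float = 0.0
    reservoir: float = 0.0
    off_river: float = 0.0
    off_river_min_m: float = 550.0
    off_river_max_m: float = 1500.0

    def total(self) -> float:
        return self.uncertain + self.old_date + self.reservoir + self.off_river


def sample_occurrences(
    network: StreamNetwork,
    suitability: np.ndarray,
    n: int,
    contamination: Contamination,
    seed: int,
    evidence_fraction: float = 0.3,
    snap_radius_m: float = 500.0,
) -> list[OccurrenceRecord]:
    """Draw presences proportional to suitability, then contaminate.

    Contaminated records carry ``truth_reason`` ground truth naming the
    stage that should remove them; clean records have ``truth_reason``
    None.  Deterministic for a fixed seed.
    """
    if n < 1:
        raise SyntheticDataError("n must be >= 1")
    if contamination.total() > 1.0 + 1e-9:
        raise SyntheticDataError("contamination fractions sum to more than 1")
    rng = np.random.default_rng(seed)
    mask = network.river_mask
    weights = np.where(mask & np.isfinite(suitability), suitability, 0.0)
    total = weights.sum()
    if total <= 0:
        raise SyntheticDataError("no river cell has positive suitability")
    flat_idx = np.flatnonzero(weights.ravel())
    p = weights.ravel()[flat_idx] / total
    draws = rng.choice(len(flat_idx), size=n, p=p, replace=True)
    rows, cols = np.unravel_index(flat_idx[draws], mask.shape)

    n_rows = mask.shape[0]
    s = network.cell_size_km
    centers = cell_centers(np.column_stack([rows, cols]), n_rows, s)
    jitter = rng.uniform(-0.2 * s, 0.2 * s, size=(n, 2))
    xy = centers + jitter

    # disjoint contamination classes
    order = rng.permutation(n)
    counts = {
        "uncertainty": round(contamination.uncertain * n),
        "date": round(contamination.old_date * n),
        "waterbody": round(contamination.reservoir * n),
        "unsnappable": round(contamination.off_river * n),
    }
    labels = [None] * n
    pos = 0
    for reason, k in counts.items():
        for i in order[pos : pos + k]:
            labels[i] = reason
        pos += k

    river_centers = cell_centers(np.argwhere(mask), n_rows, s)
    tree = cKDTree(river_centers)

    records = []
    for i in range(n):
        reason = labels[i]
        x, y = float(xy[i, 0]), float(xy[i, 1])
        if reason == "uncertainty":
            unc = float(rng.uniform(1001.0, 5000.0))
        else:
            unc = float(rng.uniform(10.0, 900.0)) if rng.random() < 0.7 else None
        if reason == "date":
            year = int(rng.integers(1950, 1990))
        else:
            year = int(rng.integers(1990, 2023)) if rng.random() < 0.85 else None
        date = (
            _dt.date(year, int(rng.integers(1, 13)), int(rng.integers(1, 29)))
            if year is not None
            else None
        )
        if reason == "waterbody":
            wb = "reservoir" if rng.random() < 0.5 else "dam"
        else:
            wb = "river" if rng.random() < 0.9 else "unknown"
        if reason == "unsnappable":
            x, y = _displace_off_river(rng, x, y, tree, contamination, snap_radius_m)
        evidence = (
            "documented_spawning_or_nursing" if rng.random() < evidence_fraction else "none"
        )
        records.append(
            OccurrenceRecord(
                record_id=i,
                lon=x,
                lat=y,
                event_date=date,
                coord_uncertainty_m=unc,
                waterbody_class=wb,
                life_stage_evidence=evidence,
                source_id=f"S{int(rng.integers(1, 17)):02d}",
                truth_reason=reason,
            )
        )
    return records


def _displace_off_river(rng, x, y, tree, contamination, snap_radius_m, max_tries=100):
    """Move a point so no river cell center lies within the snap radius."""
    radius_km = snap_radius_m / 1000.0
    lo = contamination.off_river_min_m / 1000.0
    hi = contamination.off_river_max_m / 1000.0
    for attempt in range(max_tries):
        theta = rng.uniform(0, 2 * math.pi)
        mag = rng.uniform(lo, hi) * (1.0 + attempt / 10.0)
        nx, ny = x + mag * math.cos(theta), y + mag * math.sin(theta)
        d, _ = tree.query([nx, ny])
        if d > radius_km * 1.05:
            return nx, ny
    raise SyntheticDataError("could not displace record off-river")


# ---------------------------------------------------------------------------
# Context layers: protected areas, river polygons, villages, regions
# ---------------------------------------------------------------------------


@dataclass
class ProtectedAreaSet:
    polygons: list[Polygon]
    region_labels: list[str]

    def __post_init__(self):
        for poly in self.polygons:
            if not poly.is_valid:
                raise SyntheticDataError("invalid protected-area polygon")

    def union(self):
        if not self.polygons:
            return None
        return unary_union(self.polygons)


def generate_regions(
    grid_shape: tuple[int, int],
    cell_size_km: float,
    labels: tuple[str, ...] = ("west", "central", "east"),
) -> list[tuple[str, Polygon]]:
    """Vertical-strip region polygons spanning the grid."""
    rows, cols = grid_shape
    width = cols * cell_size_km
    height = rows * cell_size_km
    n = len(labels)
    out = []
    for i, label in enumerate(labels):
        out.append((label, box(i * width / n, 0.0, (i + 1) * width / n, height)))
    return out


def generate_context_layers(
    network: StreamNetwork,
    pa_fraction: float,
    n_villages: int,
    seed: int,
) -> tuple[ProtectedAreaSet, MultiPolygon, list[Point]]:
    """Protected-area polygons covering ~pa_fraction of river cells,
    river polygons buffering the river mask, and village points."""
    if not (0.0 <= pa_fraction <= 1.0):
        raise SyntheticDataError("pa_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows, cols = network.grid_shape
    s = network.cell_size_km
    mask = network.river_mask
    n_river = int(mask.sum())
    river_cells = np.argwhere(mask)
    regions = generate_regions(network.grid_shape, s)

    polygons: list[Polygon] = []
    labels: list[str] = []
    if pa_fraction >= 1.0:
        polygons.append(box(0.0, 0.0, cols * s, rows * s))
        labels.append(regions[0][0])
    elif pa_fraction > 0.0:
        covered = np.zeros_like(mask)
        target = pa_fraction * n_river
        for _ in range(10_000):
            if covered[mask].sum() >= target:
                break
            r, c = river_cells[rng.integers(len(river_cells))]
            hw = int(rng.integers(3, 9))
            hh = int(rng.integers(3, 9))
            r0, r1 = max(0, r - hh), min(rows, r + hh + 1)
            c0, c1 = max(0, c - hw), min(cols, c + hw + 1)
            x0, x1 = c0 * s, c1 * s
            y0, y1 = (rows - r1) * s, (rows - r0) * s
            polygons.append(box(x0, y0, x1, y1))
            cx = 0.5 * (x0 + x1)
            label = next(
                (lab for lab, poly in regions if poly.contains(Point(cx, 0.5 * (y0 + y1)))),
                regions[-1][0],
            )
            labels.append(label)
            covered[r0:r1, c0:c1] |= mask[r0:r1, c0:c1]

    river_boxes = [
        box(c * s, (rows - r - 1) * s, (c + 1) * s, (rows - r) * s) for r, c in river_cells
    ]
    river_polygons = unary_union(river_boxes)
    if isinstance(river_polygons, Polygon):
        river_polygons = MultiPolygon([river_polygons])

    villages = [
        Point(float(rng.uniform(0, cols * s)), float(rng.uniform(0, rows * s)))
        for _ in range(n_villages)
    ]
    return ProtectedAreaSet(polygons, labels), river_polygons, villages
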