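"""CSV / GeoJSON / YAML readers and writers for pipeline artifacts."""

from __future__ import annotations

import csv
import hashlib
import json

import yaml
from shapely.geometry import mapping, shape

from .curation import OccurrenceRecord, parse_event_date

OCCURRENCE_COLUMNS = [
    "record_id",
    "lon",
    "lat",
    "event_date",
    "coord_uncertainty_m",
    "waterbody_class",
    "life_stage_evidence",
    "source_id",
]


def write_occurrences_csv(path, records: list[OccurrenceRecord]) -> None:
    """Occurrence CSV; ground-truth contamination labels are NOT written
    here (see write_truth_csv) so the pipeline cannot peek at them."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(OCCURRENCE_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.record_id,
                    repr(r.lon),
                    repr(r.lat),
                    r.event_date.isoformat() if r.event_date else "",
                    "" if r.coord_uncertainty_m is None else repr(r.coord_uncertainty_m),
                    r.waterbody_class,
                    r.life_stage_evidence,
                    r.source_id,
                ]
            )


def read_occurrences_csv(path) -> list[OccurrenceRecord]:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                OccurrenceRecord(
                    record_id=int(row["record_id"]),
                    lon=float(row["lon"]),
                    lat=float(row["lat"]),
                    event_date=parse_event_date(row["event_date"]),
                    coord_uncertainty_m=(
                        float(row["coord_uncertainty_m"])
                        if row["coord_uncertainty_m"]
                        else None
                    ),
                    waterbody_class=row["waterbody_class"],
                    life_stage_evidence=row["life_stage_evidence"],
                    source_id=row["source_id"],
                )
            )
    return records


def write_truth_csv(path, records: list[OccurrenceRecord]) -> None:
    """Generator ground truth (record_id -> expected removal reason)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["record_id", "truth_reason"])
        for r in records:
            w.writerow([r.record_id, r.truth_reason or ""])


def write_geojson(path, geometries, properties: list[dict] | None = None) -> None:
    features = []
    for i, geom in enumerate(geometries):
        props = properties[i] if properties else {}
        features.append(
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path):
    """Returns (geometries, properties) lists."""
    with open(path) as fh:
        data = json.load(fh)
    geoms = [shape(f["geometry"]) for f in data["features"]]
    props = [f.get("properties", {}) for f in data["features"]]
    return geoms, props


def write_yaml(path, payload) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
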