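"""Pipeline orchestration: simulate -> curate -> select-vars -> fit ->
ensemble -> prioritize -> assess -> report.

Each stage is a plain function reading its inputs from, and writing its
artifacts to, a run directory, so any stage can be re-run standalone
from the prior artifacts.  Fitted classifiers are intentionally never
persisted: the `ensemble` stage re-fits the runs deterministically from
the logged stage seed, which is cheap and keeps every artifact a text
file.  A manifest (config snapshot, named stage seeds, package version,
artifact hashes) is written at the end; re-running with the same config
reproduces every CSV byte for byte.
"""

from __future__ import annotations

import datetime as _dt
import importlib.resources
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .curation import curate
from .ensemble import (
    committee_average,
    fit_runs,
    high_probability_envelope,
    importance_table,
    response_curve,
    select_models,
)
from .errors import RiverSDMError
from .grids import read_ascii_grid, write_ascii_grid
from .habitat import (
    PreferenceEnvelope,
    StressorObservation,
    WaterQualityReading,
    assess_readings,
    tally_stressors,
)
from .io_utils import (
    read_geojson,
    read_occurrences_csv,
    sha256_file,
    write_geojson,
    write_occurrences_csv,
    write_truth_csv,
    write_yaml,
)
from .network import StreamNetwork, generate_stream_network, prune_order1_adjacent
from .priority import (
    clip_to_rivers,
    detect_clumps,
    overlay_protected,
    percent_unprotected,
    threshold_map,
)
from .synthetic import (
    EnvStack,
    VARIABLE_NAMES,
    generate_context_layers,
    generate_env_stack,
    generate_regions,
    sample_occurrences,
    suitability_grid,
)
from .variables import pearson_matrix, select_uncorrelated

log = logging.getLogger("riversdm")


def _require(outdir: Path, name: str, stage: str) -> Path:
    path = outdir / name
    if not path.exists():
        raise RiverSDMError(f"stage {stage!r}: missing upstream artifact {name}")
    return path


def _load_stack(outdir: Path, cfg: RunConfig, stage: str) -> EnvStack:
    grids = {}
    for name in VARIABLE_NAMES:
        grid, _ = read_ascii_grid(_require(outdir, f"env_{name}.asc", stage))
        grids[name] = grid
    return EnvStack(grids, (cfg.rows, cfg.cols), cfg.cell_size_km)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    """Generate the synthetic riverscape, truth layers, occurrences, and
    context polygons."""
    seeds = cfg.stage_seeds()
    network = generate_stream_network(
        (cfg.rows, cfg.cols),
        cfg.n_sources,
        seed=seeds["network"],
        meander=cfg.meander,
        cell_size_km=cfg.cell_size_km,
    )
    network = prune_order1_adjacent(network)
    network.to_json(outdir / "network.json")

    stack = generate_env_stack(network, seed=seeds["env"])
    for name, grid in stack.variables.items():
        write_ascii_grid(outdir / f"env_{name}.asc", grid, cfg.cell_size_km)

    envelope = cfg.trapezoids()
    suit = suitability_grid(stack, envelope)
    write_ascii_grid(outdir / "true_suitability.asc", suit, cfg.cell_size_km)
    write_yaml(outdir / "true_envelope.yaml", cfg.envelope)

    records = sample_occurrences(
        network,
        suit,
        cfg.n_occurrences,
        cfg.contamination_obj(),
        seed=seeds["occurrences"],
        evidence_fraction=cfg.evidence_fraction,
        snap_radius_m=cfg.snap_radius_m,
    )
    write_occurrences_csv(outdir / "occurrences.csv", records)
    write_truth_csv(outdir / "occurrences_truth.csv", records)

    pa_set, river_polygons, villages = generate_context_layers(
        network, cfg.pa_fraction, cfg.n_villages, seed=seeds["context"]
    )
    write_geojson(
        outdir / "protected_areas.geojson",
        pa_set.polygons,
        [{"region": lab} for lab in pa_set.region_labels],
    )
    write_geojson(outdir / "rivers.geojson", list(river_polygons.geoms))
    write_geojson(outdir / "villages.geojson", villages)
    regions = generate_regions((cfg.rows, cfg.cols), cfg.cell_size_km)
    write_geojson(
        outdir / "regions.geojson",
        [poly for _, poly in regions],
        [{"region": lab} for lab, _ in regions],
    )
    log.info(
        "simulate: %d segments, %d river cells, %d occurrence records",
        len(network.segments),
        int(network.river_mask.sum()),
        len(records),
    )


def stage_curate(cfg: RunConfig, outdir: Path) -> None:
    """Filter, classify, snap, grid-sample, and draw pseudoabsences."""
    seeds = cfg.stage_seeds()
    network = StreamNetwork.from_json(_require(outdir, "network.json", "curate"))
    stack = _load_stack(outdir, cfg, "curate")
    records = read_occurrences_csv(_require(outdir, "occurrences.csv", "curate"))
    curated = curate(records, network, stack, cfg.curation_config(), seed=seeds["pseudoabsence"])

    pd.DataFrame(curated.presences, columns=["row", "col"]).to_csv(
        outdir / "presences.csv", index=False
    )
    pd.DataFrame(curated.pseudoabsences, columns=["row", "col"]).to_csv(
        outdir / "pseudoabsences.csv", index=False
    )
    pd.DataFrame(curated.audit).to_csv(outdir / "curation_audit.csv", index=False)

    cells = curated.presences + curated.pseudoabsences
    labels = [1] * len(curated.presences) + [0] * len(curated.pseudoabsences)
    values = stack.values_at(cells)
    sites = pd.DataFrame(
        {
            "row": [c[0] for c in cells],
            "col": [c[1] for c in cells],
            "label": labels,
            **{name: values[name] for name in VARIABLE_NAMES},
        }
    )
    sites.to_csv(outdir / "sites.csv", index=False)
    log.info(
        "curate: %d presences, %d pseudoabsences", len(curated.presences), len(curated.pseudoabsences)
    )


def stage_select_vars(cfg: RunConfig, outdir: Path) -> None:
    """Pearson screen of the candidate variables at the curated sites."""
    sites = pd.read_csv(_require(outdir, "sites.csv", "select-vars"))
    table = sites[list(VARIABLE_NAMES)]
    matrix = pearson_matrix(table)
    result = select_uncorrelated(matrix, cfg.priority_order, cfg.correlation_threshold)
    matrix.to_csv(outdir / "correlation_matrix.csv")
    write_yaml(
        outdir / "selection.yaml",
        {
            "kept": result.kept,
            "threshold": result.threshold,
            "priority_order": cfg.priority_order,
        },
    )
    log.info("select-vars: kept %s", ", ".join(result.kept))


def _fit_runs_from_artifacts(cfg: RunConfig, outdir: Path, stage: str):
    from .io_utils import read_yaml

    seeds = cfg.stage_seeds()
    sites = pd.read_csv(_require(outdir, "sites.csv", stage))
    kept = read_yaml(_require(outdir, "selection.yaml", stage))["kept"]
    table = sites[kept]
    labels = sites["label"].to_numpy()
    runs = fit_runs(
        table,
        labels,
        n_runs=cfg.n_runs,
        seed=seeds["modeling"],
        frac=cfg.train_frac,
        hyperparams={"n_estimators": cfg.n_trees},
    )
    return runs, table, labels


def stage_fit(cfg: RunConfig, outdir: Path):
    """Fit the repeated runs and write per-run evaluation scores."""
    runs, _, _ = _fit_runs_from_artifacts(cfg, outdir, "fit")
    scores = pd.DataFrame(
        {
            "run_id": [r.run_id for r in runs],
            "seed": [r.seed for r in runs],
            "tss": [r.tss for r in runs],
            "auc": [r.auc for r in runs],
            "optimal_cutoff": [r.optimal_cutoff for r in runs],
            "selected": [r.tss >= cfg.tss_threshold for r in runs],
        }
    )
    scores.to_csv(outdir / "run_scores.csv", index=False)
    log.info(
        "fit: median TSS %.3f, median AUC %.3f",
        float(scores["tss"].median()),
        float(scores["auc"].median()),
    )
    return runs


def stage_ensemble(cfg: RunConfig, outdir: Path, runs=None) -> None:
    """Select runs by TSS, committee-average, and derive interpretation
    products (importance, response curves, high-probability envelope).

    Classifiers are re-fitted deterministically from the logged seed when
    not passed in memory.
    """
    from .io_utils import read_yaml

    seeds = cfg.stage_seeds()
    sites = pd.read_csv(_require(outdir, "sites.csv", "ensemble"))
    kept = read_yaml(_require(outdir, "selection.yaml", "ensemble"))["kept"]
    table = sites[kept]
    if runs is None:
        runs = fit_runs(
            table,
            sites["label"].to_numpy(),
            n_runs=cfg.n_runs,
            seed=seeds["modeling"],
            frac=cfg.train_frac,
            hyperparams={"n_estimators": cfg.n_trees},
        )
    stack = _load_stack(outdir, cfg, "ensemble")
    selected = select_models(runs, cfg.tss_threshold)
    emca = committee_average(selected, stack)
    write_ascii_grid(outdir / "emca.asc", emca, cfg.cell_size_km)

    imp = importance_table(runs, table, n_shuffles=cfg.n_shuffles, seed=seeds["importance"])
    imp.to_csv(outdir / "importance.csv", index_label="variable")

    curves = []
    for name in table.columns:
        curve = response_curve(selected, table, name)
        curve = curve.rename(columns={name: "value"})
        curve.insert(0, "variable", name)
        curves.append(curve)
    pd.concat(curves, ignore_index=True).to_csv(outdir / "response_curves.csv", index=False)

    envelope = high_probability_envelope(emca, stack, p=cfg.probability_threshold)
    envelope.to_csv(outdir / "high_probability_envelope.csv", index_label="variable")
    log.info("ensemble: %d/%d runs selected", len(selected), len(runs))


def stage_prioritize(cfg: RunConfig, outdir: Path) -> None:
    """Threshold EMca, detect clumps, clip to rivers, account by region."""
    emca, _ = read_ascii_grid(_require(outdir, "emca.asc", "prioritize"))
    binary = threshold_map(emca, cfg.probability_threshold)
    cell_area = cfg.cell_size_km**2
    clumps = detect_clumps(binary, adjacency=8, min_cells=cfg.min_clump_cells, cell_area_km2=cell_area)

    rivers, _ = read_geojson(_require(outdir, "rivers.geojson", "prioritize"))
    from shapely.ops import unary_union

    river_union = unary_union(rivers)
    clipped, clip_log = clip_to_rivers(clumps, river_union, cfg.cell_size_km, cfg.rows)
    pd.DataFrame(clip_log, columns=["clump_id", "event", "reason", "cell_count"]).to_csv(
        outdir / "clump_log.csv", index=False
    )

    labels_grid = np.zeros((cfg.rows, cfg.cols), dtype=float)
    for clump in clipped:
        for cell in clump.cells:
            labels_grid[cell] = clump.clump_id
    labels_grid[labels_grid == 0] = np.nan
    write_ascii_grid(outdir / "clump_labels.asc", labels_grid, cfg.cell_size_km)

    pa_geoms, pa_props = read_geojson(_require(outdir, "protected_areas.geojson", "prioritize"))
    from .synthetic import ProtectedAreaSet

    pa_set = ProtectedAreaSet(pa_geoms, [p.get("region", "") for p in pa_props])
    region_geoms, region_props = read_geojson(_require(outdir, "regions.geojson", "prioritize"))
    region_layer = [(p["region"], g) for g, p in zip(region_geoms, region_props)]

    priority_cells = [cell for clump in clipped for cell in clump.cells]
    table = overlay_protected(priority_cells, pa_set, region_layer, cfg.cell_size_km, cfg.rows)
    table.to_csv(outdir / "priority_table.csv", index_label="region")

    pct = {
        region: percent_unprotected(table, region)
        for region in table.index
        if table.loc[region, "total_km2"] > 0
    }
    pd.Series(pct, name="percent_unprotected").to_csv(
        outdir / "percent_unprotected.csv", index_label="region"
    )
    log.info(
        "prioritize: %d clumps, %.2f km2 priority area, %.1f%% unprotected",
        len(clipped),
        float(table.loc["all", "total_km2"]),
        pct.get("all", float("nan")),
    )


def stage_assess(
    cfg: RunConfig,
    outdir: Path,
    readings_csv: Path | None = None,
    stressors_csv: Path | None = None,
) -> None:
    """Water-quality envelope checks and stressor tallies for field sites."""
    data_pkg = importlib.resources.files("riversdm") / "data"
    readings_path = readings_csv or data_pkg / "example_field_readings_synthetic.csv"
    stressors_path = stressors_csv or data_pkg / "example_stressor_observations_synthetic.csv"

    readings_df = pd.read_csv(readings_path)
    readings = [
        WaterQualityReading(
            site=row["site"],
            ph=row["ph"],
            temp_c=row["temp_c"],
            conductivity_us=row["conductivity_us"],
            tds_mg_l=row["tds_mg_l"],
            do_mg_l=row["do_mg_l"],
        )
        for _, row in readings_df.iterrows()
    ]
    status = assess_readings(readings, PreferenceEnvelope())
    status.to_csv(outdir / "water_quality_status.csv")

    stressor_df = pd.read_csv(stressors_path)
    observations = [
        StressorObservation(row["site"], row["category"], row["component"])
        for _, row in stressor_df.iterrows()
    ]
    tally, modal = tally_stressors(observations)
    tally.to_csv(outdir / "stressor_tally.csv", index_label="site")

    lines = ["Habitat assessment", "==================", ""]
    lines.append(f"Sites assessed: {len(readings)}")
    for param in status.columns:
        outside = (status[param].isin(["below", "above"])).sum()
        lines.append(f"  {param}: {outside} of {len(status)} readings outside preference")
    lines.append(f"Most observed stressor category: {', '.join(modal) if modal else 'none'}")
    (outdir / "assessment.txt").write_text("\n".join(lines) + "\n")
    log.info("assess: modal stressor %s", ", ".join(modal) if modal else "none")


def stage_report(cfg: RunConfig, outdir: Path) -> dict:
    """Assemble the run manifest with seeds, version, and artifact hashes."""
    artifacts = sorted(
        p.name
        for p in outdir.iterdir()
        if p.is_file() and p.suffix in (".csv", ".asc", ".json", ".geojson", ".yaml", ".txt")
        and p.name != "manifest.yaml"
    )
    manifest = {
        "package_version": __version__,
        "generated_utc": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "config": cfg.to_dict(),
        "stage_seeds": cfg.stage_seeds(),
        "artifact_sha256": {name: sha256_file(outdir / name) for name in artifacts},
    }
    write_yaml(outdir / "manifest.yaml", manifest)

    summary = ["riversdm run summary", "====================", ""]
    scores_path = outdir / "run_scores.csv"
    if scores_path.exists():
        scores = pd.read_csv(scores_path)
        summary.append(
            f"Runs: {len(scores)}; selected at TSS>={cfg.tss_threshold}: {int(scores['selected'].sum())}"
        )
        summary.append(
            f"Median TSS {scores['tss'].median():.3f}; median AUC {scores['auc'].median():.3f}"
        )
    table_path = outdir / "priority_table.csv"
    if table_path.exists():
        table = pd.read_csv(table_path, index_col="region")
        total = table.loc["all", "total_km2"]
        outside = table.loc["all", "outside_pa_km2"]
        summary.append(f"Priority area {total:.2f} km2; unprotected {outside:.2f} km2")
    (outdir / "summary.txt").write_text("\n".join(summary) + "\n")
    return manifest


STAGES = {
    "simulate": stage_simulate,
    "curate": stage_curate,
    "select-vars": stage_select_vars,
    "fit": stage_fit,
    "ensemble": stage_ensemble,
    "prioritize": stage_prioritize,
    "assess": stage_assess,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Run every stage in order, passing fitted runs in memory between
    fit and ensemble, and return the manifest."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_simulate(cfg, outdir)
    stage_curate(cfg, outdir)
    stage_select_vars(cfg, outdir)
    runs = stage_fit(cfg, outdir)
    stage_ensemble(cfg, outdir, runs=runs)
    stage_prioritize(cfg, outdir)
    stage_assess(cfg, outdir)
    return stage_report(cfg, outdir)
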