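"""Full-pipeline orchestration over a multi-date scenario.

Runs, in order: land-use change accounting, landscape-pattern metrics,
MSPA core extraction, habitat quality, source selection (dPC), least-cost
corridors, network topology and attack robustness — either on rasters
supplied per date or on a synthetic scenario generated from a seed.  All
stage outputs are collected into a :class:`RunReport` and, when an output
directory is given, written as CSV with a JSON manifest of file hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import change, corridors, habitat, metrics, mspa, network, sources, synthetic
from .raster import LandUseRaster, RasterGrid

__all__ = ["PipelineConfig", "RunReport", "ReferenceTables", "load_tables",
           "run_pipeline"]

log = logging.getLogger("econet")


@dataclass
class ReferenceTables:
    """Typed bundle of the packaged parameter and result tables."""

    threats: habitat.ThreatSpec
    sensitivity: habitat.SensitivityTable
    resistance_weights: dict[str, float]
    class_areas: pd.DataFrame
    network_inventory: pd.DataFrame
    connectivity_indices: pd.DataFrame


def load_tables(fixtures_dir: str | Path | None = None) -> ReferenceTables:
    """Load the packaged CSV tables (or the same files from a directory)."""
    base = Path(__file__).parent / "data" if fixtures_dir is None \
        else Path(fixtures_dir)

    def _read(name: str) -> pd.DataFrame:
        path = base / name
        if not path.exists():
            raise FileNotFoundError(f"fixture table {name} not found in {base}")
        return pd.read_csv(path)

    tf = _read("threat_factors.csv")
    threats = habitat.ThreatSpec(threats=[
        habitat.Threat(r["threat"], r["source_class"], float(r["d_max_km"]),
                       float(r["weight"]), r["decay"])
        for _, r in tf.iterrows()
    ])
    sens = habitat.SensitivityTable.from_frame(_read("habitat_sensitivity.csv"))
    rw = _read("resistance_weights.csv")
    weights = dict(zip(rw["factor"], rw["weight"].astype(float)))
    return ReferenceTables(
        threats=threats,
        sensitivity=sens,
        resistance_weights=weights,
        class_areas=_read("class_areas_by_year.csv"),
        network_inventory=_read("network_inventory.csv"),
        connectivity_indices=_read("connectivity_indices.csv"),
    )


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run."""

    dates: list[str]
    scenario: synthetic.ScenarioConfig | None = None
    rasters: dict[str, LandUseRaster] | None = None
    dem: RasterGrid | None = None
    ndvi_noise_sd: float = 0.05
    edge_width: int = 1
    n_candidate_sources: int = 30
    min_source_quality: float = 0.5
    median_dispersal_m: float = 2500.0
    attack_trials: int = 100
    seed: int = 0
    skip_stages: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.dates:
            raise ValueError("at least one date is required")
        if list(self.dates) != sorted(self.dates):
            raise ValueError("dates must be strictly ordered")
        if len(set(self.dates)) != len(self.dates):
            raise ValueError("dates must be distinct")
        if self.scenario is None and self.rasters is None:
            raise ValueError("either a scenario or input rasters are required")


@dataclass
class RunReport:
    """Collected outputs of one pipeline run."""

    area_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    dynamic_degrees: pd.DataFrame | None = None
    transition_matrices: dict[str, pd.DataFrame] = field(default_factory=dict)
    metric_table: pd.DataFrame | None = None
    network_summary: pd.DataFrame | None = None
    attack_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    indices: dict[str, network.ConnectivityIndices] = field(default_factory=dict)


def _simulate_series(config: PipelineConfig) -> dict[str, LandUseRaster]:
    """Generate a date series from the scenario: a base mosaic evolved by
    the scenario's transitions once per date step."""
    scen = config.scenario
    base = synthetic.generate_landuse(scen)
    out = {config.dates[0]: base}
    current = base
    for k, date in enumerate(config.dates[1:], start=1):
        step = synthetic.ScenarioConfig(
            extent=scen.extent, cell_size=scen.cell_size,
            class_proportions=scen.class_proportions,
            clustering=scen.clustering, transitions=scen.transitions,
            seed=scen.seed + k,
        )
        current = synthetic.evolve_landuse(current, step)
        out[date] = current
    return out


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None,
                 tables: ReferenceTables | None = None) -> RunReport:
    """Execute every configured stage and return the collected report."""
    t0 = time.time()
    tables = tables or load_tables()
    report = RunReport()
    skip = set(config.skip_stages)

    rasters = config.rasters or _simulate_series(config)
    dates = list(config.dates)
    first = rasters[dates[0]]

    dem = config.dem or synthetic.generate_dem(
        first.shape, cell_size=first.cell_size, seed=config.seed + 11)
    slope, relief = corridors.derive_terrain(dem)

    # --- change accounting -------------------------------------------------
    if "change" not in skip:
        log.info("stage change: %d dates", len(dates))
        for date in dates:
            report.area_tables[date] = change.class_areas(rasters[date], date=date)
        dd_rows = []
        for d0, d1 in zip(dates[:-1], dates[1:]):
            key = f"{d0}-{d1}"
            report.transition_matrices[key] = change.transition_matrix(
                rasters[d0], rasters[d1])
            years = _year_gap(d0, d1)
            a0 = report.area_tables[d0]["area_km2"]
            a1 = report.area_tables[d1]["area_km2"]
            for cls in a0.index:
                if a0[cls] > 0:
                    dd_rows.append({
                        "period": key, "class": cls,
                        "K_pct_per_year": change.dynamic_degree(
                            a0[cls], a1[cls], years),
                    })
        report.dynamic_degrees = pd.DataFrame(dd_rows)

    # --- landscape metrics -------------------------------------------------
    if "metrics" not in skip:
        log.info("stage metrics")
        report.metric_table = metrics.metric_timeseries(
            {d: rasters[d] for d in dates})

    # --- per-date network stages -------------------------------------------
    net_rows = []
    for date in dates:
        lu = rasters[date]
        if "network" in skip:
            continue
        log.info("stage network: date %s", date)
        fg = mspa.binarize_foreground(lu)
        seg = mspa.segment(fg, edge_width=config.edge_width,
                           cell_size=lu.cell_size)
        cores = mspa.core_patches(seg)

        ndvi = synthetic.generate_ndvi(lu, noise_sd=config.ndvi_noise_sd,
                                       seed=config.seed + 23)
        threats = habitat.threat_rasters(lu, tables.threats)
        d_raster = habitat.degradation(lu, threats, tables.threats,
                                       tables.sensitivity)
        q_raster = habitat.quality(d_raster, lu, tables.sensitivity)

        row = {"date": date, "core_patches": len(cores.table)}
        if cores.table.empty:
            net_rows.append(row | {"sources": 0, "corridors": 0})
            continue
        total_km2 = lu.values.size * lu.cell_area_km2
        params = sources.ConnectivityParams(
            median_dispersal_m=config.median_dispersal_m, a_l_km2=total_km2)
        cands = sources.candidate_cores(
            cores, q_raster, n=config.n_candidate_sources,
            min_quality=config.min_source_quality)
        cands = sources.rank_sources(cands, params, cell_size=lu.cell_size)
        selected = [s for s in cands if s.tier != "excluded"]
        row["sources"] = len(selected)
        row["important_sources"] = sum(s.tier == "important" for s in selected)
        row["source_area_km2"] = sum(s.area_km2 for s in selected)

        if len(selected) >= 2:
            levels = corridors.grade_factors(q_raster, lu, ndvi, slope,
                                             relief, dem)
            surface = corridors.resistance_surface(
                levels, tables.resistance_weights, cell_size=lu.cell_size)
            corrs = corridors.least_cost_corridors(surface, selected)
            corrs = corridors.classify_corridors(corrs, selected)
            reachable = [c for c in corrs if np.isfinite(c.cost)]
            row["corridors"] = len(reachable)
            row["important_corridors"] = sum(
                c.tier == "important" for c in reachable)
            row["corridor_length_km"] = sum(c.length_km for c in reachable)
            net = network.build_graph(corrs, selected)
            idx = network.connectivity_indices(net)
            report.indices[date] = idx
            row["V"] = idx.v
            row["L"] = idx.l
            rid = idx.rounded()
            row["alpha"], row["beta"], row["gamma"] = rid.alpha, rid.beta, rid.gamma
            curve = network.random_attack(net, n_trials=config.attack_trials,
                                          seed=config.seed + 37)
            report.attack_curves[date] = curve
            row["collapse_at"] = network.collapse_summary(curve)
        else:
            row["corridors"] = 0
        net_rows.append(row)
    if net_rows:
        report.network_summary = pd.DataFrame(net_rows)

    if output_dir is not None:
        _write_outputs(report, Path(output_dir))
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return report


def _year_gap(d0: str, d1: str) -> float:
    try:
        return float(int(d1) - int(d0))
    except ValueError:
        return 1.0


def _write_outputs(report: RunReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {}

    def _save(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = outdir / name
        df.to_csv(path, index=index)
        manifest[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    for date, df in report.area_tables.items():
        _save(df, f"areas_{date}.csv", index=True)
    for key, df in report.transition_matrices.items():
        _save(df, f"transition_{key}.csv", index=True)
    if report.dynamic_degrees is not None:
        _save(report.dynamic_degrees, "dynamic_degrees.csv")
    if report.metric_table is not None:
        _save(report.metric_table, "metrics.csv")
    if report.network_summary is not None:
        _save(report.network_summary, "network_summary.csv")
    for date, df in report.attack_curves.items():
        _save(df, f"attack_{date}.csv")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
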