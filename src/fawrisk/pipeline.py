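"""End-to-end orchestration: suitability -> cleaning -> migration -> economics.

Each stage reads and writes declared file artefacts inside the run
directory, so any stage can be re-run from its predecessors' outputs. A
manifest records the package version, the configuration hash and the seed;
re-running with an identical configuration reproduces identical CSV/JSON
artefacts byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from fawrisk import __version__
from fawrisk.params import SpeciesParameters
from fawrisk.climex import run_grid
from fawrisk.occurrences import clean_records, deduplicate, CleaningConfig
from fawrisk.migration import (
    classify_population, apply_exclusions, hub_cells,
    distance_to_nearest_hub, build_ecdf, buffer_zones, zones_to_geojson,
)
from fawrisk.economics import run_scenarios, format_per_ha_table, \
    format_national_table
from fawrisk import synthetic

logger = logging.getLogger("fawrisk")

_KNOWN_KEYS = {
    "outdir", "seed", "scenario", "percentiles", "exclusions",
    "species_parameters", "n_occurrences", "dirty_fraction",
    "n_states", "n_years",
    "climate", "irrigation_mask", "occurrences", "econ_panel",
    "yield_losses", "state_distances",
}
_PATH_KEYS = ("climate", "irrigation_mask", "occurrences", "econ_panel",
              "yield_losses", "state_distances")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run.

    With no input paths the bundled synthetic world is generated from the
    seed; any provided path replaces the corresponding synthetic input.
    """

    outdir: str = "fawrisk_run"
    seed: int = 0
    scenario: str = "rainfed"
    percentiles: tuple = (50.0, 75.0, 95.0, 97.5, 100.0)
    exclusions: list = field(default_factory=list)
    species_parameters: dict = field(default_factory=dict)
    n_occurrences: int = 1000
    dirty_fraction: float = 0.1
    n_states: int = 5
    n_years: int = 5
    climate: str | None = None
    irrigation_mask: str | None = None
    occurrences: str | None = None
    econ_panel: str | None = None
    yield_losses: str | None = None
    state_distances: str | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.scenario not in ("rainfed", "irrigated"):
            raise ValueError("scenario must be 'rainfed' or 'irrigated'")
        if list(self.percentiles) != sorted(self.percentiles):
            raise ValueError("percentiles must be sorted ascending")
        for key in _PATH_KEYS:
            value = getattr(self, key)
            if value is not None and not Path(value).exists():
                raise ValueError(f"configured {key} path does not exist: {value}")
        SpeciesParameters().with_overrides(**self.species_parameters)

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def run_all(config: RunConfig) -> Path:
    """Execute the four stages in order; returns the run directory.

    A stage failure raises with the failing stage named; artefacts written
    by completed stages remain in place and the manifest marks the run as
    partial.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s stage=%(stage)s level=%(levelname)s msg=%(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages_completed": [],
        "status": "partial",
    }

    def _log(stage: str, msg: str) -> None:
        logger.info(msg, extra={"stage": stage})

    def _checkpoint() -> None:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         default=str))

    p = SpeciesParameters().with_overrides(**config.species_parameters)
    rng = np.random.default_rng(config.seed)

    try:
        # -------------------------------------------------- stage: inputs
        stage = "inputs"
        t0 = time.time()
        spec = synthetic.SyntheticWorldSpec(seed=config.seed)
        if config.climate is not None:
            monthly = xr.open_dataset(config.climate, engine="scipy").load()
        else:
            monthly, irrigation, zone_truth = synthetic.gen_climate_grid(spec)
            monthly.to_netcdf(outdir / "climate_monthly.nc", engine="scipy")
            zone_truth.to_dataset(name="zone").to_netcdf(
                outdir / "zone_truth.nc", engine="scipy")
        if config.irrigation_mask is not None:
            irrigation = xr.open_dataset(config.irrigation_mask,
                                         engine="scipy").load()["irrigated"]
        elif config.climate is not None:
            irrigation = xr.zeros_like(monthly["tmin"].isel(month=0, drop=True))
        irrigation.to_dataset(name="irrigated").to_netcdf(
            outdir / "irrigation_mask.nc", engine="scipy")
        _log(stage, f"inputs ready in {time.time() - t0:.1f}s")
        manifest["stages_completed"].append(stage)

        # --------------------------------------------- stage: suitability
        stage = "suitability"
        t0 = time.time()
        suit = run_grid(monthly, irrigation, p, scenario=config.scenario)
        suit.to_netcdf(outdir / f"suitability_{config.scenario}.nc",
                       engine="scipy")
        _log(stage, f"grid of {suit['EI'].size} cells in {time.time() - t0:.1f}s")
        manifest["stages_completed"].append(stage)

        # ------------------------------------------------ stage: cleaning
        stage = "clean-occurrences"
        t0 = time.time()
        if config.occurrences is not None:
            raw = pd.read_csv(config.occurrences)
        else:
            hub = hub_cells(suit["EI"])
            if hub.empty:
                raise RuntimeError("no EI > 0 cells; cannot place occurrences")
            raw = synthetic.gen_occurrences(
                hub, n=config.n_occurrences,
                dirty_fraction=config.dirty_fraction,
                seed=int(rng.integers(2**31)))
            _write_csv(raw, outdir / "occurrences_raw.csv")
        clean, report = clean_records(raw, CleaningConfig())
        clean = deduplicate(clean)
        _write_csv(clean, outdir / "occurrences_clean.csv")
        report.to_json(outdir / "cleaning_report.json")
        _log(stage, f"{report.input_count} -> {len(clean)} records "
                    f"in {time.time() - t0:.1f}s")
        manifest["stages_completed"].append(stage)

        # ----------------------------------------------- stage: migration
        stage = "migration"
        t0 = time.time()
        classified = classify_population(clean, suit["EI"], suit["GIA"])
        transient = classified[classified["population_class"] == "transient"]
        kept, excluded = apply_exclusions(transient, config.exclusions)
        hub = hub_cells(suit["EI"])
        dists = distance_to_nearest_hub(
            kept["decimalLongitude"].values, kept["decimalLatitude"].values,
            hub["lon"].values, hub["lat"].values)
        kept = kept.assign(hub_distance_km=dists)
        _write_csv(classified, outdir / "occurrences_classified.csv")
        _write_csv(kept, outdir / "transient_distances.csv")
        dist = build_ecdf(dists)
        _write_csv(dist.to_frame(), outdir / "ecdf.csv")
        radii = [float(dist.percentile(q)) for q in config.percentiles]
        _write_csv(pd.DataFrame({"percentile": list(config.percentiles),
                                 "radius_km": radii}),
                   outdir / "percentiles.csv")
        zones = buffer_zones(synthetic.northern_edge(hub), radii,
                             percentiles=list(config.percentiles))
        zones_to_geojson(zones, outdir / "dispersal_zones.geojson")
        _log(stage, f"{len(kept)} transient records "
                    f"({len(excluded)} excluded) in {time.time() - t0:.1f}s")
        manifest["stages_completed"].append(stage)

        # ----------------------------------------------- stage: economics
        stage = "economics"
        t0 = time.time()
        if config.econ_panel is not None:
            panel = pd.read_csv(config.econ_panel)
            yl = pd.read_csv(config.yield_losses)
            d_states = pd.read_csv(config.state_distances)
        else:
            panel, yl, d_states, truth = synthetic.gen_econ_panel(
                n_states=config.n_states, n_years=config.n_years,
                seed=int(rng.integers(2**31)))
            (outdir / "econ_truth.json").write_text(
                json.dumps(truth, indent=2, sort_keys=True))
            _write_csv(panel, outdir / "econ_panel.csv")
            _write_csv(yl, outdir / "yield_losses.csv")
        pp = d_states.assign(PP=dist.presence_probability(d_states["D_km"].values))
        _write_csv(pp, outdir / "presence_probability.csv")
        results = run_scenarios(panel, yl, pp)
        _write_csv(results, outdir / "economics_full.csv")
        _write_csv(format_per_ha_table(results), outdir / "economics_per_ha.csv")
        _write_csv(format_national_table(results),
                   outdir / "economics_national.csv")
        summary = results[results["state"] == "Average/Sum"].iloc[0]
        report_json = {
            "n_transient_records": int(len(kept)),
            "median_migration_km": float(dist.percentile(50)),
            "percentiles_km": dict(zip(map(str, config.percentiles), radii)),
            "mean_baseline_gm_eur_ha": float(summary["gm_baseline"]),
            "mean_dei_eur_ha": {s: float(summary[f"dei_{s}"])
                                for s in ("best", "moderate", "worst")},
            "total_dei_million_eur": {s: float(summary[f"dei_{s}_national"])
                                      for s in ("best", "moderate", "worst")},
        }
        (outdir / "report.json").write_text(
            json.dumps(report_json, indent=2, sort_keys=True))
        _log(stage, f"economics for {len(results) - 1} states "
                    f"in {time.time() - t0:.1f}s")
        manifest["stages_completed"].append(stage)

        manifest["status"] = "complete"
        _checkpoint()
        return outdir
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _checkpoint()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
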