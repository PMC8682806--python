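"""End-to-end orchestration: one seeded, reproducible pipeline run.

``run_pipeline`` wires the five analysis stages together on the idealised
synthetic domain — environment generation, spill-trajectory ensembles,
oil-fate Monte Carlo, atmospheric dispersion over the season x release x
mode scenario matrix, exposure-response health impacts, and supply
disruption — and exports every table, field and polygon along with a
manifest recording seeds and output checksums.  Identical configuration
and seed yield identical checksums.

Per-stage seeds are derived from the global seed by hashing
``"{seed}:{stage}"`` so stages re-run in isolation reproduce their part
of a full run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dispersion, environment, fate, health, impacts, transport
from .environment import (
    AssetLayer,
    DesalinationPlant,
    FisheryYieldGrid,
    Port,
)
from .errors import ConfigError
from .grids import GridSpec, LandMask

log = logging.getLogger("spillsim")

SCENARIO_SEASONS = ("summer", "winter")
RELEASES_H = (24.0, 72.0)
MODES = ("leak", "fire")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Full pipeline configuration with desk-scale synthetic defaults.

    Ensemble sizes here are deliberately smaller than the module-level
    defaults so that a complete eight-scenario run finishes in minutes on
    one CPU while keeping every structural feature of the analysis; scale
    them up through a config file for production-size runs.
    """

    seed: int = 0
    # domain
    lat_min: float = 11.0
    lat_max: float = 21.0
    lon_min: float = 38.0
    lon_max: float = 46.0
    cell_size: float = 0.25
    t_step_h: float = 3.0
    duration_days: float = 24.0
    # idealised coastline
    coast_west_lon: float = 40.0
    coast_east_lon: float = 43.0
    gulf_lat_band: tuple[float, float] = (11.5, 12.5)
    source: tuple[float, float] = (42.8, 15.15)
    # transport
    n_simulations: int = 30
    n_particles: int = 120
    dt_minutes: float = 30.0
    horizon_days: float = 21.0
    release_duration_h: float = 168.0
    concentration_decimals: int = 2
    # fate
    fate_n_mc: int = 300
    # dispersion
    disp_n_particles: int = 600
    disp_n_start_times: int = 6
    disp_run_hours: int = 144
    # health
    health_n_draws: int = 400
    exposure_threshold: float = 10.0
    risk_preset: str = "burnett-style"
    # population
    population_total: int = 20_000_000
    # external inputs (optional overrides; must exist when given)
    environment_paths: dict = field(default_factory=dict)  # season -> nc path
    assets_path: str | None = None
    output_dir: str = "spill_outputs"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "gulf_lat_band" in data:
            data["gulf_lat_band"] = tuple(data["gulf_lat_band"])
        if "source" in data:
            data["source"] = tuple(data["source"])
        return cls(**data)

    def grid(self) -> GridSpec:
        return GridSpec(
            lat_min=self.lat_min, lat_max=self.lat_max,
            lon_min=self.lon_min, lon_max=self.lon_max,
            cell_size=self.cell_size,
            t_start=pd.Timestamp("2020-01-01"),
            t_end=pd.Timestamp("2020-01-01") + pd.Timedelta(days=self.duration_days),
            t_step_h=self.t_step_h,
        )

    def land_mask(self) -> LandMask:
        return LandMask.channel(
            self.grid(),
            west_lon=self.coast_west_lon,
            east_lon=self.coast_east_lon,
            arm_lat_band=self.gulf_lat_band,
        )

    def risk(self) -> health.RiskFunction:
        presets = {
            "burnett-style": health.RiskFunction.burnett_style,
            "wei-style": health.RiskFunction.wei_style,
            "kloog-style": health.RiskFunction.kloog_style,
        }
        if self.risk_preset not in presets:
            raise ConfigError(f"unknown risk preset {self.risk_preset!r}")
        return presets[self.risk_preset]()

    def preflight(self) -> None:
        for season, path in self.environment_paths.items():
            if not Path(path).exists():
                raise ConfigError(f"environment file for {season!r} not found: {path}")
        if self.assets_path is not None and not Path(self.assets_path).exists():
            raise ConfigError(f"assets file not found: {self.assets_path}")


# ---------------------------------------------------------------------------
# synthetic default assets and socio-economic series
# ---------------------------------------------------------------------------

#: Synthetic monthly fuel imports (metric tons, n = 5) through the Red Sea
#: ports, sized around the ~200,000 t/month the affected ports handle.
DEFAULT_FUEL_IMPORTS = [193_000.0, 215_000.0, 187_000.0, 226_000.0, 204_000.0]

#: Synthetic monthly people targeted for food assistance (persons, n = 10).
DEFAULT_FOOD_TARGETED = [
    9.6e6, 10.4e6, 8.9e6, 10.1e6, 9.2e6, 10.8e6, 9.9e6, 9.4e6, 10.6e6, 9.8e6,
]

#: Synthetic fuel prices (currency units) before/after a full port closure.
DEFAULT_PRICES_T0 = {"diesel": 305.0, "petrol": 315.0, "gas": 290.0}
DEFAULT_PRICES_T1 = {"diesel": 525.0, "petrol": 545.0, "gas": 498.0}

#: Synthetic per-capita daily water use by country (m^3/person/day).
DEFAULT_PER_CAPITA_USE = {"yemen": 0.075, "saudi": 0.25, "eritrea": 0.05}

#: National desalination capacity to divide among plants lacking their own.
DEFAULT_COUNTRY_CAPACITY = {"yemen": 120_000.0}


def synthetic_assets(config: RunConfig, seed: int | None = None) -> AssetLayer:
    """Synthetic ports, desalination plants and fishery yield for the channel.

    Ports sit just inside the eastern coast near the spill site; plants
    line both coasts; fishery yield decays away from the eastern coast
    with the southern arm labelled as the gulf region.
    """
    rng = np.random.default_rng(stage_seed(seed if seed is not None else config.seed, "assets"))
    # coastal assets sit on the waterline, where beached oil accumulates
    east = config.coast_east_lon - 0.005
    west = config.coast_west_lon + 0.005
    gulf_coast_lat = config.gulf_lat_band[0] + 0.005
    ports = [
        Port("hudaydah-like", east, 14.7, food_aid_share=0.53, monthly_fuel_tons=120_000),
        Port("salif-like", east, 15.3, food_aid_share=0.15, monthly_fuel_tons=80_000),
        Port("aden-like", 44.6, gulf_coast_lat, food_aid_share=0.32, monthly_fuel_tons=60_000),
    ]
    plants = [
        DesalinationPlant("ym-north", east, 16.0, None, "yemen"),
        DesalinationPlant("ym-central", east, 14.2, None, "yemen"),
        DesalinationPlant("ym-south", east, 13.5, None, "yemen"),
        DesalinationPlant("sa-coast", east, 18.5, 250_000.0, "saudi"),
        DesalinationPlant("er-coast", west, 15.5, 40_000.0, "eritrea"),
    ]
    g = config.grid().spatial()
    mask = config.land_mask()
    lat2, lon2 = np.meshgrid(g.lats, g.lons, indexing="ij")
    water = ~mask.land
    near_coast = np.exp(-((east - lon2) / 1.5) ** 2)
    yld = np.where(water, 50.0 * near_coast * (1.0 + 0.2 * rng.random(lat2.shape)), 0.0)
    lo, hi = config.gulf_lat_band
    in_gulf = (lat2 >= lo) & (lat2 <= hi) & (lon2 > east)
    region = np.where(water, "Red Sea", "")
    region = np.where(in_gulf & water, "Gulf of Aden", region).astype(object)
    yld = np.where(region == "", 0.0, yld)
    return AssetLayer(
        ports=ports,
        plants=plants,
        fishery=FisheryYieldGrid(grid=g, yield_tons=yld, region=region),
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_environment(config: RunConfig) -> dict[str, environment.EnvironmentFields]:
    """Generate (or read) per-season forcing fields."""
    fields = {}
    for season in SCENARIO_SEASONS:
        if season in config.environment_paths:
            fields[season] = environment.read_environment(config.environment_paths[season])
        else:
            fields[season] = environment.generate_environment(
                config.grid(), season=season,
                seed=stage_seed(config.seed, f"environment:{season}"),
            )
    return fields


def stage_transport(config: RunConfig, env_fields) -> dict[str, transport.SpillEnsembleResult]:
    results = {}
    for season, fields in env_fields.items():
        cfg = transport.TrajectoryConfig(
            n_particles=config.n_particles,
            n_simulations=config.n_simulations,
            horizon_days=config.horizon_days,
            release_duration_h=config.release_duration_h,
            dt_minutes=config.dt_minutes,
            concentration_decimals=config.concentration_decimals,
            seed=stage_seed(config.seed, f"transport:{season}"),
        )
        results[season] = transport.run_ensemble(
            cfg, fields, config.source, config.land_mask()
        )
    return results


def stage_fate(config: RunConfig) -> dict[str, fate.FateEnsemble]:
    oil = fate.OilProperties.marib_light_like()
    seed = stage_seed(config.seed, "fate")
    return {
        "evaporation_only": fate.run_fate(oil, cleanup=None, n_mc=config.fate_n_mc, seed=seed),
        "cleanup": fate.run_fate(
            oil, cleanup=fate.CleanupConfig(), n_mc=config.fate_n_mc, seed=seed
        ),
    }


def scenario_matrix(config: RunConfig) -> list[dispersion.EmissionScenario]:
    return [
        dispersion.EmissionScenario(
            season=season, release_duration_h=rel, mode=mode, source=config.source
        )
        for season in SCENARIO_SEASONS
        for rel in RELEASES_H
        for mode in MODES
    ]


def stage_dispersion(config: RunConfig, env_fields) -> dict[str, dispersion.PM25Field]:
    out = {}
    for scen in scenario_matrix(config):
        out[scen.label] = dispersion.disperse(
            scen,
            env_fields[scen.season],
            n_particles=config.disp_n_particles,
            run_hours=config.disp_run_hours,
            n_start_times=config.disp_n_start_times,
            seed=stage_seed(config.seed, f"dispersion:{scen.label}"),
        )
    return out


def stage_population(config: RunConfig) -> environment.PopulationGrid:
    hotspots = [
        (43.6, 14.9, 0.4),
        (44.4, 15.4, 0.3),
        (44.8, 12.8, 0.3),
    ]
    return environment.generate_population(
        config.grid(), config.population_total, hotspots,
        seed=stage_seed(config.seed, "population"),
        sigma_deg=0.6, land_mask=config.land_mask(),
    )


def stage_health(config: RunConfig, pm_fields, population) -> list[health.ExposureSummary]:
    risk = config.risk()
    rows = []
    for label, pm in pm_fields.items():
        mc = health.MonteCarloConfig(
            n_draws=config.health_n_draws,
            seed=stage_seed(config.seed, f"health:{label}"),
            exposure_threshold=config.exposure_threshold,
        )
        rows.append(health.propagate_uncertainty(pm, population, risk, mc))
    return rows


def cumulative_reach_field(
    result: transport.SpillEnsembleResult, week: int
) -> transport.SurfaceConcentrationField:
    """Per-cell max of the weekly fields up to ``week`` ("reached by week k")."""
    cells: dict = {}
    for w in sorted(result.fields_by_week):
        if w > week:
            break
        for key, v in result.fields_by_week[w].cells.items():
            cells[key] = max(cells.get(key, 0.0), v)
    return transport.SurfaceConcentrationField(
        cells, result.config.concentration_decimals, result.config.n_simulations
    )


def stage_impacts(config: RunConfig, transport_results, assets: AssetLayer) -> dict:
    """Port, desalination, fishery, fuel and food-aid disruption tables."""
    port_rows = []
    desal_rows = []
    fishery_rows = []
    for season, result in transport_results.items():
        for week in sorted(result.fields_by_week):
            pct_field = result.fields_by_week[week].percentile_transform()
            for pe in impacts.port_exposure(pct_field, assets.ports, week=week):
                port_rows.append({"season": season, **pe.__dict__})
            reach = cumulative_reach_field(result, week)
            des = impacts.desal_disruption(
                reach, assets.plants, DEFAULT_PER_CAPITA_USE, DEFAULT_COUNTRY_CAPACITY
            )
            desal_rows.append(
                {
                    "season": season,
                    "week": week,
                    "total_disrupted_m3_day": des.total_disrupted_m3_day,
                    "population_equivalent": des.population_equivalent,
                }
            )
            reach_pct = reach.percentile_transform()
            for thr_name, thr in (("none", None), ("p10", 10.0), ("p20", 20.0)):
                for region in ("Red Sea", "Gulf of Aden"):
                    try:
                        fl = impacts.fishery_loss(
                            reach_pct, assets.fishery, region, thr, week=week, season=season
                        )
                    except ValueError:
                        continue
                    fishery_rows.append(
                        {
                            "season": season,
                            "week": week,
                            "threshold": thr_name,
                            "region": region,
                            "threatened_fraction_pct": fl.threatened_fraction_pct,
                        }
                    )
    fuel = impacts.fuel_disruption(DEFAULT_FUEL_IMPORTS)
    spike = impacts.price_spike(DEFAULT_PRICES_T0, DEFAULT_PRICES_T1)
    shares = {p.name: p.food_aid_share for p in assets.ports}
    red_sea_ports = [p.name for p in assets.ports if p.name != "aden-like"]
    food_red_sea = impacts.food_aid_disruption(shares, DEFAULT_FOOD_TARGETED, red_sea_ports)
    food_all = impacts.food_aid_disruption(
        shares, DEFAULT_FOOD_TARGETED, [p.name for p in assets.ports]
    )
    return {
        "ports": pd.DataFrame(port_rows),
        "desalination": pd.DataFrame(desal_rows),
        "fishery": pd.DataFrame(fishery_rows),
        "fuel": fuel,
        "price_spike_pct": spike,
        "food_aid_red_sea": food_red_sea,
        "food_aid_all_ports": food_all,
    }


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, output_dir=None) -> dict:
    """Execute every stage and write all exports plus a manifest.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    config.preflight()
    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings = {}
    t0 = time.time()

    def clock(name):
        timings[name] = round(time.time() - t0, 2)

    log.info("stage: environment")
    env_fields = stage_environment(config)
    for season, f in env_fields.items():
        environment.write_environment(f, outdir / f"environment_{season}.nc")
    clock("environment")

    log.info("stage: transport")
    tr = stage_transport(config, env_fields)
    for season, result in tr.items():
        for week, fld in result.fields_by_week.items():
            df = fld.to_dataframe()
            pct = fld.percentile_transform()
            df["percentile"] = [pct.cells[k] for k in fld.cells]
            df.to_csv(outdir / f"surface_week{week}_{season}.csv", index=False)
        if result.region is not None:
            with open(outdir / f"uncertainty_region_{season}.geojson", "w") as fh:
                json.dump(result.region.to_geojson(), fh)
    clock("transport")

    log.info("stage: fate")
    fates = stage_fate(config)
    for name, ens in fates.items():
        ens.to_dataframe().to_csv(outdir / f"oil_budget_{name}.csv", index=False)
    clock("fate")

    log.info("stage: dispersion")
    pm_fields = stage_dispersion(config, env_fields)
    for label, pm in pm_fields.items():
        pm.to_dataframe().to_csv(outdir / f"pm25_{label}.csv", index=False)
    clock("dispersion")

    log.info("stage: health")
    population = stage_population(config)
    summaries = stage_health(config, pm_fields, population)
    health_df = pd.DataFrame([s.to_row() for s in summaries])
    health_df.to_csv(outdir / "health_summary.csv", index=False)
    clock("health")

    log.info("stage: impacts")
    assets = (
        environment.read_assets(config.assets_path)
        if config.assets_path
        else synthetic_assets(config)
    )
    if assets.fishery is None:
        assets.fishery = synthetic_assets(config).fishery
    environment.write_assets(assets, outdir / "assets.geojson")
    imp = stage_impacts(config, tr, assets)
    imp["ports"].to_csv(outdir / "port_exposure.csv", index=False)
    imp["desalination"].to_csv(outdir / "desalination.csv", index=False)
    imp["fishery"].to_csv(outdir / "fishery_loss.csv", index=False)
    with open(outdir / "supply_summary.json", "w") as fh:
        json.dump(
            {
                "fuel_disruption_tons_per_month": imp["fuel"].__dict__,
                "price_spike_pct": imp["price_spike_pct"],
                "food_aid_red_sea_persons": imp["food_aid_red_sea"].__dict__,
                "food_aid_all_ports_persons": imp["food_aid_all_ports"].__dict__,
            },
            fh,
            indent=1,
        )
    clock("impacts")

    manifest = {
        "seed": config.seed,
        "stage_seeds": {
            s: stage_seed(config.seed, s)
            for s in ("environment:summer", "transport:summer", "fate", "population")
        },
        "config": {k: v for k, v in asdict(config).items()},
        "timings_s": timings,
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
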