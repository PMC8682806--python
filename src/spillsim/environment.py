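"""Synthetic environmental forcing, population and asset layers.

The analysis needs hourly-to-3-hourly wind/current/temperature/salinity
grids with the statistical structure of reanalysis products: a seasonal
mean circulation plus temporally persistent, spatially smooth variability.
Here those inputs are emulated as a first-order autoregressive (AR(1))
process in time whose innovations are Gaussian-smoothed in space, so the
downstream transport, weathering and dispersion stages can be exercised
and verified without external downloads.  Readers for externally supplied
NetCDF-style files with the same variable conventions are provided.

The seasonal mean flows are configured so that "summer" circulation points
south-east along the channel axis and "winter" circulation points north,
reproducing the qualitative seasonality of the Red Sea at the level of the
synthetic forcing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter

from .errors import MissingVariableError, UnitMismatchError
from .grids import GridSpec, LandMask, bilinear_on_regular

# CF-like variable names and the fixed units of the in-memory containers.
ENV_VARS = {
    "u10": "m s-1",
    "v10": "m s-1",
    "water_u": "m s-1",
    "water_v": "m s-1",
    "water_temp": "degC",
    "salinity": "PSU",
}

SEASONS = ("summer", "winter", "spring", "autumn")


@dataclass(frozen=True)
class VariabilityConfig:
    """Mean state and stochastic structure of the synthetic forcing.

    ``mean_current`` / ``mean_wind`` are (east, north) components in m/s;
    ``ar1`` is the lag-1 temporal autocorrelation of every perturbation
    series; ``spatial_sigma_cells`` is the Gaussian smoothing scale of the
    innovations in grid cells.  Perturbation standard deviations are the
    *stationary* (marginal) standard deviations of the AR(1) process.
    """

    mean_current: tuple[float, float]
    mean_wind: tuple[float, float]
    current_std: float = 0.05
    wind_std: float = 1.5
    ar1: float = 0.9
    spatial_sigma_cells: float = 1.0
    sst_mean: float = 29.0
    sst_std: float = 1.0
    salinity_mean: float = 40.0
    salinity_std: float = 0.5
    current_cap: float = 3.0
    wind_cap: float = 40.0

    def __post_init__(self) -> None:
        vals = [
            *self.mean_current,
            *self.mean_wind,
            self.current_std,
            self.wind_std,
            self.ar1,
            self.spatial_sigma_cells,
            self.sst_mean,
            self.sst_std,
            self.salinity_mean,
            self.salinity_std,
        ]
        if not np.all(np.isfinite(vals)):
            raise ValueError("variability parameters must be finite")
        if not (0.0 <= self.ar1 < 1.0):
            raise ValueError("temporal autocorrelation must lie in [0, 1)")
        if min(self.current_std, self.wind_std, self.sst_std, self.salinity_std) < 0:
            raise ValueError("perturbation standard deviations must be >= 0")


#: Default seasonal mean states for the idealised channel.  Summer flow is
#: south-east-ward (u > 0, v < 0); winter flow is northward along the axis.
SEASON_DEFAULTS: dict[str, VariabilityConfig] = {
    "summer": VariabilityConfig(mean_current=(0.01, -0.12), mean_wind=(0.5, -3.5), sst_mean=31.0),
    "winter": VariabilityConfig(mean_current=(0.0, 0.12), mean_wind=(0.5, 3.5), sst_mean=27.0),
    "spring": VariabilityConfig(mean_current=(0.05, 0.02), mean_wind=(1.0, 0.5), sst_mean=29.0),
    "autumn": VariabilityConfig(mean_current=(0.02, 0.05), mean_wind=(0.5, 1.5), sst_mean=30.0),
}


@dataclass
class EnvironmentFields:
    """Gridded forcing over (time, lat, lon), all arrays float64."""

    grid: GridSpec
    wind_u: np.ndarray
    wind_v: np.ndarray
    current_u: np.ndarray
    current_v: np.ndarray
    sst: np.ndarray
    salinity: np.ndarray
    season: str = "summer"

    def __post_init__(self) -> None:
        shape = (self.grid.n_time, self.grid.n_lat, self.grid.n_lon)
        for name in ("wind_u", "wind_v", "current_u", "current_v", "sst", "salinity"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)

    def forcing_at(self, t_index: int, lons, lats):
        """Bilinear (current_u, current_v, wind_u, wind_v) at points."""
        g = self.grid
        args = (g.lats, g.lons)
        return (
            bilinear_on_regular(*args, self.current_u[t_index], lats, lons),
            bilinear_on_regular(*args, self.current_v[t_index], lats, lons),
            bilinear_on_regular(*args, self.wind_u[t_index], lats, lons),
            bilinear_on_regular(*args, self.wind_v[t_index], lats, lons),
        )

    def wind_at(self, t_index: int, lons, lats):
        g = self.grid
        return (
            bilinear_on_regular(g.lats, g.lons, self.wind_u[t_index], lats, lons),
            bilinear_on_regular(g.lats, g.lons, self.wind_v[t_index], lats, lons),
        )

    def to_dataset(self) -> xr.Dataset:
        g = self.grid
        coords = {"time": g.times, "lat": g.lats, "lon": g.lons}
        data = {
            "u10": self.wind_u,
            "v10": self.wind_v,
            "water_u": self.current_u,
            "water_v": self.current_v,
            "water_temp": self.sst,
            "salinity": self.salinity,
        }
        ds = xr.Dataset(
            {k: (("time", "lat", "lon"), v, {"units": ENV_VARS[k]}) for k, v in data.items()},
            coords=coords,
            attrs={"season": self.season, "cell_size": g.cell_size, "t_step_h": g.t_step_h},
        )
        return ds

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "EnvironmentFields":
        for name, units in ENV_VARS.items():
            if name not in ds:
                raise MissingVariableError(f"missing variable: {name}")
            declared = ds[name].attrs.get("units")
            if declared is not None and declared != units:
                raise UnitMismatchError(f"{name} has units {declared!r}, expected {units!r}")
        # normalise axis order to ascending
        if ds.lat.size > 1 and float(ds.lat[1]) < float(ds.lat[0]):
            ds = ds.isel(lat=slice(None, None, -1))
        if ds.lon.size > 1 and float(ds.lon[1]) < float(ds.lon[0]):
            ds = ds.isel(lon=slice(None, None, -1))
        lats = ds.lat.values.astype(float)
        lons = ds.lon.values.astype(float)
        times = pd.DatetimeIndex(ds.time.values)
        cell = float(ds.attrs.get("cell_size", lats[1] - lats[0] if lats.size > 1 else 1.0))
        t_step = float(
            ds.attrs.get(
                "t_step_h",
                (times[1] - times[0]) / pd.Timedelta(hours=1) if len(times) > 1 else 1.0,
            )
        )
        grid = GridSpec(
            lat_min=float(lats[0] - cell / 2),
            lat_max=float(lats[-1] + cell / 2),
            lon_min=float(lons[0] - cell / 2),
            lon_max=float(lons[-1] + cell / 2),
            cell_size=cell,
            t_start=times[0],
            t_end=times[-1],
            t_step_h=t_step,
        )
        return cls(
            grid=grid,
            wind_u=ds["u10"].values,
            wind_v=ds["v10"].values,
            current_u=ds["water_u"].values,
            current_v=ds["water_v"].values,
            sst=ds["water_temp"].values,
            salinity=ds["salinity"].values,
            season=str(ds.attrs.get("season", "summer")),
        )


# ---------------------------------------------------------------------------
# synthetic generators
# ---------------------------------------------------------------------------

_SMOOTH_FACTORS: dict[tuple[int, int, float], float] = {}


def _smooth_unit_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float):
    """Spatially smoothed white noise renormalised to unit marginal variance.

    Smoothing uses wrap-around boundaries so the variance reduction factor
    is uniform across the grid and can be computed once from the kernel's
    impulse response.
    """
    w = rng.standard_normal(shape)
    if sigma <= 0:
        return w
    key = (shape[0], shape[1], float(sigma))
    factor = _SMOOTH_FACTORS.get(key)
    if factor is None:
        delta = np.zeros(shape)
        delta[0, 0] = 1.0
        kernel = gaussian_filter(delta, sigma, mode="wrap")
        factor = float(np.sqrt((kernel**2).sum()))
        _SMOOTH_FACTORS[key] = factor
    return gaussian_filter(w, sigma, mode="wrap") / factor


def _ar1_series(rng, n_t, shape, mean, std, phi, sigma):
    """Stationary AR(1) field sequence: x_t = mean + e_t, e_t = phi e_{t-1} + ..."""
    out = np.empty((n_t, *shape))
    if std == 0.0:
        out[:] = mean
        return out
    e = std * _smooth_unit_noise(rng, shape, sigma)
    out[0] = mean + e
    innov_scale = std * np.sqrt(1.0 - phi**2)
    for t in range(1, n_t):
        e = phi * e + innov_scale * _smooth_unit_noise(rng, shape, sigma)
        out[t] = mean + e
    return out


def _cap_vector(u, v, cap):
    speed = np.hypot(u, v)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(speed > cap, cap / np.where(speed == 0, 1.0, speed), 1.0)
    return u * scale, v * scale


def generate_environment(
    spec: GridSpec,
    season: str = "summer",
    params: VariabilityConfig | None = None,
    seed: int = 0,
) -> EnvironmentFields:
    """Draw seed-reproducible synthetic forcing fields on ``spec``.

    Identical ``(spec, season, params, seed)`` produce bit-identical
    arrays.  Current and wind vectors are capped at the configured maxima
    by rescaling, never clipping componentwise.
    """
    if not spec.has_time:
        raise ValueError("environment generation requires a time axis")
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}")
    p = params if params is not None else SEASON_DEFAULTS[season]
    rng = np.random.default_rng(seed)
    n_t, shape = spec.n_time, (spec.n_lat, spec.n_lon)
    sig = p.spatial_sigma_cells

    cu = _ar1_series(rng, n_t, shape, p.mean_current[0], p.current_std, p.ar1, sig)
    cv = _ar1_series(rng, n_t, shape, p.mean_current[1], p.current_std, p.ar1, sig)
    wu = _ar1_series(rng, n_t, shape, p.mean_wind[0], p.wind_std, p.ar1, sig)
    wv = _ar1_series(rng, n_t, shape, p.mean_wind[1], p.wind_std, p.ar1, sig)
    sst = _ar1_series(rng, n_t, shape, p.sst_mean, p.sst_std, p.ar1, sig)
    sal = np.maximum(
        _ar1_series(rng, n_t, shape, p.salinity_mean, p.salinity_std, p.ar1, sig), 0.0
    )
    cu, cv = _cap_vector(cu, cv, p.current_cap)
    wu, wv = _cap_vector(wu, wv, p.wind_cap)
    return EnvironmentFields(
        grid=spec, wind_u=wu, wind_v=wv, current_u=cu, current_v=cv,
        sst=sst, salinity=sal, season=season,
    )


def constant_fields(
    spec: GridSpec,
    current=(0.0, 0.0),
    wind=(0.0, 0.0),
    sst: float = 29.0,
    salinity: float = 40.0,
    season: str = "summer",
) -> EnvironmentFields:
    """Spatially and temporally constant forcing (oracle/test helper)."""
    shape = (spec.n_time, spec.n_lat, spec.n_lon)
    full = lambda v: np.full(shape, float(v))
    return EnvironmentFields(
        grid=spec,
        wind_u=full(wind[0]), wind_v=full(wind[1]),
        current_u=full(current[0]), current_v=full(current[1]),
        sst=full(sst), salinity=full(salinity), season=season,
    )


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------


@dataclass
class PopulationGrid:
    """Persons per cell on a time-invariant grid; integer counts."""

    grid: GridSpec
    count: np.ndarray

    def __post_init__(self) -> None:
        self.count = np.asarray(self.count)
        if self.count.shape != (self.grid.n_lat, self.grid.n_lon):
            raise ValueError("count shape does not match grid")
        if (self.count < 0).any():
            raise ValueError("population counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.count.sum())


def generate_population(
    spec: GridSpec,
    total: int,
    hotspots: list[tuple[float, float, float]],
    seed: int = 0,
    sigma_deg: float = 0.5,
    land_mask: LandMask | None = None,
) -> PopulationGrid:
    """Gaussian-kernel population mixture around hotspots.

    Counts are conserved exactly: cell weights are scaled to ``total`` and
    rounded by the largest-remainder rule, so the grid sum equals ``total``
    for any weights.  If a land mask is given, population is placed on
    land cells only.
    """
    if total < 0:
        raise ValueError("total must be >= 0")
    g = spec.spatial()
    if total == 0:
        return PopulationGrid(grid=g, count=np.zeros((g.n_lat, g.n_lon), dtype=np.int64))
    if not hotspots:
        raise ValueError("hotspot list may not be empty when total > 0")
    if any(w < 0 for _, _, w in hotspots):
        raise ValueError("hotspot weights must be >= 0")

    lat2, lon2 = np.meshgrid(g.lats, g.lons, indexing="ij")
    dens = np.zeros_like(lat2)
    for lon0, lat0, w in hotspots:
        d2 = (lat2 - lat0) ** 2 + (lon2 - lon0) ** 2
        dens += w * np.exp(-d2 / (2.0 * sigma_deg**2))
    if land_mask is not None:
        dens = np.where(land_mask.land, dens, 0.0)
    if dens.sum() <= 0:
        raise ValueError("population density is identically zero (all hotspots masked?)")

    target = total * dens / dens.sum()
    base = np.floor(target).astype(np.int64)
    remainder = int(total - base.sum())
    if remainder:
        frac = (target - base).ravel()
        order = np.argsort(-frac, kind="stable")
        base.ravel()[order[:remainder]] += 1
    return PopulationGrid(grid=g, count=base)


# ---------------------------------------------------------------------------
# assets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Port:
    name: str
    lon: float
    lat: float
    food_aid_share: float = 0.0
    monthly_fuel_tons: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.food_aid_share <= 1.0):
            raise ValueError("food_aid_share must lie in [0, 1]")
        if self.monthly_fuel_tons < 0:
            raise ValueError("monthly_fuel_tons must be >= 0")


@dataclass(frozen=True)
class DesalinationPlant:
    name: str
    lon: float
    lat: float
    capacity_m3_per_day: float | None  # None: allocate from country capacity
    country: str

    def __post_init__(self) -> None:
        if self.capacity_m3_per_day is not None and self.capacity_m3_per_day < 0:
            raise ValueError("capacity must be >= 0")


@dataclass
class FisheryYieldGrid:
    """Gridded annual fish yield (metric tons / yr) with a region label per cell."""

    grid: GridSpec
    yield_tons: np.ndarray
    region: np.ndarray  # object array of labels, "" = no fishery

    def __post_init__(self) -> None:
        self.yield_tons = np.asarray(self.yield_tons, dtype=float)
        self.region = np.asarray(self.region, dtype=object)
        shape = (self.grid.n_lat, self.grid.n_lon)
        if self.yield_tons.shape != shape or self.region.shape != shape:
            raise ValueError("fishery arrays do not match grid")
        if (self.yield_tons < 0).any():
            raise ValueError("fishery yield must be >= 0")


@dataclass
class AssetLayer:
    ports: list[Port] = field(default_factory=list)
    plants: list[DesalinationPlant] = field(default_factory=list)
    fishery: FisheryYieldGrid | None = None


def write_assets(layer: AssetLayer, path) -> None:
    """Ports and desalination plants as a GeoJSON FeatureCollection."""
    feats = []
    for p in layer.ports:
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [p.lon, p.lat]},
                "properties": {
                    "kind": "port",
                    "name": p.name,
                    "food_aid_share": p.food_aid_share,
                    "monthly_fuel_tons": p.monthly_fuel_tons,
                },
            }
        )
    for d in layer.plants:
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [d.lon, d.lat]},
                "properties": {
                    "kind": "desalination_plant",
                    "name": d.name,
                    "capacity_m3_per_day": d.capacity_m3_per_day,
                    "country": d.country,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1)


def read_assets(path) -> AssetLayer:
    with open(path) as fh:
        gj = json.load(fh)
    layer = AssetLayer()
    for feat in gj.get("features", []):
        props = feat.get("properties", {})
        lon, lat = feat["geometry"]["coordinates"]
        if props.get("kind") == "port":
            layer.ports.append(
                Port(
                    name=props["name"], lon=lon, lat=lat,
                    food_aid_share=props.get("food_aid_share", 0.0),
                    monthly_fuel_tons=props.get("monthly_fuel_tons", 0.0),
                )
            )
        elif props.get("kind") == "desalination_plant":
            layer.plants.append(
                DesalinationPlant(
                    name=props["name"], lon=lon, lat=lat,
                    capacity_m3_per_day=props.get("capacity_m3_per_day"),
                    country=props.get("country", ""),
                )
            )
    return layer


def write_fishery_csv(fishery: FisheryYieldGrid, path) -> None:
    g = fishery.grid
    lat2, lon2 = np.meshgrid(g.lats, g.lons, indexing="ij")
    df = pd.DataFrame(
        {
            "lat": lat2.ravel(),
            "lon": lon2.ravel(),
            "yield_tons": fishery.yield_tons.ravel(),
            "region": fishery.region.ravel(),
        }
    )
    df[df["yield_tons"] > 0].to_csv(path, index=False)


def read_fishery_csv(path, grid: GridSpec) -> FisheryYieldGrid:
    g = grid.spatial()
    df = pd.read_csv(path)
    yld = np.zeros((g.n_lat, g.n_lon))
    reg = np.full((g.n_lat, g.n_lon), "", dtype=object)
    iy, ix = g.cell_index(df["lon"].values, df["lat"].values)
    for y, x, v, r in zip(iy, ix, df["yield_tons"].values, df["region"].values):
        yld[y, x] += v
        reg[y, x] = r
    return FisheryYieldGrid(grid=g, yield_tons=yld, region=reg)


# ---------------------------------------------------------------------------
# gridded environment I/O
# ---------------------------------------------------------------------------


def write_environment(fields: EnvironmentFields, path) -> None:
    """Self-describing gridded file (NetCDF classic via the scipy backend).

    Double precision is preserved, so write followed by read round-trips
    bit-exactly.
    """
    fields.to_dataset().to_netcdf(path, engine="scipy")


def read_environment(path) -> EnvironmentFields:
    with xr.open_dataset(path, engine="scipy") as ds:
        return EnvironmentFields.from_dataset(ds.load())
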