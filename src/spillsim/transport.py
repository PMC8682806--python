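"""Lagrangian surface-oil transport with Monte Carlo trajectory ensembles.

Each simulated spill releases sizeless particles carrying a surface-oil
thickness proxy from the source over the release window.  Every time step
applies deterministic advection — surface current plus a per-particle
windage fraction of the 10 m wind — followed by a Gaussian random-walk
diffusion step, using forward Euler with a sub-15-minute default step.
Particles crossing the land mask are beached at their last water position
and never move again; particles leaving the forcing domain are frozen and
excluded from concentration accounting.

Alongside the base ensemble, each simulation runs an equally sized
*uncertainty* ensemble under perturbed forcing (currents and windage
scaled by a per-simulation factor, diffusivity doubled).  The convex hull
of all uncertainty-particle locations across all simulations approximates
a 90% trajectory region.

Per-cell average surface values across simulations are collected on a
rounded lat/lon grid (3 decimals ~ 100 m, 2 decimals ~ 1.1 km), converted
to percentile ranks among exposed cells, and queried by bilinear
interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.stats import rankdata
from shapely.geometry import MultiPoint

from .environment import EnvironmentFields
from .errors import DegenerateGeometryError, OutsideDomainError
from .grids import LandMask, metres_per_degree

FLOATING, BEACHED, OUT_OF_DOMAIN = 0, 1, 2


@dataclass(frozen=True)
class TrajectoryConfig:
    """Ensemble and integration settings for the spill-trajectory model."""

    n_particles: int = 1000
    n_simulations: int = 1000
    horizon_days: float = 21.0
    release_duration_h: float = 168.0  # 7-day spill; 24 h variant available
    windage: tuple[float, float] = (0.01, 0.04)
    diffusivity: float = 10.0  # m^2/s (1e5 cm^2/s)
    dt_minutes: float = 15.0
    concentration_decimals: int = 3
    uncertainty_scale: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.n_simulations < 1:
            raise ValueError("particle and simulation counts must be >= 1")
        w_lo, w_hi = self.windage
        if not (0.0 <= w_lo <= w_hi < 1.0):
            raise ValueError("windage interval must satisfy 0 <= lo <= hi < 1")
        if self.diffusivity < 0:
            raise ValueError("diffusivity must be >= 0")
        if self.dt_minutes <= 0:
            raise ValueError("dt must be positive")
        if self.horizon_days * 24.0 < self.release_duration_h:
            raise ValueError("horizon must cover the release duration")
        if self.uncertainty_scale < 1.0:
            raise ValueError("uncertainty_scale must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.horizon_days * 24.0 * 60.0 / self.dt_minutes))


@dataclass
class ParticleEnsemble:
    """State arrays for one simulation's particles (struct-of-arrays)."""

    lon: np.ndarray
    lat: np.ndarray
    value: np.ndarray  # surface-oil thickness proxy per particle
    status: np.ndarray  # FLOATING / BEACHED / OUT_OF_DOMAIN
    windage: np.ndarray
    release_step: np.ndarray
    is_uncertainty: bool = False
    forcing_scale: float = 1.0

    @classmethod
    def at_source(
        cls,
        n: int,
        source: tuple[float, float],
        windage_range: tuple[float, float],
        release_steps: np.ndarray,
        rng: np.random.Generator,
        is_uncertainty: bool = False,
        forcing_scale: float = 1.0,
    ) -> "ParticleEnsemble":
        lon0, lat0 = source
        return cls(
            lon=np.full(n, float(lon0)),
            lat=np.full(n, float(lat0)),
            value=np.full(n, 1.0 / n),
            status=np.zeros(n, dtype=np.int8),
            windage=rng.uniform(windage_range[0], windage_range[1], n),
            release_step=np.asarray(release_steps),
            is_uncertainty=is_uncertainty,
            forcing_scale=float(forcing_scale),
        )

    def status_counts(self) -> dict[str, int]:
        return {
            "floating": int((self.status == FLOATING).sum()),
            "beached": int((self.status == BEACHED).sum()),
            "out_of_domain": int((self.status == OUT_OF_DOMAIN).sum()),
        }


# ---------------------------------------------------------------------------
# elementary steps
# ---------------------------------------------------------------------------


def advect_step(lon, lat, current_u, current_v, wind_u, wind_v, windage, dt_s):
    """Deterministic displacement by current + windage * wind over ``dt_s``.

    Velocities are m/s; the metre displacement is converted to degrees
    with the local metres-per-degree factors at the particle latitude.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    u = np.asarray(current_u) + np.asarray(windage) * np.asarray(wind_u)
    v = np.asarray(current_v) + np.asarray(windage) * np.asarray(wind_v)
    m_lat, m_lon = metres_per_degree(lat)
    return lon + u * dt_s / m_lon, lat + v * dt_s / m_lat


def diffuse_step(lon, lat, diffusivity, dt_s, rng):
    """Random-walk closure: i.i.d. Gaussian jumps with variance 2 D dt per axis."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if diffusivity == 0.0:
        return lon.copy(), lat.copy()
    sigma = np.sqrt(2.0 * diffusivity * dt_s)
    dx = rng.normal(0.0, sigma, lon.shape)
    dy = rng.normal(0.0, sigma, lat.shape)
    m_lat, m_lon = metres_per_degree(lat)
    return lon + dx / m_lon, lat + dy / m_lat


# ---------------------------------------------------------------------------
# concentration field
# ---------------------------------------------------------------------------


def _cell_keys(lats, lons, decimals: int):
    scale = 10.0**decimals
    ikey_lat = np.rint(np.asarray(lats, dtype=float) * scale).astype(np.int64)
    ikey_lon = np.rint(np.asarray(lons, dtype=float) * scale).astype(np.int64)
    return ikey_lat, ikey_lon


def _cell_sums(lats, lons, values, decimals: int) -> dict[tuple[int, int], float]:
    """Sum particle values per rounded cell for one simulation snapshot."""
    if len(lats) == 0:
        return {}
    ila, ilo = _cell_keys(lats, lons, decimals)
    keys = np.stack([ila, ilo], axis=1)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    sums = np.bincount(inverse, weights=np.asarray(values, dtype=float))
    return {(int(a), int(b)): float(s) for (a, b), s in zip(uniq, sums)}


class SurfaceConcentrationField:
    """Sparse per-cell mean surface-oil values on a rounded lat/lon grid.

    Cells never visited by any simulation are *absent*, which is distinct
    from an explicit zero; percentile ranks are computed among exposed
    (present) cells only.
    """

    def __init__(self, cells: dict[tuple[int, int], float], decimals: int, n_simulations: int):
        self.cells = dict(cells)
        self.decimals = int(decimals)
        self.n_simulations = int(n_simulations)
        if any(v < 0 for v in self.cells.values()):
            raise ValueError("surface values must be >= 0")

    @property
    def step(self) -> float:
        return 10.0**-self.decimals

    def __len__(self) -> int:
        return len(self.cells)

    def items(self):
        """Yield (lat, lon, value) over exposed cells."""
        s = self.step
        for (ila, ilo), v in self.cells.items():
            yield ila * s, ilo * s, v

    def to_dataframe(self) -> pd.DataFrame:
        rows = list(self.items())
        return pd.DataFrame(rows, columns=["lat", "lon", "value"])

    def bounds(self):
        """(lon_min, lat_min, lon_max, lat_max) of exposed cell centres."""
        if not self.cells:
            raise ValueError("empty field has no bounds")
        ilats = [k[0] for k in self.cells]
        ilons = [k[1] for k in self.cells]
        s = self.step
        return min(ilons) * s, min(ilats) * s, max(ilons) * s, max(ilats) * s

    def percentile_transform(self) -> "SurfaceConcentrationField":
        """Map each exposed cell to its percentile rank in [0, 100].

        Convention: 100 * (fraction of exposed cells with value <= x); tied
        values share the highest rank, so a constant field ranks at 100.
        Invariant under strictly increasing rescaling of the values.
        """
        if not self.cells:
            raise ValueError("cannot rank an empty field")
        keys = list(self.cells.keys())
        vals = np.array([self.cells[k] for k in keys])
        ranks = rankdata(vals, method="max") / vals.size * 100.0
        return SurfaceConcentrationField(
            dict(zip(keys, ranks)), self.decimals, self.n_simulations
        )

    def interpolate(self, lon: float, lat: float) -> float:
        """Bilinear value at a query point; absent neighbour cells count as 0.

        Raises :class:`OutsideDomainError` if the query lies outside the
        bounding box of exposed cell centres.
        """
        lon_min, lat_min, lon_max, lat_max = self.bounds()
        tol = self.step * 1e-6  # guard against float noise at the envelope edge
        if not (
            lon_min - tol <= lon <= lon_max + tol
            and lat_min - tol <= lat <= lat_max + tol
        ):
            raise OutsideDomainError(f"query ({lon}, {lat}) outside field domain")
        s = self.step
        gy = lat / s
        gx = lon / s
        y0 = int(np.floor(gy + 1e-9))
        x0 = int(np.floor(gx + 1e-9))
        fy = gy - y0
        fx = gx - x0
        get = lambda iy, ix: self.cells.get((iy, ix), 0.0)
        return (
            get(y0, x0) * (1 - fy) * (1 - fx)
            + get(y0, x0 + 1) * (1 - fy) * fx
            + get(y0 + 1, x0) * fy * (1 - fx)
            + get(y0 + 1, x0 + 1) * fy * fx
        )


def grid_concentration(snapshots, decimals: int, n_simulations: int | None = None):
    """Average per-cell surface values across simulation snapshots.

    ``snapshots`` is a sequence over simulations of ``(lats, lons, values)``
    particle arrays.  Within a simulation, particle values falling in the
    same cell add; across simulations the per-cell mean divides by the
    total number of simulations, counting zero for simulations that never
    touched the cell.
    """
    snapshots = list(snapshots)
    if not snapshots:
        raise ValueError("at least one simulation snapshot is required")
    n_sims = n_simulations if n_simulations is not None else len(snapshots)
    sums: dict[tuple[int, int], float] = {}
    for lats, lons, values in snapshots:
        for key, v in _cell_sums(lats, lons, values, decimals).items():
            sums[key] = sums.get(key, 0.0) + v
    return SurfaceConcentrationField(
        {k: v / n_sims for k, v in sums.items()}, decimals, n_sims
    )


# ---------------------------------------------------------------------------
# uncertainty region
# ---------------------------------------------------------------------------


@dataclass
class UncertaintyRegion:
    """Convex envelope of uncertainty-particle locations."""

    polygon: shapely.Polygon
    coverage_note: str = "approximately 90% of trajectories"

    @property
    def area(self) -> float:
        return float(self.polygon.area)

    def contains_all(self, lons, lats) -> bool:
        pts = shapely.points(np.column_stack([lons, lats]))
        return bool(np.all(shapely.covers(self.polygon, pts)))

    def to_geojson(self) -> dict:
        return {
            "type": "Feature",
            "geometry": shapely.geometry.mapping(self.polygon),
            "properties": {"coverage_note": self.coverage_note},
        }


def uncertainty_region(lons, lats) -> UncertaintyRegion:
    """Minimal convex polygon containing every uncertainty-particle location."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if lons.size < 3:
        raise DegenerateGeometryError("need at least 3 points for a convex hull")
    hull = MultiPoint(np.column_stack([lons, lats])).convex_hull
    if hull.geom_type != "Polygon":
        raise DegenerateGeometryError("points are collinear; hull is degenerate")
    return UncertaintyRegion(polygon=hull)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Per-simulation snapshots at week marks plus final particle state."""

    week_snapshots: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]
    uncertainty_positions: dict[int, tuple[np.ndarray, np.ndarray]]
    base: ParticleEnsemble
    uncertainty: ParticleEnsemble
    source: tuple[float, float]


def _release_steps(config: TrajectoryConfig) -> np.ndarray:
    """Release step index per particle, uniform over the release window."""
    release_steps_total = config.release_duration_h * 60.0 / config.dt_minutes
    return np.floor(
        np.linspace(0.0, release_steps_total, config.n_particles, endpoint=False)
    ).astype(int)


def _step_ensemble(ens, released, fields, land_mask, t_index, dt_s, diffusivity, rng):
    active = (ens.status == FLOATING) & released
    if not active.any():
        return
    lon = ens.lon[active]
    lat = ens.lat[active]
    cu, cv, wu, wv = fields.forcing_at(t_index, lon, lat)
    s = ens.forcing_scale
    new_lon, new_lat = advect_step(
        lon, lat, cu * s, cv * s, wu, wv, ens.windage[active] * s, dt_s
    )
    new_lon, new_lat = diffuse_step(new_lon, new_lat, diffusivity, dt_s, rng)

    g = fields.grid
    out = ~g.contains(new_lon, new_lat)
    landed = np.zeros_like(out)
    if land_mask is not None:
        landed = land_mask.is_land(new_lon, new_lat) & ~out

    keep = ~(out | landed)
    idx = np.flatnonzero(active)
    ens.lon[idx[keep]] = new_lon[keep]
    ens.lat[idx[keep]] = new_lat[keep]
    # beached particles anchor at their last water position; out-of-domain
    # particles freeze where they were last seen inside the domain
    ens.status[idx[landed]] = BEACHED
    ens.status[idx[out]] = OUT_OF_DOMAIN


def run_simulation(
    config: TrajectoryConfig,
    fields: EnvironmentFields,
    source: tuple[float, float],
    land_mask: LandMask | None = None,
    rng: np.random.Generator | None = None,
    start_offset_h: float = 0.0,
) -> SimulationResult:
    """Run one spill simulation (base + uncertainty particle ensembles).

    Particles are released uniformly over the release window, advected and
    diffused each step, beached on land crossing and frozen on domain
    exit.  Snapshots of the base ensemble (floating and beached particles)
    are recorded at the ends of weeks 1..3 that fit in the horizon, as are
    uncertainty-particle positions.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lon0, lat0 = source
    if land_mask is not None and bool(land_mask.is_land([lon0], [lat0])[0]):
        raise ValueError("spill source lies on land")
    if not bool(fields.grid.contains([lon0], [lat0])[0]):
        raise OutsideDomainError("spill source outside the forcing domain")

    rel = _release_steps(config)
    base = ParticleEnsemble.at_source(
        config.n_particles, source, config.windage, rel, rng
    )
    unc_scale = float(rng.uniform(1.0, config.uncertainty_scale))
    unc = ParticleEnsemble.at_source(
        config.n_particles, source, config.windage, rel, rng,
        is_uncertainty=True, forcing_scale=unc_scale,
    )

    dt_s = config.dt_minutes * 60.0
    week_steps = {
        w: int(round(w * 7 * 24 * 60.0 / config.dt_minutes))
        for w in (1, 2, 3)
        if w * 7 <= config.horizon_days + 1e-9
    }
    week_snapshots: dict[int, tuple] = {}
    unc_positions: dict[int, tuple] = {}

    n_steps = config.n_steps
    for k in range(1, n_steps + 1):
        t_index = fields.grid.time_index(start_offset_h + k * config.dt_minutes / 60.0)
        # particles not yet released stay at the source
        _step_ensemble(base, base.release_step < k, fields, land_mask, t_index,
                       dt_s, config.diffusivity, rng)
        _step_ensemble(unc, unc.release_step < k, fields, land_mask, t_index,
                       dt_s, 2.0 * config.diffusivity, rng)
        for w, ws in week_steps.items():
            if k == ws:
                keep = base.status != OUT_OF_DOMAIN
                week_snapshots[w] = (
                    base.lat[keep].copy(), base.lon[keep].copy(), base.value[keep].copy()
                )
                ukeep = unc.status != OUT_OF_DOMAIN
                unc_positions[w] = (unc.lat[ukeep].copy(), unc.lon[ukeep].copy())
    return SimulationResult(
        week_snapshots=week_snapshots,
        uncertainty_positions=unc_positions,
        base=base,
        uncertainty=unc,
        source=source,
    )


@dataclass
class SpillEnsembleResult:
    """Aggregated output of a Monte Carlo spill ensemble."""

    fields_by_week: dict[int, SurfaceConcentrationField]
    region: UncertaintyRegion | None
    uncertainty_points: tuple[np.ndarray, np.ndarray]  # (lons, lats)
    mean_final_dlon: float
    mean_final_dlat: float
    config: TrajectoryConfig
    season: str


def run_ensemble(
    config: TrajectoryConfig,
    fields: EnvironmentFields,
    source: tuple[float, float],
    land_mask: LandMask | None = None,
) -> SpillEnsembleResult:
    """Monte Carlo over ``n_simulations`` spills with varying start times.

    Start times are sampled uniformly over the forcing period (leaving
    room for the simulation horizon), emulating variation of date and time
    of day within a season.
    """
    master = np.random.default_rng(config.seed)
    g = fields.grid
    horizon_h = config.horizon_days * 24.0
    max_start = max((g.n_time - 1) * g.t_step_h - horizon_h, 0.0)

    week_sums: dict[int, dict[tuple[int, int], float]] = {}
    unc_lons: list[np.ndarray] = []
    unc_lats: list[np.ndarray] = []
    dlon_sum = 0.0
    dlat_sum = 0.0
    n_disp = 0

    for _ in range(config.n_simulations):
        rng = np.random.default_rng(int(master.integers(2**31)))
        start = float(rng.uniform(0.0, max_start)) if max_start > 0 else 0.0
        sim = run_simulation(config, fields, source, land_mask, rng, start)
        for w, (lats, lons, values) in sim.week_snapshots.items():
            acc = week_sums.setdefault(w, {})
            for key, v in _cell_sums(lats, lons, values, config.concentration_decimals).items():
                acc[key] = acc.get(key, 0.0) + v
        for w, (lats, lons) in sim.uncertainty_positions.items():
            unc_lats.append(lats)
            unc_lons.append(lons)
        ok = sim.base.status != OUT_OF_DOMAIN
        dlon_sum += float((sim.base.lon[ok] - source[0]).sum())
        dlat_sum += float((sim.base.lat[ok] - source[1]).sum())
        n_disp += int(ok.sum())

    fields_by_week = {
        w: SurfaceConcentrationField(
            {k: v / config.n_simulations for k, v in acc.items()},
            config.concentration_decimals,
            config.n_simulations,
        )
        for w, acc in week_sums.items()
    }
    all_lons = np.concatenate(unc_lons) if unc_lons else np.array([])
    all_lats = np.concatenate(unc_lats) if unc_lats else np.array([])
    region = None
    if all_lons.size >= 3:
        try:
            region = uncertainty_region(all_lons, all_lats)
        except DegenerateGeometryError:
            region = None
    return SpillEnsembleResult(
        fields_by_week=fields_by_week,
        region=region,
        uncertainty_points=(all_lons, all_lats),
        mean_final_dlon=dlon_sum / max(n_disp, 1),
        mean_final_dlat=dlat_sum / max(n_disp, 1),
        config=config,
        season=fields.season,
    )


def trajectories_to_csv(sim: SimulationResult, simulation_id: int, path) -> None:
    """Final particle states as CSV (simulation_id, particle_id, lon, lat, ...)."""
    rows = []
    for ens in (sim.base, sim.uncertainty):
        status_names = {FLOATING: "floating", BEACHED: "beached", OUT_OF_DOMAIN: "out_of_domain"}
        for i in range(len(ens.lon)):
            rows.append(
                {
                    "simulation_id": simulation_id,
                    "particle_id": i,
                    "lon": ens.lon[i],
                    "lat": ens.lat[i],
                    "status": status_names[int(ens.status[i])],
                    "is_uncertainty": ens.is_uncertainty,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
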