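"""Atmospheric PM2.5 dispersion from the spill site.

Spilled oil mass is converted to a fine-particulate emission rate
(micrograms per hour) via an oil-to-PM2.5 conversion rate; for a burning
spill the combustion conversion rate adds to the evaporative one.  The
plume is modelled as a single-layer Lagrangian particle cloud: equal-mass
particles released continuously over the emission window are advected by
the 10 m wind plus an isotropic Gaussian turbulent velocity and assumed
mixed through a fixed boundary-layer depth.  Binning particle mass into
grid cells and dividing by cell volume (area x mixing depth) yields
ground-level concentrations; the headline field is the 24-hour average
ending when the release stops, averaged over an ensemble of start times
spread through the season.

Concentration is linear in both the conversion rate and the spilled mass,
which the uncertainty propagation in :mod:`spillsim.health` exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environment import EnvironmentFields
from .errors import OutsideDomainError
from .grids import GridSpec, metres_per_degree

UG_PER_TON = 1e12


@dataclass(frozen=True)
class EmissionScenario:
    """One season x release-duration x mode emission configuration."""

    season: str = "summer"
    release_duration_h: float = 24.0  # 24 fast, 72 slow
    mode: str = "leak"  # or "fire"
    total_oil_mass_tons: float = 150_000.0
    evaporative_conversion_rate: float = 0.008  # ug PM2.5 per ug oil
    combustion_conversion_rate: float = 0.05  # additional, fire mode only
    conversion_rate_sd: float | None = None  # for Monte Carlo; None -> 25% of mean
    source: tuple[float, float] = (42.8, 15.15)

    def __post_init__(self) -> None:
        if self.release_duration_h <= 0:
            raise ValueError("release duration must be positive")
        if self.mode not in ("leak", "fire"):
            raise ValueError("mode must be 'leak' or 'fire'")
        if min(self.evaporative_conversion_rate, self.combustion_conversion_rate) < 0:
            raise ValueError("conversion rates must be >= 0")

    @property
    def conversion_rate(self) -> float:
        """Total ug-PM2.5 per ug-oil; fire adds the combustion rate."""
        if self.mode == "fire":
            return self.evaporative_conversion_rate + self.combustion_conversion_rate
        return self.evaporative_conversion_rate

    @property
    def label(self) -> str:
        speed = "fast" if self.release_duration_h <= 24 else "slow"
        return f"{self.season}-{speed}-{self.mode}"

    @property
    def mass_ug(self) -> float:
        return self.total_oil_mass_tons * UG_PER_TON


def emission_rate(scenario: EmissionScenario) -> float:
    """PM2.5 emission rate in ug/h: mass x conversion rate / duration."""
    return scenario.mass_ug * scenario.conversion_rate / scenario.release_duration_h


@dataclass
class PM25Field:
    """24-h-average ground-level PM2.5 on a regular grid, plus daily fields."""

    grid: GridSpec
    concentration: np.ndarray  # ug/m^3, 24-h average at end of release
    daily: list[np.ndarray]  # one 24-h average per release day
    scenario: str
    conversion_rate: float
    conversion_rate_sd: float
    ensemble_size: int
    mass_audit: dict[str, float]

    def __post_init__(self) -> None:
        if (np.asarray(self.concentration) < 0).any():
            raise ValueError("concentrations must be >= 0")
        if not np.all(np.isfinite(self.concentration)):
            raise ValueError("concentrations must be finite")

    def to_dataframe(self) -> pd.DataFrame:
        g = self.grid
        lat2, lon2 = np.meshgrid(g.lats, g.lons, indexing="ij")
        return pd.DataFrame(
            {
                "lat": lat2.ravel(),
                "lon": lon2.ravel(),
                "pm25_ug_m3": self.concentration.ravel(),
            }
        )


def disperse(
    scenario: EmissionScenario,
    fields: EnvironmentFields,
    out_grid: GridSpec | None = None,
    n_particles: int = 2500,
    run_hours: int = 144,
    n_start_times: int = 8,
    turbulence_std: float = 0.5,
    mixing_depth_m: float = 800.0,
    seed: int = 0,
) -> PM25Field:
    """Lagrangian particle dispersion averaged over an ensemble of starts.

    Each start time runs ``run_hours`` hourly steps with ``n_particles``
    equal-mass particles released evenly over the emission window.  The
    mass audit (in-domain + out-of-domain = emitted) is exact because
    particle masses are equal shares of the emitted total.
    """
    g_out = (out_grid or fields.grid).spatial()
    src_lon, src_lat = scenario.source
    if not bool(fields.grid.contains([src_lon], [src_lat])[0]):
        raise OutsideDomainError("emission source outside the forcing domain")

    emitted_per_start = emission_rate(scenario) * scenario.release_duration_h
    mass_p = emitted_per_start / n_particles
    release_h = scenario.release_duration_h
    n_days = int(np.ceil(release_h / 24.0))
    rng = np.random.default_rng(seed)

    env_grid = fields.grid
    latest_start = max((env_grid.n_time - 1) * env_grid.t_step_h - run_hours, 0.0)
    start_offsets = np.linspace(0.0, latest_start, max(n_start_times, 1))

    cell_rows_area = g_out.cell_area_m2(g_out.lats)  # (n_lat,)
    acc_daily = np.zeros((n_days, g_out.n_lat, g_out.n_lon))
    audit = {"emitted_ug": 0.0, "in_domain_ug": 0.0, "out_of_domain_ug": 0.0}

    for start in start_offsets:
        rel_times = (np.arange(n_particles) + 0.5) * release_h / n_particles
        lon = np.full(n_particles, float(src_lon))
        lat = np.full(n_particles, float(src_lat))
        alive = np.ones(n_particles, dtype=bool)  # inside forcing domain
        for t in range(run_hours):
            released = rel_times <= t + 1.0 - 1e-12
            active = released & alive
            if active.any():
                wu, wv = fields.wind_at(
                    env_grid.time_index(start + t), lon[active], lat[active]
                )
                tu = rng.normal(0.0, turbulence_std, wu.shape)
                tv = rng.normal(0.0, turbulence_std, wv.shape)
                m_lat, m_lon = metres_per_degree(lat[active])
                lon[active] = lon[active] + (wu + tu) * 3600.0 / m_lon
                lat[active] = lat[active] + (wv + tv) * 3600.0 / m_lat
                exited = active & ~env_grid.contains(lon, lat)
                alive[exited] = False
            # deposit the current hour's airborne mass while emitting
            if t < release_h:
                day = int(t // 24)
                dep = released & alive & g_out.contains(lon, lat)
                if dep.any():
                    iy, ix = g_out.cell_index(lon[dep], lat[dep])
                    np.add.at(acc_daily[day], (iy, ix), mass_p)
        audit["emitted_ug"] += mass_p * n_particles
        audit["in_domain_ug"] += mass_p * int(alive.sum())
        audit["out_of_domain_ug"] += mass_p * int((~alive).sum())

    n_starts = len(start_offsets)
    hours_per_day = [min(24.0, release_h - 24.0 * d) for d in range(n_days)]
    cell_volume = cell_rows_area[:, None] * mixing_depth_m
    daily = [
        acc_daily[d] / hours_per_day[d] / cell_volume / n_starts
        for d in range(n_days)
    ]
    return PM25Field(
        grid=g_out,
        concentration=daily[-1],
        daily=daily,
        scenario=scenario.label,
        conversion_rate=scenario.conversion_rate,
        conversion_rate_sd=(
            scenario.conversion_rate_sd
            if scenario.conversion_rate_sd is not None
            else 0.25 * scenario.conversion_rate
        ),
        ensemble_size=n_starts,
        mass_audit=audit,
    )
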