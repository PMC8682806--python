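"""Downstream supply-disruption estimators.

Each estimator is a small, fully specified computation over the surface
concentration fields and the asset layers: port exposure against a
percentile threshold, desalination-capacity disruption with equal
division of unattributed national capacity, fuel-import disruption from a
short monthly series, a two-date fuel price spike, food-aid disruption
from port shares, and fishery-yield loss under optional trace-oil
percentile thresholds.

One quantile convention is used throughout: linear-interpolation sample
quantiles (numpy's default, R type 7), with 95% uncertainty intervals at
the 2.5th and 97.5th percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environment import DesalinationPlant, FisheryYieldGrid, Port
from .errors import OutsideDomainError
from .transport import SurfaceConcentrationField


@dataclass
class PortExposure:
    port: str
    week: int
    percentile: float
    exposed: bool
    warning: str | None = None


def port_exposure(
    field: SurfaceConcentrationField,
    ports: list[Port],
    week: int = 0,
    threshold_percentile: float = 90.0,
) -> list[PortExposure]:
    """Interpolated concentration percentile at each port.

    ``field`` must already be percentile-transformed.  A port is exposed
    iff its bilinear percentile meets the threshold; ports outside the
    field's domain are flagged unexposed with a warning status.
    """
    out = []
    for p in ports:
        try:
            pct = field.interpolate(p.lon, p.lat)
        except OutsideDomainError:
            out.append(PortExposure(p.name, week, 0.0, False, warning="outside domain"))
            continue
        out.append(PortExposure(p.name, week, float(pct), pct >= threshold_percentile))
    return out


def allocate_capacity(
    plants: list[DesalinationPlant],
    country_capacity: dict[str, float] | None = None,
) -> list[DesalinationPlant]:
    """Fill unknown plant capacities by equal division of country capacity.

    Plants with a known capacity keep it; for each country, plants with
    ``capacity_m3_per_day=None`` share that country's configured capacity
    equally.  Conservation is exact: the allocated capacities of a
    country's unknown plants sum to the configured country capacity.
    """
    country_capacity = country_capacity or {}
    unknown_by_country: dict[str, int] = {}
    for p in plants:
        if p.capacity_m3_per_day is None:
            unknown_by_country[p.country] = unknown_by_country.get(p.country, 0) + 1
    for country, cap in country_capacity.items():
        if cap > 0 and unknown_by_country.get(country, 0) == 0:
            raise ValueError(
                f"country capacity configured for {country!r} but no plants to allocate it to"
            )
    out = []
    for p in plants:
        if p.capacity_m3_per_day is None:
            cap = country_capacity.get(p.country, 0.0) / unknown_by_country[p.country]
            out.append(DesalinationPlant(p.name, p.lon, p.lat, cap, p.country))
        else:
            out.append(p)
    return out


@dataclass
class DesalinationImpact:
    """Disrupted desalination capacity and its population equivalent."""

    plants: list[tuple[DesalinationPlant, bool]]  # (plant with capacity, disrupted)
    total_disrupted_m3_day: float
    population_equivalent: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": p.name,
                    "country": p.country,
                    "capacity_m3_per_day": p.capacity_m3_per_day,
                    "disrupted": d,
                }
                for p, d in self.plants
            ]
        )


def desal_disruption(
    field: SurfaceConcentrationField,
    plants: list[DesalinationPlant],
    per_capita_use_m3: dict[str, float],
    country_capacity: dict[str, float] | None = None,
) -> DesalinationImpact:
    """Plants reached by any oil are disrupted; totals and person-equivalents.

    A plant is "reached" when the bilinear mean surface concentration at
    its location is positive.  The population equivalent divides each
    country's disrupted capacity by that country's per-capita daily use.
    """
    for use in per_capita_use_m3.values():
        if use <= 0:
            raise ValueError("per-capita water use must be positive")
    resolved = allocate_capacity(plants, country_capacity)
    rows = []
    total = 0.0
    pop_equiv = 0.0
    for p in resolved:
        try:
            disrupted = field.interpolate(p.lon, p.lat) > 0.0
        except OutsideDomainError:
            disrupted = False
        rows.append((p, disrupted))
        if disrupted:
            total += p.capacity_m3_per_day
            use = per_capita_use_m3.get(p.country)
            if use is None:
                raise ValueError(f"no per-capita use configured for {p.country!r}")
            pop_equiv += p.capacity_m3_per_day / use
    return DesalinationImpact(
        plants=rows, total_disrupted_m3_day=total, population_equivalent=pop_equiv
    )


@dataclass
class SeriesEstimate:
    mean: float
    lo95: float
    hi95: float
    n: int


def fuel_disruption(monthly_imports_tons) -> SeriesEstimate:
    """Mean and 95% UI of monthly fuel imports through the affected ports."""
    x = np.asarray(monthly_imports_tons, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two monthly observations")
    return SeriesEstimate(
        mean=float(x.mean()),
        lo95=float(np.quantile(x, 0.025)),
        hi95=float(np.quantile(x, 0.975)),
        n=int(x.size),
    )


def price_spike(prices_t0: dict[str, float], prices_t1: dict[str, float]) -> float:
    """Percent change of the median price across fuels between two dates."""
    common = sorted(set(prices_t0) & set(prices_t1))
    if not common:
        raise ValueError("no fuel type present at both dates")
    m0 = float(np.median([prices_t0[f] for f in common]))
    m1 = float(np.median([prices_t1[f] for f in common]))
    if m0 == 0:
        raise ValueError("baseline median price is zero")
    return 100.0 * (m1 - m0) / m0


def food_aid_disruption(
    port_shares: dict[str, float],
    targeted_series,
    disrupted_ports,
) -> SeriesEstimate:
    """People whose food aid is disrupted by the given port closures.

    Point estimate: (sum of disrupted ports' aid shares) x mean of the
    monthly people-targeted series; the UI multiplies the share by the
    series' 2.5th/97.5th quantiles.
    """
    x = np.asarray(targeted_series, dtype=float)
    if x.size == 0:
        raise ValueError("targeted series is empty")
    for name, share in port_shares.items():
        if not (0.0 <= share <= 1.0):
            raise ValueError(f"share for {name!r} outside [0, 1]")
    share = sum(port_shares.get(name, 0.0) for name in disrupted_ports)
    return SeriesEstimate(
        mean=share * float(x.mean()),
        lo95=share * float(np.quantile(x, 0.025)),
        hi95=share * float(np.quantile(x, 0.975)),
        n=int(x.size),
    )


@dataclass
class FisheryLoss:
    week: int
    season: str
    threshold: float | None  # percentile threshold, None = no threshold
    threatened_fraction_pct: float
    region: str


def fishery_loss(
    field: SurfaceConcentrationField,
    fishery: FisheryYieldGrid,
    region: str,
    threshold: float | None = 10.0,
    week: int = 0,
    season: str = "",
) -> FisheryLoss:
    """Share of a region's annual fish yield in cells reached by the spill.

    ``field`` is the percentile-transformed surface concentration; a
    fishery cell counts as reached if any exposed oil cell at/above the
    percentile threshold falls inside it (``threshold=None`` counts every
    exposed cell, however faint).
    """
    g = fishery.grid
    region_mask = fishery.region == region
    denom = float(fishery.yield_tons[region_mask].sum())
    if denom == 0:
        raise ValueError(f"no fishery yield recorded for region {region!r}")
    reached = np.zeros((g.n_lat, g.n_lon), dtype=bool)
    for lat, lon, pct in field.items():
        if threshold is not None and pct < threshold:
            continue
        if bool(g.contains([lon], [lat])[0]):
            iy, ix = g.cell_index([lon], [lat])
            reached[iy[0], ix[0]] = True
    lost = float(fishery.yield_tons[region_mask & reached].sum())
    return FisheryLoss(
        week=week,
        season=season,
        threshold=threshold,
        threatened_fraction_pct=100.0 * lost / denom,
        region=region,
    )
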