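"""Regular latitude-longitude grids, land masks and interpolation helpers.

Conventions shared by every stage of the pipeline:

* coordinates are WGS84 decimal degrees,
* gridded arrays are ordered ``(time, lat, lon)`` with both spatial axes
  ascending,
* cells are indexed by their centres, which are reproducible from the
  :class:`GridSpec` alone,
* metre/degree conversion uses the local metres-per-degree approximation
  (111,320 m per degree of latitude, scaled by cos(lat) for longitude),
  adequate for the few-hundred-kilometre displacements modelled here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

M_PER_DEG_LAT = 111_320.0


def metres_per_degree(lat_deg):
    """Local (metres per degree latitude, metres per degree longitude)."""
    lat_deg = np.asarray(lat_deg, dtype=float)
    return M_PER_DEG_LAT, M_PER_DEG_LAT * np.cos(np.radians(lat_deg))


@dataclass(frozen=True)
class GridSpec:
    """Spatial (and optionally temporal) discretisation of the model domain.

    The time axis is optional: population and asset grids are
    time-invariant and carry only the spatial part.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    cell_size: float
    t_start: pd.Timestamp | None = None
    t_end: pd.Timestamp | None = None
    t_step_h: float | None = None

    def __post_init__(self) -> None:
        if not (self.lat_min < self.lat_max):
            raise ValueError("lat_min must be < lat_max")
        if not (self.lon_min < self.lon_max):
            raise ValueError("lon_min must be < lon_max")
        if not (self.cell_size > 0):
            raise ValueError("cell_size must be positive")
        if self.t_start is not None or self.t_end is not None:
            if self.t_start is None or self.t_end is None or self.t_step_h is None:
                raise ValueError("t_start, t_end and t_step_h must be given together")
            object.__setattr__(self, "t_start", pd.Timestamp(self.t_start))
            object.__setattr__(self, "t_end", pd.Timestamp(self.t_end))
            if self.t_step_h <= 0:
                raise ValueError("t_step_h must be positive")
            if self.t_end < self.t_start:
                raise ValueError("t_end must not precede t_start")

    # -- axes -----------------------------------------------------------
    @property
    def n_lat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.cell_size))

    @property
    def n_lon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.cell_size))

    @property
    def lats(self) -> np.ndarray:
        """Cell-centre latitudes, ascending."""
        return self.lat_min + self.cell_size * (np.arange(self.n_lat) + 0.5)

    @property
    def lons(self) -> np.ndarray:
        return self.lon_min + self.cell_size * (np.arange(self.n_lon) + 0.5)

    @property
    def has_time(self) -> bool:
        return self.t_start is not None

    @property
    def n_time(self) -> int:
        if not self.has_time:
            return 0
        span_h = (self.t_end - self.t_start) / pd.Timedelta(hours=1)
        return int(np.floor(span_h / self.t_step_h)) + 1

    @property
    def times(self) -> pd.DatetimeIndex:
        if not self.has_time:
            return pd.DatetimeIndex([])
        return self.t_start + pd.to_timedelta(
            np.arange(self.n_time) * self.t_step_h, unit="h"
        )

    # -- helpers --------------------------------------------------------
    def spatial(self) -> "GridSpec":
        """The same grid with the time axis dropped."""
        return replace(self, t_start=None, t_end=None, t_step_h=None)

    def contains(self, lons, lats):
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        return (
            (lons >= self.lon_min)
            & (lons <= self.lon_max)
            & (lats >= self.lat_min)
            & (lats <= self.lat_max)
        )

    def cell_index(self, lons, lats):
        """(row, col) of the cell containing each point, clipped to the grid."""
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        iy = np.floor((lats - self.lat_min) / self.cell_size).astype(int)
        ix = np.floor((lons - self.lon_min) / self.cell_size).astype(int)
        return (
            np.clip(iy, 0, self.n_lat - 1),
            np.clip(ix, 0, self.n_lon - 1),
        )

    def cell_area_m2(self, lat_deg):
        m_lat, m_lon = metres_per_degree(lat_deg)
        return (self.cell_size * m_lat) * (self.cell_size * m_lon)

    def time_index(self, offset_h: float) -> int:
        """Nearest time index for an offset (hours) from the grid start."""
        if not self.has_time:
            raise ValueError("grid has no time axis")
        return int(np.clip(round(offset_h / self.t_step_h), 0, self.n_time - 1))


def bilinear_on_regular(lats, lons, arr, qlats, qlons):
    """Bilinear interpolation of ``arr`` (lat, lon) at query points.

    Queries outside the cell-centre envelope are clamped to the edge value
    (constant extrapolation); callers that must reject such queries check
    the domain themselves.
    """
    lats = np.asarray(lats)
    lons = np.asarray(lons)
    qlats = np.asarray(qlats, dtype=float)
    qlons = np.asarray(qlons, dtype=float)

    dy = lats[1] - lats[0] if lats.size > 1 else 1.0
    dx = lons[1] - lons[0] if lons.size > 1 else 1.0
    gy = (qlats - lats[0]) / dy
    gx = (qlons - lons[0]) / dx
    gy = np.clip(gy, 0.0, lats.size - 1.0)
    gx = np.clip(gx, 0.0, lons.size - 1.0)
    y0 = np.clip(np.floor(gy).astype(int), 0, max(lats.size - 2, 0))
    x0 = np.clip(np.floor(gx).astype(int), 0, max(lons.size - 2, 0))
    y1 = np.minimum(y0 + 1, lats.size - 1)
    x1 = np.minimum(x0 + 1, lons.size - 1)
    fy = gy - y0
    fx = gx - x0
    return (
        arr[y0, x0] * (1 - fy) * (1 - fx)
        + arr[y0, x1] * (1 - fy) * fx
        + arr[y1, x0] * fy * (1 - fx)
        + arr[y1, x1] * fy * fx
    )


def regrid_bilinear(arr, src: GridSpec, dst: GridSpec):
    """Interpolate a (lat, lon) field from one grid's centres to another's."""
    qlat, qlon = np.meshgrid(dst.lats, dst.lons, indexing="ij")
    return bilinear_on_regular(src.lats, src.lons, np.asarray(arr), qlat, qlon)


@dataclass
class LandMask:
    """Rasterised land/water mask on a spatial grid.

    Lookups are nearest-cell; points outside the grid count as water (the
    transport code handles domain exit separately).
    """

    grid: GridSpec
    land: np.ndarray  # bool, (n_lat, n_lon)

    def __post_init__(self) -> None:
        self.land = np.asarray(self.land, dtype=bool)
        if self.land.shape != (self.grid.n_lat, self.grid.n_lon):
            raise ValueError("mask shape does not match grid")

    @classmethod
    def channel(
        cls,
        grid: GridSpec,
        west_lon: float = 40.0,
        east_lon: float = 43.0,
        arm_lat_band: tuple[float, float] | None = None,
        arm_east_lon: float | None = None,
    ) -> "LandMask":
        """Idealised two-coast sea channel (optionally with a southern arm).

        Water lies between ``west_lon`` and ``east_lon`` at all latitudes;
        if ``arm_lat_band`` is given, an east-opening arm of water extends
        to ``arm_east_lon`` (default: the grid's eastern edge) within that
        latitude band, so that a "gulf" region is exercisable.
        """
        g = grid.spatial()
        lat2, lon2 = np.meshgrid(g.lats, g.lons, indexing="ij")
        water = (lon2 >= west_lon) & (lon2 <= east_lon)
        if arm_lat_band is not None:
            lo, hi = arm_lat_band
            east = arm_east_lon if arm_east_lon is not None else g.lon_max
            water |= (lat2 >= lo) & (lat2 <= hi) & (lon2 >= west_lon) & (lon2 <= east)
        return cls(grid=g, land=~water)

    @classmethod
    def all_water(cls, grid: GridSpec) -> "LandMask":
        g = grid.spatial()
        return cls(grid=g, land=np.zeros((g.n_lat, g.n_lon), dtype=bool))

    def is_land(self, lons, lats):
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        inside = self.grid.contains(lons, lats)
        iy, ix = self.grid.cell_index(lons, lats)
        return np.where(inside, self.land[iy, ix], False)

    def is_water(self, lons, lats):
        return ~self.is_land(lons, lats)
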