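"""Gridded monthly air temperature handling and site-level climate predictors.

The grid emulates a CRU-TS-style product: regular 0.5 degree lat/lon cells,
monthly mean air temperature in degC, continuous calendar years. Site
predictors are computed over the k calendar years *strictly before* the
collection year (the collection year itself is excluded), with summer taken
as June-August (boreal convention).

Degree-day quantities (effective temperature sum, growing-season length) use
the monthly approximation appropriate to a monthly grid: a month contributes
whole-month blocks of (T - base) * days or days when its mean exceeds the
base. February is always 28 days; the sub-0.1% leap-year bias is accepted
for determinism. Missing grid months propagate as missing site values and
are never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import LocationError, MissingClimateError

MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
SUMMER_MONTHS = (6, 7, 8)
SPRING_MONTHS = (3, 4, 5)
AUTUMN_MONTHS = (9, 10, 11)
#: standard averaging windows, years before collection
MST_WINDOWS = (10, 20, 30, 40, 50)


@dataclass
class ClimateGrid:
    """Monthly mean air temperature on a regular lat/lon grid.

    ``data`` has shape (n_years, 12, n_lat, n_lon) in degC with NaN for
    missing months; ``lat_centers`` / ``lon_centers`` are ascending cell
    centers and ``years`` consecutive calendar years.
    """

    lat_centers: np.ndarray
    lon_centers: np.ndarray
    years: np.ndarray
    data: np.ndarray
    resolution_deg: float = 0.5

    def __post_init__(self) -> None:
        self.lat_centers = np.asarray(self.lat_centers, float)
        self.lon_centers = np.asarray(self.lon_centers, float)
        self.years = np.asarray(self.years, int)
        self.data = np.asarray(self.data, float)
        expected = (len(self.years), 12, len(self.lat_centers), len(self.lon_centers))
        if self.data.shape != expected:
            raise ValueError(f"grid data shape {self.data.shape} != {expected}")
        if np.any(np.diff(self.years) != 1):
            raise ValueError("grid years must be consecutive")
        finite = self.data[np.isfinite(self.data)]
        if finite.size and (finite.min() < -60 or finite.max() > 60):
            raise ValueError("temperatures outside [-60, 60] degC")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_long_csv(cls, path, resolution_deg: float = 0.5) -> "ClimateGrid":
        """Read a long-format table (year, month, lat_center, lon_center, tmean_c)."""
        df = pd.read_csv(path)
        required = {"year", "month", "lat_center", "lon_center", "tmean_c"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        lats = np.sort(df["lat_center"].unique())
        lons = np.sort(df["lon_center"].unique())
        years = np.arange(df["year"].min(), df["year"].max() + 1)
        data = np.full((len(years), 12, len(lats), len(lons)), np.nan)
        yi = df["year"].to_numpy() - years[0]
        mi = df["month"].to_numpy() - 1
        li = np.searchsorted(lats, df["lat_center"].to_numpy())
        oi = np.searchsorted(lons, df["lon_center"].to_numpy())
        data[yi, mi, li, oi] = df["tmean_c"].to_numpy()
        return cls(lats, lons, years, data, resolution_deg)

    @classmethod
    def from_netcdf(cls, path, var: str | None = None,
                    resolution_deg: float = 0.5) -> "ClimateGrid":
        """Read a NetCDF grid with dims (time, lat, lon), monthly degC."""
        import xarray as xr

        ds = xr.open_dataset(path)
        if var is None:
            candidates = [v for v in ds.data_vars if set(ds[v].dims) >= {"time"}]
            if not candidates:
                raise ValueError(f"{path}: no time-indexed variable found")
            var = candidates[0]
        da = ds[var].transpose("time", "lat", "lon")
        years_all = da["time"].dt.year.to_numpy()
        months_all = da["time"].dt.month.to_numpy()
        years = np.arange(years_all.min(), years_all.max() + 1)
        lats = np.sort(da["lat"].to_numpy())
        lons = np.sort(da["lon"].to_numpy())
        da = da.sortby("lat").sortby("lon")
        data = np.full((len(years), 12, len(lats), len(lons)), np.nan)
        data[years_all - years[0], months_all - 1] = da.to_numpy()
        ds.close()
        return cls(lats, lons, years, data, resolution_deg)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format view (year, month, lat_center, lon_center, tmean_c)."""
        ny, _, nla, nlo = self.data.shape
        yy, mm, la, lo = np.meshgrid(
            self.years, np.arange(1, 13), self.lat_centers, self.lon_centers,
            indexing="ij",
        )
        df = pd.DataFrame(
            {
                "year": yy.ravel(),
                "month": mm.ravel(),
                "lat_center": la.ravel(),
                "lon_center": lo.ravel(),
                "tmean_c": self.data.ravel(),
            }
        )
        return df.dropna(subset=["tmean_c"]).reset_index(drop=True)

    def to_netcdf(self, path, var: str = "tmean") -> None:
        import xarray as xr

        ny = len(self.years)
        time = pd.to_datetime(
            [f"{y}-{m:02d}-15" for y in self.years for m in range(1, 13)]
        )
        da = xr.DataArray(
            self.data.reshape(ny * 12, len(self.lat_centers), len(self.lon_centers)),
            dims=("time", "lat", "lon"),
            coords={"time": time, "lat": self.lat_centers, "lon": self.lon_centers},
            name=var,
            attrs={"units": "degC"},
        )
        da.to_dataset().to_netcdf(path, engine="scipy")

    # -- indexing ---------------------------------------------------------

    def year_index(self, year: int) -> int:
        if not (self.years[0] <= year <= self.years[-1]):
            raise MissingClimateError(
                f"year {year} outside grid span {self.years[0]}-{self.years[-1]}"
            )
        return int(year - self.years[0])

    def monthly(self, cell: tuple[int, int], year: int, month: int) -> float:
        return float(self.data[self.year_index(year), month - 1, cell[0], cell[1]])


@dataclass
class SiteClimate:
    """Candidate climatic predictors for one population site."""

    population_id: str
    mst_k: dict[int, float] = field(default_factory=dict)
    spring_c: float = float("nan")
    autumn_c: float = float("nan")
    winter_c: float = float("nan")
    annual_c: float = float("nan")
    monthly_c: tuple[float, ...] = ()
    ets_5: float = float("nan")
    ets_10: float = float("nan")
    growing_season_5: float = float("nan")
    growing_season_10: float = float("nan")


def locate_cell(grid: ClimateGrid, lat: float, lon: float) -> tuple[int, int]:
    """Map a point to its containing cell; edges are half-open [south, north)."""
    res = grid.resolution_deg
    south = grid.lat_centers[0] - res / 2
    west = grid.lon_centers[0] - res / 2
    i = int(np.floor((lat - south) / res))
    j = int(np.floor((lon - west) / res))
    if not (0 <= i < len(grid.lat_centers) and 0 <= j < len(grid.lon_centers)):
        raise LocationError(f"point ({lat}, {lon}) outside grid bounds")
    return i, j


def _window_years(grid: ClimateGrid, collection_year: int, k: int) -> np.ndarray:
    """Indices of the k calendar years strictly before the collection year."""
    first, last = collection_year - k, collection_year - 1
    if first < grid.years[0] or last > grid.years[-1]:
        raise MissingClimateError(
            f"window {first}-{last} not covered by grid "
            f"({grid.years[0]}-{grid.years[-1]})"
        )
    return np.arange(first - grid.years[0], last - grid.years[0] + 1)


def _require_finite(values: np.ndarray, what: str) -> np.ndarray:
    if np.any(~np.isfinite(values)):
        raise MissingClimateError(f"missing monthly values in {what}")
    return values


def mst_window(
    grid: ClimateGrid,
    cell: tuple[int, int],
    collection_year: int,
    k: int,
    months: Sequence[int] = SUMMER_MONTHS,
) -> float:
    """Mean summer (June-August) temperature over the k years before collection."""
    yi = _window_years(grid, collection_year, k)
    mi = np.asarray(months) - 1
    vals = grid.data[np.ix_(yi, mi)][:, :, cell[0], cell[1]]
    return float(_require_finite(vals, f"MST_{k} window ending {collection_year - 1}").mean())


def seasonal_and_annual_means(
    grid: ClimateGrid, cell: tuple[int, int], collection_year: int, k: int
) -> dict:
    """Seasonal (MAM/SON/DJF), annual and per-calendar-month means over the window.

    Winter for a window year y spans December of y-1 through February of y, so
    the December of the year preceding the window must also be on the grid.
    """
    yi = _window_years(grid, collection_year, k)
    i, j = cell
    block = _require_finite(grid.data[yi][:, :, i, j], "seasonal window")
    out = {
        "spring_c": float(block[:, [m - 1 for m in SPRING_MONTHS]].mean()),
        "autumn_c": float(block[:, [m - 1 for m in AUTUMN_MONTHS]].mean()),
        "annual_c": float(block.mean()),
        "monthly_c": tuple(float(v) for v in block.mean(axis=0)),
    }
    if yi[0] == 0:
        raise MissingClimateError(
            "winter mean needs December of the year before the window"
        )
    dec_prev = grid.data[yi - 1, 11, i, j]
    winter = np.column_stack([dec_prev, block[:, 0], block[:, 1]])
    out["winter_c"] = float(_require_finite(winter, "winter months").mean())
    return out


def effective_temperature_sum(
    grid: ClimateGrid, cell: tuple[int, int], collection_year: int, k: int,
    base_c: float,
) -> float:
    """Mean annual degree-day sum above ``base_c``, monthly approximation."""
    yi = _window_years(grid, collection_year, k)
    block = _require_finite(grid.data[yi][:, :, cell[0], cell[1]], "ETS window")
    excess = np.clip(block - base_c, 0.0, None)
    excess[block <= base_c] = 0.0
    return float((excess * MONTH_DAYS).sum(axis=1).mean())


def growing_season_length(
    grid: ClimateGrid, cell: tuple[int, int], collection_year: int, k: int,
    base_c: float,
) -> float:
    """Mean annual count of days in months with mean temperature above base."""
    yi = _window_years(grid, collection_year, k)
    block = _require_finite(grid.data[yi][:, :, cell[0], cell[1]], "season window")
    return float(((block > base_c) * MONTH_DAYS).sum(axis=1).mean())


def site_climate(
    grid: ClimateGrid,
    lat: float,
    lon: float,
    collection_year: int,
    population_id: str = "",
    k: int = 20,
    windows: Sequence[int] = MST_WINDOWS,
) -> SiteClimate:
    """Compute the full predictor battery for one site.

    MST is evaluated at every window in ``windows`` that the grid covers;
    the seasonal/annual/degree-day battery is evaluated at window ``k``.
    """
    cell = locate_cell(grid, lat, lon)
    sc = SiteClimate(population_id=population_id)
    for w in windows:
        try:
            sc.mst_k[w] = mst_window(grid, cell, collection_year, w)
        except MissingClimateError:
            continue
    try:
        seas = seasonal_and_annual_means(grid, cell, collection_year, k)
        sc.spring_c = seas["spring_c"]
        sc.autumn_c = seas["autumn_c"]
        sc.winter_c = seas["winter_c"]
        sc.annual_c = seas["annual_c"]
        sc.monthly_c = seas["monthly_c"]
        sc.ets_5 = effective_temperature_sum(grid, cell, collection_year, k, 5.0)
        sc.ets_10 = effective_temperature_sum(grid, cell, collection_year, k, 10.0)
        sc.growing_season_5 = growing_season_length(grid, cell, collection_year, k, 5.0)
        sc.growing_season_10 = growing_season_length(grid, cell, collection_year, k, 10.0)
    except MissingClimateError:
        pass
    return sc


_MONTH_ABBR = ["jan", "feb", "mar", "apr", "may", "jun",
               "jul", "aug", "sep", "oct", "nov", "dec"]


def site_climates_to_frame(sites: Sequence[SiteClimate]) -> pd.DataFrame:
    """Tabulate SiteClimate objects: one row per site, one column per predictor."""
    rows = []
    for s in sites:
        row: dict[str, float | str] = {"population_id": s.population_id}
        for w, v in s.mst_k.items():
            row[f"mst_{w}"] = v
        row.update(
            spring=s.spring_c, autumn=s.autumn_c, winter=s.winter_c,
            annual=s.annual_c, ets_5=s.ets_5, ets_10=s.ets_10,
            growing_season_5=s.growing_season_5,
            growing_season_10=s.growing_season_10,
        )
        for m, v in zip(_MONTH_ABBR, s.monthly_c):
            row[f"month_{m}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
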