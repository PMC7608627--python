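"""Gridded fields on regular latitude-longitude grids.

Containers (:class:`Grid`, :class:`Field`, :class:`AnnualSeries`,
:class:`ModelRun`), spherical cell areas, area-weighted aggregates,
regridding, and CF-style NetCDF round-tripping.

The NetCDF dialect written (and read back) by this package stores the time
coordinate as decimal years (annual slices at ``year + 0.5``, monthly slices
at ``year + (month - 0.5)/12``), so files are calendar-agnostic: reading
groups slices by ``floor(time)`` and averages within each calendar year.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field as dc_field

import numpy as np
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

EARTH_RADIUS_M = 6_371_000.0
#: Area of the full sphere, m^2 (~5.1006e14).
SPHERE_AREA_M2 = 4.0 * np.pi * EARTH_RADIUS_M**2

_LAT_NAMES = ("lat", "latitude")
_LON_NAMES = ("lon", "longitude")
_TIME_NAMES = ("time", "year")


class GridError(ValueError):
    """Invalid grid geometry or grid mismatch between fields."""


class UnitsError(ValueError):
    """A field's units are not what the operation requires."""


def _bounds_from_centers(centers: np.ndarray, clamp: tuple[float, float] | None) -> np.ndarray:
    """Midpoint bounds between centers; outermost edges extrapolated and
    optionally clamped (used for latitude poles)."""
    c = np.asarray(centers, dtype=float)
    mid = 0.5 * (c[:-1] + c[1:])
    first = c[0] - (mid[0] - c[0])
    last = c[-1] + (c[-1] - mid[-1])
    b = np.concatenate([[first], mid, [last]])
    if clamp is not None:
        b = np.clip(b, *clamp)
    return b


@dataclass(frozen=True)
class Grid:
    """Regular latitude-longitude grid defined by cell centers and edges.

    Latitudes in degrees north (strictly monotonic, within [-90, 90]),
    longitudes in degrees east. Bounds arrays have one more element than the
    corresponding centers and are contiguous.
    """

    lat_centers: np.ndarray
    lon_centers: np.ndarray
    lat_bounds: np.ndarray
    lon_bounds: np.ndarray

    def __post_init__(self) -> None:
        for name in ("lat_centers", "lon_centers", "lat_bounds", "lon_bounds"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        lat, lon = self.lat_centers, self.lon_centers
        if lat.ndim != 1 or lon.ndim != 1:
            raise GridError("grid centers must be 1-D")
        dlat = np.diff(lat)
        if not (np.all(dlat > 0) or np.all(dlat < 0)):
            raise GridError("latitude centers must be strictly monotonic")
        if np.any(np.abs(lat) > 90.0):
            raise GridError("latitude centers outside [-90, 90]")
        if self.lat_bounds.shape != (lat.size + 1,) or self.lon_bounds.shape != (lon.size + 1,):
            raise GridError("bounds must have len(centers) + 1 entries")
        if np.any(np.diff(self.lat_bounds) == 0) or np.any(np.diff(self.lon_bounds) == 0):
            raise GridError("degenerate (zero-width) grid cell")

    @classmethod
    def from_centers(cls, lat_centers, lon_centers) -> "Grid":
        """Build a grid from centers alone; bounds are center midpoints with
        the latitude edges clamped to the poles."""
        lat_b = _bounds_from_centers(np.asarray(lat_centers), clamp=(-90.0, 90.0))
        lon_b = _bounds_from_centers(np.asarray(lon_centers), clamp=None)
        return cls(np.asarray(lat_centers), np.asarray(lon_centers), lat_b, lon_b)

    @classmethod
    def regular(cls, nlat: int, nlon: int) -> "Grid":
        """Globally uniform nlat x nlon grid covering the full sphere."""
        lat_b = np.linspace(-90.0, 90.0, nlat + 1)
        lon_b = np.linspace(0.0, 360.0, nlon + 1)
        lat_c = 0.5 * (lat_b[:-1] + lat_b[1:])
        lon_c = 0.5 * (lon_b[:-1] + lon_b[1:])
        return cls(lat_c, lon_c, lat_b, lon_b)

    @property
    def shape(self) -> tuple[int, int]:
        return self.lat_centers.size, self.lon_centers.size

    def __eq__(self, other) -> bool:
        if not isinstance(other, Grid):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.allclose(self.lat_centers, other.lat_centers)
            and np.allclose(self.lon_centers, other.lon_centers)
        )

    def __hash__(self) -> int:  # frozen dataclass with arrays: identity hash
        return id(self)


@dataclass
class Field:
    """One 2-D geophysical variable on a grid, with units and validity mask.

    ``mask`` is True on valid cells; masked (False) cells are excluded from
    every aggregate.
    """

    grid: Grid
    values: np.ndarray
    units: str
    mask: np.ndarray = dc_field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridError(
                f"field shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool) & np.isfinite(self.values)

    def copy_with(self, values: np.ndarray, units: str | None = None,
                  mask: np.ndarray | None = None) -> "Field":
        return Field(self.grid, np.asarray(values, dtype=float),
                     self.units if units is None else units,
                     self.mask.copy() if mask is None else mask)


@dataclass
class AnnualSeries:
    """A stack of annual fields on a common grid with common units."""

    grid: Grid
    years: np.ndarray          # strictly increasing integers, no gaps
    values: np.ndarray         # (nyears, nlat, nlon)
    units: str
    mask: np.ndarray = dc_field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(np.diff(self.years) != 1):
            raise ValueError("years must have no gaps within a run")
        if self.values.shape != (self.years.size, *self.grid.shape):
            raise GridError("series values shape does not match (nyears, nlat, nlon)")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool) & np.isfinite(self.values)

    def field(self, year: int) -> Field:
        i = int(np.searchsorted(self.years, year))
        if i >= self.years.size or self.years[i] != year:
            raise KeyError(f"year {year} not in series ({self.years[0]}..{self.years[-1]})")
        return Field(self.grid, self.values[i], self.units, self.mask[i])

    def subset(self, start: int, end: int) -> "AnnualSeries":
        """Inclusive year range."""
        sel = (self.years >= start) & (self.years <= end)
        if not sel.any():
            raise ValueError(f"period {start}-{end} outside series coverage")
        return AnnualSeries(self.grid, self.years[sel], self.values[sel], self.units,
                            self.mask[sel])


@dataclass
class ModelRun:
    """One model x scenario bundle of annual soil carbon (cs, kg C m-2),
    heterotrophic respiration (rh), and near-surface air temperature
    (tas, degC) series, plus the historical reference decade."""

    model_id: str
    scenario_id: str
    cs: AnnualSeries
    rh: AnnualSeries
    tas: AnnualSeries
    reference_period: tuple[int, int] = (1995, 2005)

    def __post_init__(self) -> None:
        g = self.cs.grid
        if self.rh.grid != g or self.tas.grid != g:
            raise GridError("cs, rh, tas must share one grid")
        y0, y1 = self.reference_period
        for s in (self.cs, self.rh, self.tas):
            if s.years[0] > y0 or s.years[-1] < y1:
                raise ValueError(
                    f"{self.model_id}/{self.scenario_id}: series does not cover "
                    f"reference period {y0}-{y1}"
                )


# ---------------------------------------------------------------------------
# area and aggregation


def cell_areas(grid: Grid) -> np.ndarray:
    """Spherical cell areas in m^2: A = R^2 * dlambda * (sin(phi_t) - sin(phi_b))."""
    lat_b = np.deg2rad(grid.lat_bounds)
    lon_b = np.deg2rad(grid.lon_bounds)
    dsin = np.abs(np.diff(np.sin(lat_b)))
    dlam = np.abs(np.diff(lon_b))
    areas = EARTH_RADIUS_M**2 * np.outer(dsin, dlam)
    if np.any(areas <= 0):
        raise GridError("degenerate cell: non-positive area")
    return areas


def global_total_pgc(f: Field) -> float:
    """Area-weighted global total of a surface density field, in PgC.

    Requires kg C m-2; masked cells contribute zero. 1 PgC = 1e12 kg C.
    """
    if _normalise_units(f.units) != "kg m-2":
        raise UnitsError(f"global_total_pgc requires kg C m-2 units, got {f.units!r}")
    areas = cell_areas(f.grid)
    vals = np.where(f.mask, f.values, 0.0)
    return float(np.sum(vals * areas) / 1e12)


def area_weighted_mean(f: Field) -> float:
    """Area-weighted mean over unmasked cells, in the field's own units."""
    areas = cell_areas(f.grid)
    w = np.where(f.mask, areas, 0.0)
    tot = w.sum()
    if tot == 0:
        raise ValueError("area_weighted_mean of a fully masked field")
    return float(np.sum(np.where(f.mask, f.values, 0.0) * w) / tot)


def _normalise_units(units: str) -> str:
    u = units.strip().lower().replace("^", "").replace("**", "")
    u = u.replace("c ", " ").replace("kg c", "kg").replace("kgc", "kg")
    u = " ".join(u.split())
    aliases = {
        "kg/m2": "kg m-2", "kg m2": "kg m-2", "kg m-2": "kg m-2",
        "kg m-2 s-1": "kg m-2 s-1", "kg/m2/s": "kg m-2 s-1", "kg m-2 yr-1": "kg m-2 yr-1",
        "kg/m2/yr": "kg m-2 yr-1", "kg m-2 year-1": "kg m-2 yr-1",
    }
    return aliases.get(u, u)


# ---------------------------------------------------------------------------
# regridding


def _periodic_pad(lon: np.ndarray, arr2d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lon_ext = np.concatenate([[lon[-1] - 360.0], lon, [lon[0] + 360.0]])
    arr_ext = np.concatenate([arr2d[:, -1:], arr2d, arr2d[:, :1]], axis=1)
    return lon_ext, arr_ext


def regrid(f: Field, target: Grid, method: str = "bilinear") -> Field:
    """Interpolate a field onto another lat-lon grid.

    ``bilinear`` interpolates valid-cell values with mask-aware weight
    renormalisation (a target cell is masked only where the entire source
    support is masked); ``nearest`` copies the nearest source cell. Longitude
    is treated as periodic. Constant fields are preserved exactly.
    """
    if method not in ("bilinear", "nearest"):
        raise ValueError(f"unknown regrid method {method!r}")
    lat = f.grid.lat_centers
    lon = np.mod(f.grid.lon_centers, 360.0)
    order = np.argsort(lon)
    lat_order = np.argsort(lat)
    vals = f.values[np.ix_(lat_order, order)]
    msk = f.mask[np.ix_(lat_order, order)].astype(float)
    lat_s, lon_s = lat[lat_order], lon[order]
    lon_ext, vals_ext = _periodic_pad(lon_s, np.where(msk > 0, vals, 0.0))
    _, msk_ext = _periodic_pad(lon_s, msk)

    tlat = target.lat_centers
    tlon = np.mod(target.lon_centers, 360.0)
    glon, glat = np.meshgrid(tlon, tlat)
    # clamp target latitudes into the source range (poleward extrapolation
    # is replaced by the edge value)
    glat_c = np.clip(glat, lat_s[0], lat_s[-1])
    pts = np.stack([glat_c.ravel(), glon.ravel()], axis=1)

    interp_method = "linear" if method == "bilinear" else "nearest"
    vi = RegularGridInterpolator((lat_s, lon_ext), vals_ext, method=interp_method,
                                 bounds_error=False, fill_value=np.nan)
    mi = RegularGridInterpolator((lat_s, lon_ext), msk_ext, method=interp_method,
                                 bounds_error=False, fill_value=np.nan)
    num = vi(pts).reshape(target.shape)
    den = mi(pts).reshape(target.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out_mask = np.isfinite(out) & (np.nan_to_num(den) > 1e-12)
    if not out_mask.any():
        raise GridError("regrid produced no valid cells (empty overlap)")
    out = np.where(out_mask, out, np.nan)
    return Field(target, out, f.units, out_mask)


# ---------------------------------------------------------------------------
# NetCDF I/O


def _find_coord(ds: xr.Dataset, candidates: tuple[str, ...], path: str) -> str:
    for name in candidates:
        if name in ds.coords or name in ds.dims:
            return name
    raise KeyError(f"{path}: no coordinate among {candidates} found")


def read_gridded_var(path: str | os.PathLike, varname: str) -> AnnualSeries:
    """Read one variable from a CF-style NetCDF file as an annual series.

    The time coordinate is interpreted as decimal years; monthly slices are
    averaged to calendar years (unweighted). Non-finite values are masked.
    """
    path = os.fspath(path)
    with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
        if varname not in ds:
            raise KeyError(f"{path}: variable {varname!r} not found "
                           f"(has {sorted(ds.data_vars)})")
        da = ds[varname]
        tname = _find_coord(ds, _TIME_NAMES, path)
        latname = _find_coord(ds, _LAT_NAMES, path)
        lonname = _find_coord(ds, _LON_NAMES, path)
        da = da.transpose(tname, latname, lonname)
        tvals = np.asarray(ds[tname].values, dtype=float)
        years_per_slice = np.floor(tvals).astype(int)
        uniq_years = np.unique(years_per_slice)
        grid = Grid.from_centers(np.asarray(ds[latname].values),
                                 np.asarray(ds[lonname].values))
        raw = np.asarray(da.values, dtype=float)
        annual = np.empty((uniq_years.size, *grid.shape))
        import warnings
        with warnings.catch_warnings():
            # all-NaN cells are legitimate: they come back masked
            warnings.simplefilter("ignore", category=RuntimeWarning)
            for i, y in enumerate(uniq_years):
                annual[i] = np.nanmean(raw[years_per_slice == y], axis=0)
        units = str(da.attrs.get("units", ""))
        if not units:
            raise KeyError(f"{path}: variable {varname!r} has no 'units' attribute")
    return AnnualSeries(grid, uniq_years, annual, units)


def write_annual_series(series: AnnualSeries, path: str | os.PathLike,
                        varname: str) -> None:
    """Write an annual series in the package's NetCDF dialect (time in
    decimal years at mid-year, NetCDF3 classic format)."""
    vals = np.where(series.mask, series.values, np.nan)
    da = xr.DataArray(
        vals,
        dims=("time", "lat", "lon"),
        coords={
            "time": series.years + 0.5,
            "lat": series.grid.lat_centers,
            "lon": series.grid.lon_centers,
        },
        name=varname,
        attrs={"units": series.units},
    )
    ds = da.to_dataset()
    ds["time"].attrs["units"] = "year"
    ds["lat"].attrs["units"] = "degrees_north"
    ds["lon"].attrs["units"] = "degrees_east"
    ds.to_netcdf(os.fspath(path), engine="scipy")


def write_field(f: Field, path: str | os.PathLike, varname: str) -> None:
    """Write a single 2-D field (no time axis) as NetCDF3."""
    vals = np.where(f.mask, f.values, np.nan)
    da = xr.DataArray(
        vals, dims=("lat", "lon"),
        coords={"lat": f.grid.lat_centers, "lon": f.grid.lon_centers},
        name=varname, attrs={"units": f.units},
    )
    da.to_dataset().to_netcdf(os.fspath(path), engine="scipy")


def read_field(path: str | os.PathLike, varname: str) -> Field:
    path = os.fspath(path)
    with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
        if varname not in ds:
            raise KeyError(f"{path}: variable {varname!r} not found")
        da = ds[varname]
        latname = _find_coord(ds, _LAT_NAMES, path)
        lonname = _find_coord(ds, _LON_NAMES, path)
        da = da.transpose(latname, lonname)
        grid = Grid.from_centers(np.asarray(ds[latname].values),
                                 np.asarray(ds[lonname].values))
        return Field(grid, np.asarray(da.values, dtype=float),
                     str(da.attrs.get("units", "")))
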