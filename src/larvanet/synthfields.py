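"""Synthetic environmental fields and habitat fixtures.

Supplies the gridded inputs the dispersal simulation samples: horizontal
velocity (u, v), horizontal diffusivity K, mixed-layer depth (MLD),
bathymetry and a land mask, on a lon/lat/depth grid with a climatological
monthly time axis.  Monthly values are anchored to the middle of each month
and interpolated linearly in between, wrapping cyclically from mid-December
to mid-January.

Two field flavours share one sampling contract (bilinear in the horizontal,
linear in depth and time, exactly zero velocity over land cells):

* :class:`EnvironmentFields` — gridded arrays, the standard container,
  written/read as NetCDF.
* :class:`AnalyticFields` — fields given as callables, evaluated exactly at
  particle positions; used for closed-form kernel verification.

The default fixture is a two-gyre basin: two counter-rotating gyres derived
from a streamfunction on a ~600 km square domain ringed by land, with
vertical shear so that near-surface and mixed-layer transport differ, and a
seasonal modulation anchored mid-month.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .hexgrid import HexGrid

METERS_PER_DEGREE = 111_194.93  # pi/180 * mean Earth radius

_MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], float)
_YEAR_DAYS = float(_MONTH_LENGTHS.sum())  # 365
MONTH_MID_DAYS = np.cumsum(_MONTH_LENGTHS) - _MONTH_LENGTHS / 2.0  # Jan 15.5, ...


def day_of_year(month: int, day: int) -> float:
    """Day offset from Jan 1 00:00 of the climatological (non-leap) year."""
    if not 1 <= month <= 12:
        raise ValueError("month must be in 1..12")
    return float(_MONTH_LENGTHS[: month - 1].sum()) + (day - 1)


def month_weights(t_days):
    """Cyclic mid-month-anchored linear time weights.

    Returns (i0, i1, w) such that a monthly field F interpolates as
    ``(1 - w) * F[i0] + w * F[i1]`` at time ``t_days`` (days since Jan 1).
    Queries exactly at a mid-month return that month's value; the
    December->January gap interpolates cyclically.
    """
    t = np.asarray(t_days, dtype=float) % _YEAR_DAYS
    anchors = np.concatenate([[MONTH_MID_DAYS[-1] - _YEAR_DAYS], MONTH_MID_DAYS])
    idx = np.searchsorted(anchors, t, side="right") - 1  # 0..12; 0 = wrapped Dec
    idx = np.clip(idx, 0, 12)
    lo = anchors[idx]
    hi = np.where(idx < 12, anchors[np.minimum(idx + 1, 12)], MONTH_MID_DAYS[0] + _YEAR_DAYS)
    w = (t - lo) / (hi - lo)
    i0 = (idx - 1) % 12
    i1 = (idx) % 12
    return i0, i1, w


def _lin_weights(axis: np.ndarray, x: np.ndarray):
    """Clamped linear interpolation weights on a sorted 1-D axis."""
    i1 = np.searchsorted(axis, x, side="right")
    i1 = np.clip(i1, 1, len(axis) - 1)
    i0 = i1 - 1
    denom = axis[i1] - axis[i0]
    w = np.where(denom > 0, (x - axis[i0]) / np.where(denom > 0, denom, 1.0), 0.0)
    return i0, i1, np.clip(w, 0.0, 1.0)


@dataclass
class EnvironmentFields:
    """Gridded environmental fields on a regular lon/lat/depth/month grid.

    Array axis order is (time, depth, lat, lon) for u, v, K;
    (time, lat, lon) for mld; (lat, lon) for bathy and land_mask.
    Depth is in meters, positive down.  ``months`` is None for steady fields.
    """

    lon: np.ndarray
    lat: np.ndarray
    depth: np.ndarray
    u: np.ndarray
    v: np.ndarray
    K: np.ndarray
    mld: np.ndarray
    bathy: np.ndarray
    land_mask: np.ndarray
    months: np.ndarray | None = None  # (nt,) month indices 1..12, or None
    _dK_cache: tuple | None = field(default=None, repr=False, compare=False)
    _uv_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        # uniform-spacing fast path for interpolation weights
        for ax in (self.lon, self.lat):
            d = np.diff(ax)
            if len(d) and not np.allclose(d, d[0]):
                raise ValueError("lon/lat axes must be uniformly spaced")
        if self.months is not None:
            self._month_slot = np.full(13, -1, dtype=int)
            self._month_slot[np.asarray(self.months, dtype=int)] = np.arange(len(self.months))
        else:
            self._month_slot = None
        self._K_const = float(self.K.ravel()[0]) if np.ptp(self.K) == 0.0 else None

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        lm = self.land_mask
        if np.any(self.u[..., lm] != 0.0) or np.any(self.v[..., lm] != 0.0):
            raise ValueError("velocity must be exactly zero on land cells")
        if np.any(self.K < 0):
            raise ValueError("diffusivity must be non-negative")
        water = ~lm
        if np.any(self.mld[..., water] > self.bathy[water]):
            raise ValueError("mixed-layer depth exceeds bathymetry in water")

    # -- coordinate helpers -----------------------------------------------

    @property
    def extent(self):
        dlon = self.lon[1] - self.lon[0]
        dlat = self.lat[1] - self.lat[0]
        return (
            self.lon[0] - dlon / 2,
            self.lon[-1] + dlon / 2,
            self.lat[0] - dlat / 2,
            self.lat[-1] + dlat / 2,
        )

    def in_domain(self, lon, lat):
        x0, x1, y0, y1 = self.extent
        lon = np.asarray(lon)
        lat = np.asarray(lat)
        return (lon >= x0) & (lon <= x1) & (lat >= y0) & (lat <= y1)

    def containing_cell(self, lon, lat):
        dlon = self.lon[1] - self.lon[0]
        dlat = self.lat[1] - self.lat[0]
        ix = np.clip(np.round((np.asarray(lon) - self.lon[0]) / dlon).astype(int), 0, len(self.lon) - 1)
        iy = np.clip(np.round((np.asarray(lat) - self.lat[0]) / dlat).astype(int), 0, len(self.lat) - 1)
        return iy, ix

    def is_land(self, lon, lat):
        iy, ix = self.containing_cell(lon, lat)
        return self.land_mask[iy, ix]

    def cell_areas_km2(self) -> np.ndarray:
        """(ny, nx) true cell areas."""
        dlon = float(self.lon[1] - self.lon[0])
        dlat = float(self.lat[1] - self.lat[0])
        dy = dlat * METERS_PER_DEGREE
        dx = dlon * METERS_PER_DEGREE * np.cos(np.radians(self.lat))
        return np.broadcast_to((dx * dy)[:, None] / 1e6, self.land_mask.shape).copy()

    def water_area_km2(self) -> float:
        return float(self.cell_areas_km2()[~self.land_mask].sum())

    # -- interpolation core ------------------------------------------------

    def _hweights(self, lon, lat):
        # uniform axes: direct index arithmetic, clamped at the outer centers
        fx = (np.asarray(lon, float) - self.lon[0]) / (self.lon[1] - self.lon[0])
        fy = (np.asarray(lat, float) - self.lat[0]) / (self.lat[1] - self.lat[0])
        ix0 = np.clip(np.floor(fx).astype(int), 0, len(self.lon) - 2)
        iy0 = np.clip(np.floor(fy).astype(int), 0, len(self.lat) - 2)
        wx = np.clip(fx - ix0, 0.0, 1.0)
        wy = np.clip(fy - iy0, 0.0, 1.0)
        return (ix0, ix0 + 1, wx), (iy0, iy0 + 1, wy)

    def _tweights(self, t_days):
        if self.months is None or len(self.months) == 1:
            z = np.zeros(np.shape(np.asarray(t_days)), dtype=float)
            zi = z.astype(int)
            return zi, zi, z
        i0, i1, w = month_weights(t_days)
        return self._month_slot[i0 + 1], self._month_slot[i1 + 1], w

    def _interp4(self, arr, lon, lat, z, t_days):
        (ix0, ix1, wx), (iy0, iy1, wy) = self._hweights(lon, lat)
        iz0, iz1, wz = _lin_weights(self.depth, np.asarray(z, float))
        it0, it1, wt = self._tweights(np.broadcast_to(np.asarray(t_days, float), np.shape(ix0)))
        out = np.zeros(np.shape(ix0), dtype=float)
        for it, cwt in ((it0, 1 - wt), (it1, wt)):
            for iz, cwz in ((iz0, 1 - wz), (iz1, wz)):
                for iy, cwy in ((iy0, 1 - wy), (iy1, wy)):
                    for ix, cwx in ((ix0, 1 - wx), (ix1, wx)):
                        out += cwt * cwz * cwy * cwx * arr[it, iz, iy, ix]
        return out

    def _interp3(self, arr, lon, lat, t_days):
        (ix0, ix1, wx), (iy0, iy1, wy) = self._hweights(lon, lat)
        it0, it1, wt = self._tweights(np.broadcast_to(np.asarray(t_days, float), np.shape(ix0)))
        out = np.zeros(np.shape(ix0), dtype=float)
        for it, cwt in ((it0, 1 - wt), (it1, wt)):
            for iy, cwy in ((iy0, 1 - wy), (iy1, wy)):
                for ix, cwx in ((ix0, 1 - wx), (ix1, wx)):
                    out += cwt * cwy * cwx * arr[it, iy, ix]
        return out

    def _interp2(self, arr, lon, lat):
        (ix0, ix1, wx), (iy0, iy1, wy) = self._hweights(lon, lat)
        out = np.zeros(np.shape(ix0), dtype=float)
        for iy, cwy in ((iy0, 1 - wy), (iy1, wy)):
            for ix, cwx in ((ix0, 1 - wx), (ix1, wx)):
                out += cwy * cwx * arr[iy, ix]
        return out

    # -- sampling contract --------------------------------------------------

    def velocity(self, lon, lat, z, t_days):
        """(u, v) in m/s; exactly zero anywhere inside a land cell."""
        if self._uv_cache is None:
            uv = np.stack([self.u, self.v], axis=-1)  # (..., 2): one gather per corner
            object.__setattr__(self, "_uv_cache", np.ascontiguousarray(uv))
        (ix0, ix1, wx), (iy0, iy1, wy) = self._hweights(lon, lat)
        iz0, iz1, wz = _lin_weights(self.depth, np.asarray(z, float))
        it0, it1, wt = self._tweights(np.broadcast_to(np.asarray(t_days, float), np.shape(ix0)))
        uv = np.zeros(np.shape(ix0) + (2,), dtype=float)
        arr = self._uv_cache
        for it, cwt in ((it0, 1 - wt), (it1, wt)):
            for iz, cwz in ((iz0, 1 - wz), (iz1, wz)):
                for iy, cwy in ((iy0, 1 - wy), (iy1, wy)):
                    for ix, cwx in ((ix0, 1 - wx), (ix1, wx)):
                        uv += (cwt * cwz * cwy * cwx)[..., None] * arr[it, iz, iy, ix]
        land = self.is_land(lon, lat)
        u = np.where(land, 0.0, uv[..., 0])
        v = np.where(land, 0.0, uv[..., 1])
        return u, v

    def diffusivity(self, lon, lat, z, t_days):
        if self._K_const is not None:
            return np.full(np.shape(np.asarray(lon)), self._K_const)
        return self._interp4(self.K, lon, lat, z, t_days)

    def diffusivity_gradient(self, lon, lat, z, t_days):
        """(dK/dx, dK/dy) in m/s, centered finite differences on the grid."""
        if self._K_const is not None:
            zero = np.zeros(np.shape(np.asarray(lon)))
            return zero, zero.copy()
        if self._dK_cache is None:
            dy = (self.lat[1] - self.lat[0]) * METERS_PER_DEGREE
            dx = (self.lon[1] - self.lon[0]) * METERS_PER_DEGREE * np.cos(np.radians(self.lat))
            dKdx = np.gradient(self.K, axis=3) / dx[None, None, :, None]
            dKdy = np.gradient(self.K, axis=2) / dy
            object.__setattr__(self, "_dK_cache", (dKdx, dKdy))
        dKdx, dKdy = self._dK_cache
        return (
            self._interp4(dKdx, lon, lat, z, t_days),
            self._interp4(dKdy, lon, lat, z, t_days),
        )

    def mixed_layer_depth(self, lon, lat, t_days):
        return self._interp3(self.mld, lon, lat, t_days)

    def bathymetry(self, lon, lat):
        return self._interp2(self.bathy, lon, lat)

    # -- I/O ---------------------------------------------------------------

    def to_netcdf(self, path) -> None:
        coords = {"lon": self.lon, "lat": self.lat, "depth": self.depth}
        coords["time"] = self.months if self.months is not None else [0]
        nt = len(coords["time"])
        ds = xr.Dataset(
            {
                "u": (("time", "depth", "lat", "lon"), self.u.reshape(nt, *self.u.shape[-3:])),
                "v": (("time", "depth", "lat", "lon"), self.v.reshape(nt, *self.v.shape[-3:])),
                "K": (("time", "depth", "lat", "lon"), self.K.reshape(nt, *self.K.shape[-3:])),
                "mld": (("time", "lat", "lon"), self.mld.reshape(nt, *self.mld.shape[-2:])),
                "bathy": (("lat", "lon"), self.bathy),
                "land_mask": (("lat", "lon"), self.land_mask.astype(np.int8)),
            },
            coords=coords,
            attrs={"steady": int(self.months is None)},
        )
        ds.lon.attrs["units"] = "degrees_east"
        ds.lat.attrs["units"] = "degrees_north"
        ds.depth.attrs["units"] = "m"
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "EnvironmentFields":
        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        steady = bool(ds.attrs.get("steady", 0))
        return cls(
            lon=ds.lon.values.astype(float),
            lat=ds.lat.values.astype(float),
            depth=ds.depth.values.astype(float),
            u=ds.u.values.astype(float),
            v=ds.v.values.astype(float),
            K=ds.K.values.astype(float),
            mld=ds.mld.values.astype(float),
            bathy=ds.bathy.values.astype(float),
            land_mask=ds.land_mask.values.astype(bool),
            months=None if steady else ds.time.values.astype(int),
        )


@dataclass
class AnalyticFields:
    """Fields given as callables of (lon, lat, z, t_days); exact sampling.

    Used where a closed form is wanted (kernel verification); obeys the same
    contract as the gridded container, including land zeroing when a
    ``land_test`` predicate is supplied.
    """

    u_fn: Callable
    v_fn: Callable
    K_fn: Callable = lambda lon, lat, z, t: np.zeros(np.shape(lon))
    dKdx_fn: Callable = lambda lon, lat, z, t: np.zeros(np.shape(lon))
    dKdy_fn: Callable = lambda lon, lat, z, t: np.zeros(np.shape(lon))
    mld_fn: Callable = lambda lon, lat, t: np.full(np.shape(lon), 25.0)
    bathy_fn: Callable = lambda lon, lat: np.full(np.shape(lon), 200.0)
    land_test: Callable | None = None
    extent: tuple = (-180.0, 180.0, -89.0, 89.0)

    def in_domain(self, lon, lat):
        x0, x1, y0, y1 = self.extent
        lon = np.asarray(lon)
        lat = np.asarray(lat)
        return (lon >= x0) & (lon <= x1) & (lat >= y0) & (lat <= y1)

    def is_land(self, lon, lat):
        if self.land_test is None:
            return np.zeros(np.shape(np.asarray(lon)), dtype=bool)
        return self.land_test(lon, lat)

    def velocity(self, lon, lat, z, t_days):
        u = np.asarray(self.u_fn(lon, lat, z, t_days), dtype=float)
        v = np.asarray(self.v_fn(lon, lat, z, t_days), dtype=float)
        land = self.is_land(lon, lat)
        return np.where(land, 0.0, u), np.where(land, 0.0, v)

    def diffusivity(self, lon, lat, z, t_days):
        return np.asarray(self.K_fn(lon, lat, z, t_days), dtype=float)

    def diffusivity_gradient(self, lon, lat, z, t_days):
        return (
            np.asarray(self.dKdx_fn(lon, lat, z, t_days), dtype=float),
            np.asarray(self.dKdy_fn(lon, lat, z, t_days), dtype=float),
        )

    def mixed_layer_depth(self, lon, lat, t_days):
        return np.asarray(self.mld_fn(lon, lat, t_days), dtype=float)

    def bathymetry(self, lon, lat):
        return np.asarray(self.bathy_fn(lon, lat), dtype=float)


# ---------------------------------------------------------------------------
# fixture generators
# ---------------------------------------------------------------------------

DEFAULT_DEPTHS = np.array([0.0, 5.0, 10.0, 20.0, 30.0, 50.0, 75.0, 100.0, 150.0, 200.0])


def default_shear(z):
    """Velocity scale factor vs depth: e-folding over 40 m."""
    return np.exp(-np.asarray(z, float) / 40.0)


def make_double_gyre(
    domain_km: float = 600.0,
    cell_km: float = 10.0,
    gyre_strength: float = 0.1,
    shear_profile: Callable | None = default_shear,
    center: tuple[float, float] = (-63.0, 45.0),
    seasonal_amplitude: float = 0.2,
    peak_month: int = 9,
    K0: float = 10.0,
    depths: np.ndarray = DEFAULT_DEPTHS,
    steady: bool = False,
    land_border: int = 1,
) -> EnvironmentFields:
    """Two counter-rotating gyres in a square basin ringed by land.

    The surface flow derives from the streamfunction
    ``psi = A sin(pi x/L) sin(2 pi y/L)`` via centered differences, so the
    discrete divergence vanishes and the two gyre centers (at L/2, L/4) and
    (L/2, 3L/4) are stagnation points.  ``gyre_strength`` sets the peak
    surface speed (m/s); flow at depth z is the surface flow times
    ``shear_profile(z)``; months modulate the strength by
    ``1 + seasonal_amplitude * cos(2 pi (m - peak_month)/12)``.
    """
    if domain_km <= 0 or cell_km <= 0:
        raise ValueError("domain and cell sizes must be positive")
    n = int(round(domain_km / cell_km))
    if n < 2 * land_border + 4:
        raise ValueError("domain too small for the land border")
    L = n * cell_km * 1000.0  # meters
    lon0, lat0 = center
    dlat = cell_km * 1000.0 / METERS_PER_DEGREE
    dlon = cell_km * 1000.0 / (METERS_PER_DEGREE * np.cos(np.radians(lat0)))
    lat = lat0 + dlat * (np.arange(n) - (n - 1) / 2.0)
    lon = lon0 + dlon * (np.arange(n) - (n - 1) / 2.0)

    # planar basin coordinates of cell centers, meters
    xs = (np.arange(n) + 0.5) * cell_km * 1000.0
    X, Y = np.meshgrid(xs, xs)
    A = gyre_strength * L / (2.0 * np.pi)
    psi = A * np.sin(np.pi * X / L) * np.sin(2.0 * np.pi * Y / L)
    dxy = cell_km * 1000.0
    u0 = -np.gradient(psi, dxy, axis=0)  # -dpsi/dy
    v0 = np.gradient(psi, dxy, axis=1)  # +dpsi/dx

    land = np.zeros((n, n), dtype=bool)
    if land_border > 0:
        land[:land_border, :] = True
        land[-land_border:, :] = True
        land[:, :land_border] = True
        land[:, -land_border:] = True
    u0 = np.where(land, 0.0, u0)
    v0 = np.where(land, 0.0, v0)

    shear = np.ones(len(depths)) if shear_profile is None else np.asarray(
        shear_profile(depths), dtype=float
    )
    months = None if steady else np.arange(1, 13)
    nt = 1 if steady else 12
    seas = np.ones(nt)
    if not steady and seasonal_amplitude != 0.0:
        seas = 1.0 + seasonal_amplitude * np.cos(
            2.0 * np.pi * (np.arange(1, 13) - peak_month) / 12.0
        )
    u = seas[:, None, None, None] * shear[None, :, None, None] * u0[None, None, :, :]
    v = seas[:, None, None, None] * shear[None, :, None, None] * v0[None, None, :, :]
    K = np.full((nt, len(depths), n, n), float(K0))

    fields = EnvironmentFields(
        lon=lon,
        lat=lat,
        depth=np.asarray(depths, dtype=float),
        u=u,
        v=v,
        K=K,
        mld=np.full((nt, n, n), 25.0),
        bathy=np.where(land, 0.0, 200.0),
        land_mask=land,
        months=months,
    )
    fields.gyre_centers_xy_m = ((L / 2.0, L / 4.0), (L / 2.0, 3.0 * L / 4.0))
    fields.basin_origin = (lon[0] - dlon / 2.0, lat[0] - dlat / 2.0)
    return fields


def basin_xy_to_lonlat(fields: EnvironmentFields, x_m, y_m):
    """Planar basin coordinates (m from the SW corner) -> lon/lat."""
    lon_sw, lat_sw = fields.basin_origin
    dlat = fields.lat[1] - fields.lat[0]
    dlon = fields.lon[1] - fields.lon[0]
    cell_m = dlat * METERS_PER_DEGREE
    return lon_sw + np.asarray(x_m) / cell_m * dlon, lat_sw + np.asarray(y_m) / cell_m * dlat


def make_mld_and_bathy(
    fields: EnvironmentFields,
    mld_mean: float = 25.0,
    mld_amplitude: float = 10.0,
    peak_month: int = 3,
    bathy_coast: float = 60.0,
    bathy_max: float = 200.0,
) -> EnvironmentFields:
    """Attach a bowl bathymetry and a mid-month-anchored seasonal MLD.

    MLD(month) = mean + amplitude * cos(2 pi (month - peak_month) / 12),
    uniform in space; raises if the MLD would exceed bathymetry anywhere in
    water.
    """
    if mld_mean <= 0:
        raise ValueError("mld_mean must be positive")
    n_lat, n_lon = fields.land_mask.shape
    ix = (np.arange(n_lon) + 0.5) / n_lon
    iy = (np.arange(n_lat) + 0.5) / n_lat
    bowl = np.sqrt(np.outer(np.sin(np.pi * iy), np.sin(np.pi * ix)))
    bathy = bathy_coast + (bathy_max - bathy_coast) * bowl
    bathy = np.where(fields.land_mask, 0.0, bathy)

    nt = 1 if fields.months is None else len(fields.months)
    m = np.array([1.0]) if fields.months is None else fields.months.astype(float)
    cyc = mld_mean + mld_amplitude * np.cos(2.0 * np.pi * (m - peak_month) / 12.0)
    mld = np.broadcast_to(cyc[:, None, None], (nt, n_lat, n_lon)).copy()

    water = ~fields.land_mask
    if np.any(mld[:, water] > bathy[water]):
        raise ValueError("mixed-layer depth exceeds bathymetry in water")
    fields.bathy = bathy
    fields.mld = mld
    fields.validate()
    return fields


@dataclass(frozen=True)
class HabitatMap:
    """Suitable habitat for one genetic lineage, as a set of grid cells."""

    lineage: str
    cells: frozenset

    def __contains__(self, cell_id) -> bool:
        return int(cell_id) in self.cells


def water_hex_cells(fields: EnvironmentFields, grid: HexGrid) -> set:
    """Hexagonal cells whose center lies in water, over the field domain.

    Enumerates the axial-coordinate window covering the domain, so it works
    whether hex cells are coarser or finer than the field grid.
    """
    x0, x1, y0, y1 = fields.extent
    cx, cy = grid.project(
        np.array([x0, x1, x0, x1]), np.array([y0, y0, y1, y1])
    )
    qc, rc = grid._xy_to_axial(
        np.array([cx.min(), cx.max(), cx.min(), cx.max()]),
        np.array([cy.min(), cy.min(), cy.max(), cy.max()]),
    )
    qs = np.arange(qc.min() - 2, qc.max() + 3)
    rs = np.arange(rc.min() - 2, rc.max() + 3)
    Q, R = np.meshgrid(qs, rs)
    hx, hy = grid._axial_to_xy(Q.ravel(), R.ravel())
    lon, lat = grid.unproject(hx, hy)
    ok = fields.in_domain(lon, lat)
    ok[ok] = ~fields.is_land(lon[ok], lat[ok])
    return set(int(c) for c in grid._pack(Q.ravel()[ok], R.ravel()[ok]))


def gyre_habitat_seeds(fields: EnvironmentFields, grid: HexGrid, n_lineages: int = 3) -> list:
    """Habitat patch seeds anchored on the basin's retentive features.

    Benthic habitat in the emulated system sits on banks inside retentive
    circulation features, so the first two seeds go to the two gyre
    centers; further lineages seed at fixed mid-basin positions.
    """
    (x1, y1), (x2, y2) = fields.gyre_centers_xy_m
    L = x1 * 2.0
    positions = [(x1, y1), (x2, y2), (L / 4, L / 2), (3 * L / 4, L / 2), (L / 4, L / 4)]
    if n_lineages > len(positions):
        raise ValueError(f"at most {len(positions)} gyre-anchored lineages")
    seeds = []
    for x, y in positions[:n_lineages]:
        lon, lat = basin_xy_to_lonlat(fields, x, y)
        seeds.append(int(grid.cell(float(lon), float(lat))))
    return seeds


def make_habitat_patches(
    fields: EnvironmentFields,
    grid: HexGrid,
    n_lineages: int = 3,
    patch_seeds: Sequence[int] | None = None,
    rng_seed: int = 0,
    growth_steps: int = 5,
    grow_prob: float = 0.85,
) -> list[HabitatMap]:
    """Grow disjoint contiguous habitat patches, one per lineage.

    Patches grow by stochastic frontier expansion over the hex adjacency,
    restricted to water cells; lineages claim cells round-robin so patches
    are pairwise disjoint by construction.  Deterministic given ``rng_seed``.
    """
    if n_lineages < 1:
        raise ValueError("n_lineages must be >= 1")
    rng = np.random.default_rng(rng_seed)
    water = water_hex_cells(fields, grid)
    if not water:
        raise ValueError("no water cells in domain")
    order = sorted(water)

    if patch_seeds is None:
        # farthest-point seeding for separated patches
        centers = {c: grid.cell_center(c) for c in order}
        first = order[int(rng.integers(len(order)))]
        seeds = [first]
        while len(seeds) < n_lineages:
            best, best_d = None, -1.0
            for c in order:
                d = min(
                    (centers[c][0] - centers[s][0]) ** 2 + (centers[c][1] - centers[s][1]) ** 2
                    for s in seeds
                )
                if d > best_d:
                    best, best_d = c, d
            seeds.append(best)
    else:
        seeds = [int(s) for s in patch_seeds]
        if len(seeds) != n_lineages:
            raise ValueError("need one patch seed per lineage")
    if len(set(seeds)) != len(seeds):
        raise ValueError("patch seeds overlap")
    for s in seeds:
        if s not in water:
            raise ValueError(f"patch seed {s} is not a water cell")

    claimed = {s: k for k, s in enumerate(seeds)}
    patches = [{s} for s in seeds]
    for _ in range(growth_steps):
        for k in range(n_lineages):
            frontier = []
            for c in sorted(patches[k]):
                for nb in grid.neighbors(c):
                    nb = int(nb)
                    if nb in water and nb not in claimed:
                        frontier.append(nb)
            frontier = sorted(set(frontier))
            for nb in frontier:
                if nb in claimed:
                    continue
                if rng.random() < grow_prob:
                    claimed[nb] = k
                    patches[k].add(nb)

    maps = [
        HabitatMap(lineage=f"lineage_{k + 1}", cells=frozenset(patches[k]))
        for k in range(n_lineages)
    ]
    for a in range(n_lineages):
        for b in range(a + 1, n_lineages):
            if maps[a].cells & maps[b].cells:
                raise ValueError("habitat patches overlap")
    return maps


def habitat_to_csv(maps: Sequence[HabitatMap], path) -> None:
    rows = [(m.lineage, c) for m in maps for c in sorted(m.cells)]
    pd.DataFrame(rows, columns=["lineage", "cell_id"]).to_csv(path, index=False)


def habitat_from_csv(path) -> list[HabitatMap]:
    df = pd.read_csv(path)
    return [
        HabitatMap(lineage=str(lin), cells=frozenset(int(c) for c in grp["cell_id"]))
        for lin, grp in df.groupby("lineage", sort=True)
    ]
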