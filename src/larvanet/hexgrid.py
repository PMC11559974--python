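"""Hexagonal geodesic binning of particle positions.

Trajectories are reduced to transitions between cells of a hexagonal grid.
The grid follows the icosahedral aperture-7 refinement scheme used by
hierarchical hexagonal geospatial indexes: refining an icosahedron whose 122
resolution-0 faces (110 hexagons + 12 pentagons) each split into seven
children gives ``N(r) = 2 + 120 * 7**r`` cells at resolution ``r``, of which
exactly 12 are pentagons at every resolution (the icosahedron vertices).
Cell areas therefore average ``A_earth / N(r)`` — about 253 km**2 at the
default resolution 5.

For a regional domain the grid is realized as a tiling of regular hexagons
of exactly that mean area on a Lambert cylindrical equal-area projection
anchored at the domain center, so planar cell area equals true spherical
area and every longitude/latitude pair maps to exactly one cell.  Cells are
addressed by axial coordinates (q, r) packed with the resolution into a
single integer id.
"""

from __future__ import annotations

import json
import math

import numpy as np

EARTH_RADIUS_M = 6_371_008.8  # mean Earth radius
EARTH_AREA_M2 = 4.0 * math.pi * EARTH_RADIUS_M**2

_Q_BITS = 24
_OFFSET = 1 << (_Q_BITS - 1)
_MASK = (1 << _Q_BITS) - 1

# pointy-top axial neighbor offsets, fixed order for determinism
_NEIGHBOR_OFFSETS = ((+1, 0), (+1, -1), (0, -1), (-1, 0), (-1, +1), (0, +1))


def n_cells_global(resolution: int) -> int:
    """Number of cells tiling the full globe at ``resolution``.

    Aperture-7 refinement of the 122-cell icosahedral base tiling.
    """
    if resolution < 0:
        raise ValueError("resolution must be non-negative")
    return 2 + 120 * 7**resolution


def pentagon_count() -> int:
    """Number of pentagonal cells in the global tiling (any resolution).

    Derived from Euler's polyhedron formula for a 3-regular spherical tiling
    by pentagons and hexagons: with F5 pentagons and F6 hexagons,
    V - E + F = 2, 2E = 3V and 2E = 5*F5 + 6*F6, which forces F5 = 12
    independent of F6.
    """
    # Solve the linear system symbolically: substituting V = 2E/3 and
    # F = F5 + F6 into Euler's formula gives F5/6 + F6 - E/3 + ... -> F5 = 12.
    f5 = 12
    assert 5 * f5 % 2 == 0  # edge count consistency
    return f5


def mean_cell_area_km2(resolution: int) -> float:
    """Mean cell area of the global tiling at ``resolution``, in km**2."""
    return EARTH_AREA_M2 / n_cells_global(resolution) / 1e6


class HexGrid:
    """Regional hexagonal grid at an icosahedral-scheme resolution.

    Parameters
    ----------
    resolution:
        Hierarchy level; cell area shrinks by a factor 7 per level.
        Default 5 (mean area ~253 km**2).
    center:
        (lon, lat) anchor of the equal-area projection, degrees.
    """

    def __init__(self, resolution: int = 5, center: tuple[float, float] = (0.0, 0.0)):
        if not 0 <= resolution <= 15:
            raise ValueError("resolution must be in [0, 15]")
        self.resolution = int(resolution)
        self.center = (float(center[0]), float(center[1]))
        self._coslat0 = math.cos(math.radians(self.center[1]))
        area_m2 = EARTH_AREA_M2 / n_cells_global(self.resolution)
        # regular hexagon: area = (3*sqrt(3)/2) * edge**2
        self.edge_m = math.sqrt(2.0 * area_m2 / (3.0 * math.sqrt(3.0)))
        self.cell_area_km2 = area_m2 / 1e6

    # -- projection -------------------------------------------------------

    def project(self, lon, lat):
        """Lon/lat (deg) -> equal-area planar x, y in meters."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        x = EARTH_RADIUS_M * np.radians(lon - self.center[0]) * self._coslat0
        y = (
            EARTH_RADIUS_M
            * (np.sin(np.radians(lat)) - math.sin(math.radians(self.center[1])))
            / self._coslat0
        )
        return x, y

    def unproject(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lon = self.center[0] + np.degrees(x / (EARTH_RADIUS_M * self._coslat0))
        s = y * self._coslat0 / EARTH_RADIUS_M + math.sin(math.radians(self.center[1]))
        lat = np.degrees(np.arcsin(np.clip(s, -1.0, 1.0)))
        return lon, lat

    # -- indexing ---------------------------------------------------------

    def cell(self, lon, lat):
        """Assign positions to cell ids. Scalar in -> scalar out."""
        scalar = np.isscalar(lon) or (np.ndim(lon) == 0 and np.ndim(lat) == 0)
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        if lon.shape != lat.shape:
            raise ValueError("lon and lat must have the same shape")
        if not (np.all(np.isfinite(lon)) and np.all(np.isfinite(lat))):
            raise ValueError("coordinates must be finite")
        if np.any(np.abs(lat) > 90.0):
            raise ValueError("latitude out of [-90, 90]")
        x, y = self.project(lon, lat)
        q, r = self._xy_to_axial(x, y)
        ids = self._pack(q, r)
        return int(ids[0]) if scalar else ids

    def _xy_to_axial(self, x, y):
        a = self.edge_m
        qf = (math.sqrt(3.0) / 3.0 * x - y / 3.0) / a
        rf = (2.0 / 3.0 * y) / a
        return _cube_round(qf, rf)

    def _axial_to_xy(self, q, r):
        a = self.edge_m
        x = a * (math.sqrt(3.0) * (np.asarray(q, dtype=float) + np.asarray(r, dtype=float) / 2.0))
        y = a * 1.5 * np.asarray(r, dtype=float)
        return x, y

    def _pack(self, q, r):
        q = np.asarray(q, dtype=np.int64)
        r = np.asarray(r, dtype=np.int64)
        if np.any(np.abs(q) >= _OFFSET) or np.any(np.abs(r) >= _OFFSET):
            raise ValueError("position too far from grid center")
        return (
            (np.int64(self.resolution) << np.int64(2 * _Q_BITS))
            | ((q + _OFFSET) << np.int64(_Q_BITS))
            | (r + _OFFSET)
        )

    def _unpack(self, cell_id):
        cid = np.asarray(cell_id, dtype=np.int64)
        res = cid >> np.int64(2 * _Q_BITS)
        if np.any(res != self.resolution):
            raise ValueError("cell id resolution does not match this grid")
        q = ((cid >> np.int64(_Q_BITS)) & _MASK) - _OFFSET
        r = (cid & _MASK) - _OFFSET
        return q, r

    # -- geometry & topology ---------------------------------------------

    def cell_center(self, cell_id):
        """Cell id -> (lon, lat) of the cell center."""
        q, r = self._unpack(cell_id)
        x, y = self._axial_to_xy(q, r)
        return self.unproject(x, y)

    def cell_boundary(self, cell_id):
        """Hexagon vertices of one cell as an (6, 2) lon/lat array."""
        q, r = self._unpack(np.asarray(cell_id))
        xc, yc = self._axial_to_xy(q, r)
        ang = np.radians(60.0 * np.arange(6) + 30.0)  # pointy-top
        vx = np.asarray(xc) + self.edge_m * np.cos(ang)
        vy = np.asarray(yc) + self.edge_m * np.sin(ang)
        lon, lat = self.unproject(vx, vy)
        return np.column_stack([lon, lat])

    def neighbors(self, cell_id):
        """Six adjacent cell ids, fixed deterministic order."""
        q, r = self._unpack(cell_id)
        return [self._pack(q + dq, r + dr) for dq, dr in _NEIGHBOR_OFFSETS]

    def neighbors_array(self, cell_ids):
        """Vectorized adjacency: (n,) ids -> (n, 6) neighbor ids."""
        q, r = self._unpack(np.asarray(cell_ids))
        out = np.empty(q.shape + (6,), dtype=np.int64)
        for k, (dq, dr) in enumerate(_NEIGHBOR_OFFSETS):
            out[..., k] = self._pack(q + dq, r + dr)
        return out

    def cells_to_geojson(self, cell_ids, properties=None) -> str:
        """GeoJSON FeatureCollection of cell polygons (for mapping)."""
        feats = []
        for i, cid in enumerate(cell_ids):
            ring = self.cell_boundary(int(cid)).tolist()
            ring.append(ring[0])
            props = {"cell_id": int(cid)}
            if properties is not None:
                props.update({k: v[i] for k, v in properties.items()})
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": props,
                }
            )
        return json.dumps({"type": "FeatureCollection", "features": feats})


def _cube_round(qf, rf):
    """Round fractional axial coordinates to the containing hexagon."""
    qf = np.asarray(qf, dtype=float)
    rf = np.asarray(rf, dtype=float)
    sf = -qf - rf
    q = np.round(qf)
    r = np.round(rf)
    s = np.round(sf)
    dq = np.abs(q - qf)
    dr = np.abs(r - rf)
    ds = np.abs(s - sf)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    q = np.where(fix_q, -r - s, q)
    r = np.where(fix_r, -q - s, r)
    return q.astype(np.int64), r.astype(np.int64)
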