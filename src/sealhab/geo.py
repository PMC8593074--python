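"""Geodesy and grid primitives shared across the pipeline.

All distances are great-circle (haversine) kilometres on a spherical Earth;
speeds are metres per second from great-circle distance over elapsed time.
Grids are regular lon/lat grids in WGS84 degrees with half-open cell
membership [lower, upper) on both axes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing_deg(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing (degrees clockwise from north)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.degrees(np.arctan2(y, x)) % 360.0


def inner_angle_deg(lon_a, lat_a, lon_b, lat_b, lon_c, lat_c):
    """Inner turning angle at B of the triple A-B-C, in [0, 180].

    180 means straight-ahead travel; small angles are spikes.
    """
    b1 = initial_bearing_deg(lon_b, lat_b, lon_a, lat_a)
    b2 = initial_bearing_deg(lon_b, lat_b, lon_c, lat_c)
    d = np.abs(b1 - b2) % 360.0
    return np.where(d > 180.0, 360.0 - d, d)


def normalize_lon(lon):
    """Normalize longitudes to [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid. ``lon0``/``lat0`` are the outer edges of the
    first (south-west) cell; cells are ``cell`` degrees on each side."""

    lon0: float
    lat0: float
    cell: float
    nlon: int
    nlat: int

    def __post_init__(self):
        if self.cell <= 0:
            raise ValueError("cell size must be > 0")
        if self.nlon < 1 or self.nlat < 1:
            raise ValueError("grid must be non-empty")

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon0 + (np.arange(self.nlon) + 0.5) * self.cell

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat0 + (np.arange(self.nlat) + 0.5) * self.cell

    @property
    def lon_max(self) -> float:
        return self.lon0 + self.nlon * self.cell

    @property
    def lat_max(self) -> float:
        return self.lat0 + self.nlat * self.cell

    def to_cell(self, lon, lat):
        """Map positions to (row, col) with half-open [lower, upper) bins.

        Returns integer arrays; out-of-bounds positions get -1.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon0) / self.cell).astype(int)
        row = np.floor((lat - self.lat0) / self.cell).astype(int)
        bad = (col < 0) | (col >= self.nlon) | (row < 0) | (row >= self.nlat)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def cell_center(self, row, col):
        return (
            self.lon0 + (np.asarray(col) + 0.5) * self.cell,
            self.lat0 + (np.asarray(row) + 0.5) * self.cell,
        )

    def contains(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (lon >= self.lon0) & (lon < self.lon_max) & (lat >= self.lat0) & (lat < self.lat_max)


def local_planar_km(lon, lat, lon_ref, lat_ref):
    """Equirectangular projection to km around a reference point.

    Adequate for track-scale extents (hundreds of km); x east, y north.
    """
    kx = EARTH_RADIUS_KM * np.cos(np.radians(lat_ref)) * np.pi / 180.0
    ky = EARTH_RADIUS_KM * np.pi / 180.0
    return (np.asarray(lon, float) - lon_ref) * kx, (np.asarray(lat, float) - lat_ref) * ky


def planar_to_lonlat(x_km, y_km, lon_ref, lat_ref):
    kx = EARTH_RADIUS_KM * np.cos(np.radians(lat_ref)) * np.pi / 180.0
    ky = EARTH_RADIUS_KM * np.pi / 180.0
    return lon_ref + np.asarray(x_km, float) / kx, lat_ref + np.asarray(y_km, float) / ky
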