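"""Geodetic <-> local metric coordinates.

All positioning math in this package runs in a local east-north tangent
plane in meters; this module converts WGS84 latitude/longitude to and from
that frame and measures great-circle distances.  At the sub-kilometre
scales of an acoustic receiver array the equirectangular projection used
here agrees with the geodesic to well under 0.1%, which is far below both
the timing-noise-induced positioning error and the reference-GPS accuracy.

Depth is positive-down: the surface is z = 0 and a hydrophone or tag at
15 m depth has z = +15.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Mean Earth radius in meters (spherical model).
EARTH_RADIUS_M = 6_371_000.0


class GeoDomainError(ValueError):
    """Raised for coordinates outside the valid WGS84 domain."""


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 position with optional depth below the surface (meters)."""

    lat: float
    lon: float
    depth: float = 0.0

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise GeoDomainError(f"latitude {self.lat} outside [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise GeoDomainError(f"longitude {self.lon} outside [-180, 180]")
        if not math.isfinite(self.depth):
            raise GeoDomainError("depth must be finite")


@dataclass(frozen=True)
class LocalPoint:
    """East (x), north (y), depth (z, positive down) in meters."""

    x: float
    y: float
    z: float = 0.0

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.x, self.y, self.z))):
            raise GeoDomainError("local coordinates must be finite")

    def horizontal(self) -> np.ndarray:
        return np.array([self.x, self.y])

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class LocalFrame:
    """East-north tangent plane anchored at ``origin``.

    The projection is equirectangular at the origin latitude: exact along
    the origin meridian, with an east-west scale of cos(lat0).  Its
    analytic inverse makes geo->local->geo roundtrips exact to floating
    precision.
    """

    origin: GeoPoint
    _coslat0: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_coslat0", math.cos(math.radians(self.origin.lat)))

    def to_local(self, p: GeoPoint) -> LocalPoint:
        x = math.radians(p.lon - self.origin.lon) * EARTH_RADIUS_M * self._coslat0
        y = math.radians(p.lat - self.origin.lat) * EARTH_RADIUS_M
        return LocalPoint(x, y, p.depth)

    def to_geo(self, p: LocalPoint) -> GeoPoint:
        lat = self.origin.lat + math.degrees(p.y / EARTH_RADIUS_M)
        lon = self.origin.lon + math.degrees(p.x / (EARTH_RADIUS_M * self._coslat0))
        return GeoPoint(lat, lon, p.z)

    def to_local_arrays(self, lats, lons) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized ``to_local`` for coordinate arrays (degrees -> meters)."""
        lats = np.asarray(lats, dtype=float)
        lons = np.asarray(lons, dtype=float)
        x = np.radians(lons - self.origin.lon) * EARTH_RADIUS_M * self._coslat0
        y = np.radians(lats - self.origin.lat) * EARTH_RADIUS_M
        return x, y

    def to_geo_arrays(self, xs, ys) -> tuple[np.ndarray, np.ndarray]:
        xs = np.asarray(xs, dtype=float)
        ys = np.asarray(ys, dtype=float)
        lat = self.origin.lat + np.degrees(ys / EARTH_RADIUS_M)
        lon = self.origin.lon + np.degrees(xs / (EARTH_RADIUS_M * self._coslat0))
        return lat, lon


def make_frame(origin: GeoPoint) -> LocalFrame:
    """Build a local tangent frame anchored at ``origin``."""
    return LocalFrame(origin)


def frame_from_points(points: list[GeoPoint]) -> LocalFrame:
    """Frame anchored at the centroid of ``points`` (minimises distortion
    over a receiver array)."""
    if not points:
        raise GeoDomainError("cannot build a frame from an empty point list")
    lat = sum(p.lat for p in points) / len(points)
    lon = sum(p.lon for p in points) / len(points)
    return LocalFrame(GeoPoint(lat, lon))


def geodesic_distance(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle (haversine) distance in meters; depth is ignored."""
    la1, lo1 = math.radians(a.lat), math.radians(a.lon)
    la2, lo2 = math.radians(b.lat), math.radians(b.lon)
    s = (
        math.sin((la2 - la1) / 2.0) ** 2
        + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(s)))
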