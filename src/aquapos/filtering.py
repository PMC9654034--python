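"""Plausibility filtering of position fixes and geofence crossings.

False or mis-grouped detections produce fixes far from the receiver
array.  The plausibility rule retains a fix iff it lies within a radius
(default 200 m) of at least one receiver, measured horizontally; a
stricter "within radius of every receiver" policy is available.  The
geofence side watches a track against a user polygon and emits one event
per in/out state change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .geo import GeoPoint
from .simulator import Receiver
from .tdoa import PositionFix


class FilterDomainError(ValueError):
    pass


@dataclass(frozen=True)
class FilterPolicy:
    """Retain a fix iff within ``radius_m`` of at least one receiver
    (scope="any", the default) or of every receiver (scope="all").
    Distance exactly equal to the radius retains."""

    radius_m: float = 200.0
    scope: Literal["any", "all"] = "any"

    def __post_init__(self) -> None:
        if self.radius_m <= 0:
            raise FilterDomainError("filter radius must be positive")


def _min_max_distances(
    xy: np.ndarray, receivers: Sequence[Receiver]
) -> tuple[np.ndarray, np.ndarray]:
    rpos = np.array([[r.position.x, r.position.y] for r in receivers])
    d = np.linalg.norm(xy[:, None, :] - rpos[None, :, :], axis=2)
    return d.min(axis=1), d.max(axis=1)


def filter_positions(
    fixes: Sequence[PositionFix] | pd.DataFrame,
    receivers: Sequence[Receiver],
    policy: FilterPolicy = FilterPolicy(),
):
    """Partition fixes into (retained, removed), order preserved.

    Accepts either a list of :class:`PositionFix` or a positions table
    with x/y columns; returns the same type it was given.
    """
    if not receivers:
        raise FilterDomainError("at least one receiver is required")
    if isinstance(fixes, pd.DataFrame):
        if fixes.empty:
            return fixes.copy(), fixes.copy()
        xy = fixes[["x", "y"]].to_numpy(dtype=float)
    else:
        if not fixes:
            return [], []
        xy = np.array([[f.position.x, f.position.y] for f in fixes])
    dmin, dmax = _min_max_distances(xy, receivers)
    crit = dmin if policy.scope == "any" else dmax
    keep = crit <= policy.radius_m
    if isinstance(fixes, pd.DataFrame):
        return fixes[keep].copy(), fixes[~keep].copy()
    retained = [f for f, k in zip(fixes, keep) if k]
    removed = [f for f, k in zip(fixes, keep) if not k]
    return retained, removed


def retention_percent(n_raw: int, n_retained: int) -> int:
    """Percentage of raw fixes surviving the filter, to the nearest integer."""
    if n_raw <= 0:
        raise FilterDomainError("raw count must be positive")
    if not (0 <= n_retained <= n_raw):
        raise FilterDomainError("retained count must be in [0, raw]")
    return round(100.0 * n_retained / n_raw)


@dataclass(frozen=True)
class GeofencePolygon:
    """A named closed ring of geographic vertices."""

    vertices: tuple[GeoPoint, ...]
    name: str = "geofence"

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise FilterDomainError("a polygon needs at least 3 vertices")
        if not self.shapely().is_valid:
            raise FilterDomainError("polygon ring is degenerate or self-intersecting")

    def shapely(self) -> Polygon:
        return Polygon([(v.lon, v.lat) for v in self.vertices])


def geofence_events(
    positions: pd.DataFrame, polygon: GeofencePolygon
) -> pd.DataFrame:
    """Crossing events for a temporally ordered track.

    One event per consecutive pair of positions whose inside/outside
    states differ; points on the boundary count as inside.  Expects
    columns time, lat, lon; returns columns time, direction ("in"/"out"),
    lat, lon of the post-crossing point.
    """
    poly = polygon.shapely()
    if positions.empty:
        return pd.DataFrame(columns=["time", "direction", "lat", "lon"])
    inside = np.array(
        [poly.covers(Point(lon, lat))
         for lat, lon in zip(positions["lat"], positions["lon"])]
    )
    events = []
    rows = positions.reset_index(drop=True)
    for i in range(1, len(rows)):
        if inside[i] != inside[i - 1]:
            events.append(
                {
                    "time": rows["time"].iloc[i],
                    "direction": "in" if inside[i] else "out",
                    "lat": rows["lat"].iloc[i],
                    "lon": rows["lon"].iloc[i],
                }
            )
    return pd.DataFrame(events, columns=["time", "direction", "lat", "lon"])
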