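"""File formats: detections/receivers/positions CSV, GPX reference
tracks, GeoJSON geofences and YAML run configs.

Timestamps are serialized as ISO 8601 UTC with microsecond precision and
held internally as float seconds since the Unix epoch — TDOA arithmetic
needs sub-millisecond resolution, which float64 epoch seconds retain.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import ReferenceTrack
from .filtering import GeofencePolygon
from .geo import GeoPoint, LocalFrame, LocalPoint, frame_from_points
from .simulator import Receiver

TIME_FORMAT = "%Y-%m-%dT%H:%M:%S.%fZ"


class FormatError(ValueError):
    pass


def seconds_to_iso(seconds) -> pd.Series:
    """Float epoch seconds -> ISO 8601 UTC strings (microsecond precision)."""
    ts = pd.to_datetime(np.round(np.asarray(seconds, float) * 1e6).astype("int64"),
                        unit="us", utc=True)
    return pd.Series(ts).dt.strftime(TIME_FORMAT)


def iso_to_seconds(values, context: str = "time") -> np.ndarray:
    """ISO 8601 UTC strings -> float epoch seconds; errors name the row."""
    out = np.empty(len(values), dtype=float)
    for i, v in enumerate(values):
        try:
            ts = pd.Timestamp(v)
            if ts.tzinfo is None:
                ts = ts.tz_localize("UTC")
            out[i] = ts.timestamp()
        except (ValueError, TypeError) as exc:
            raise FormatError(f"unparseable {context} on row {i + 1}: {v!r}") from exc
    return out


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what} file is missing columns: {', '.join(missing)}")


# -- receivers ---------------------------------------------------------------

def read_receivers(path) -> tuple[list[Receiver], LocalFrame]:
    """Receivers CSV (receiver_id, lat, lon, hydrophone_depth_m) ->
    local-frame receivers plus the frame (origin = array centroid)."""
    df = pd.read_csv(path, dtype={"receiver_id": str})
    _require_columns(df, ["receiver_id", "lat", "lon"], "receivers")
    depths = df["hydrophone_depth_m"] if "hydrophone_depth_m" in df else 0.0
    geos = [GeoPoint(la, lo, d) for la, lo, d in
            zip(df["lat"], df["lon"], np.broadcast_to(depths, len(df)))]
    frame = frame_from_points(geos)
    receivers = [
        Receiver(rid, frame.to_local(g))
        for rid, g in zip(df["receiver_id"], geos)
    ]
    return receivers, frame


def write_receivers(receivers: list[Receiver], frame: LocalFrame, path) -> None:
    rows = []
    for r in receivers:
        g = frame.to_geo(r.position)
        rows.append({"receiver_id": r.receiver_id, "lat": g.lat, "lon": g.lon,
                     "hydrophone_depth_m": g.depth})
    pd.DataFrame(rows).to_csv(path, index=False)


# -- detections --------------------------------------------------------------

DETECTION_CSV_COLUMNS = ["receiver_id", "tag_id", "arrival_time"]


def write_detections(table: pd.DataFrame, path) -> None:
    """Detections table (arrival_time in epoch seconds) -> CSV with ISO
    timestamps, sorted by arrival."""
    out = table.sort_values("arrival_time", kind="stable").reset_index(drop=True)
    out = out[[c for c in out.columns if c in DETECTION_CSV_COLUMNS]].copy()
    out["arrival_time"] = seconds_to_iso(
        table.sort_values("arrival_time", kind="stable")["arrival_time"].to_numpy()
    )
    out.to_csv(path, index=False)


def read_detections(path, receivers: list[Receiver] | None = None) -> pd.DataFrame:
    """Detections CSV -> table with float-second arrival times, sorted.

    With ``receivers`` given, unknown receiver ids raise an error naming
    the offending row.
    """
    df = pd.read_csv(path, dtype={"receiver_id": str, "tag_id": str})
    _require_columns(df, DETECTION_CSV_COLUMNS, "detections")
    if df.empty:
        df["arrival_time"] = df["arrival_time"].astype(float)
        return df
    df["arrival_time"] = iso_to_seconds(df["arrival_time"].tolist(), "arrival_time")
    if receivers is not None:
        known = {r.receiver_id for r in receivers}
        for i, rid in enumerate(df["receiver_id"]):
            if rid not in known:
                raise FormatError(f"unknown receiver {rid!r} on row {i + 1}")
    return df.sort_values("arrival_time", kind="stable").reset_index(drop=True)


# -- positions ---------------------------------------------------------------

POSITION_CSV_COLUMNS = [
    "tag_id", "time", "lat", "lon", "depth_m",
    "n_receivers", "residual_rms_m", "converged",
]


def fixes_to_frame(fixes, frame: LocalFrame) -> pd.DataFrame:
    """PositionFix list -> positions table with both geographic and
    local coordinates."""
    rows = []
    for f in fixes:
        g = frame.to_geo(f.position)
        rows.append({
            "tag_id": f.tag_id, "time": f.solve_time,
            "lat": g.lat, "lon": g.lon, "depth_m": f.position.z,
            "x": f.position.x, "y": f.position.y,
            "n_receivers": f.n_receivers,
            "residual_rms_m": f.residual_rms_m, "converged": f.converged,
        })
    return pd.DataFrame(rows, columns=POSITION_CSV_COLUMNS + ["x", "y"])


def write_positions(positions: pd.DataFrame, path) -> None:
    out = positions[POSITION_CSV_COLUMNS].copy()
    out["time"] = seconds_to_iso(positions["time"].to_numpy())
    out.to_csv(path, index=False)


def read_positions(path, frame: LocalFrame | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"tag_id": str})
    _require_columns(df, ["tag_id", "time", "lat", "lon"], "positions")
    if not df.empty:
        df["time"] = iso_to_seconds(df["time"].tolist(), "time")
    if frame is not None and not df.empty:
        x, y = frame.to_local_arrays(df["lat"], df["lon"])
        df["x"], df["y"] = x, y
    return df


# -- reference tracks --------------------------------------------------------

def _read_gpx(path) -> pd.DataFrame:
    import xml.etree.ElementTree as ET

    root = ET.parse(path).getroot()

    def local(tag):  # namespace-agnostic tag name
        return tag.rsplit("}", 1)[-1]

    rows = []
    for trkpt in root.iter():
        if local(trkpt.tag) != "trkpt":
            continue
        t = None
        for child in trkpt:
            if local(child.tag) == "time":
                t = child.text
        if t is None:
            raise FormatError("GPX trackpoint without a time element")
        rows.append({"time": t, "lat": float(trkpt.attrib["lat"]),
                     "lon": float(trkpt.attrib["lon"])})
    if not rows:
        raise FormatError("GPX file contains no trackpoints")
    return pd.DataFrame(rows)


def read_reference_track(path, frame: LocalFrame,
                         stated_accuracy_m: float | None = None) -> ReferenceTrack:
    """GPX 1.1 or CSV (time, lat, lon) -> local-frame reference track.

    Duplicate timestamps are collapsed (first kept); time reversals are
    rejected.
    """
    path = Path(path)
    if path.suffix.lower() == ".gpx":
        df = _read_gpx(path)
    else:
        df = pd.read_csv(path)
        _require_columns(df, ["time", "lat", "lon"], "reference track")
    if df.empty:
        raise FormatError("reference track is empty")
    t = iso_to_seconds(df["time"].tolist(), "time")
    keep = np.concatenate([[True], np.diff(t) != 0])
    t, df = t[keep], df[keep]
    if np.any(np.diff(t) < 0):
        raise FormatError("reference track times are not monotonic")
    x, y = frame.to_local_arrays(df["lat"], df["lon"])
    return ReferenceTrack(t, np.column_stack([x, y]), stated_accuracy_m)


def write_reference_track(track: ReferenceTrack, frame: LocalFrame, path) -> None:
    lat, lon = frame.to_geo_arrays(track.xy[:, 0], track.xy[:, 1])
    out = pd.DataFrame({"time": seconds_to_iso(track.times),
                        "lat": lat, "lon": lon})
    out.to_csv(path, index=False)


# -- geofence ----------------------------------------------------------------

def read_geofence(path) -> GeofencePolygon:
    """First polygon of a GeoJSON file -> geofence (exterior ring only)."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geom = gj["features"][0]["geometry"]
        name = gj["features"][0].get("properties", {}).get("name", "geofence")
    elif gj.get("type") == "Feature":
        geom, name = gj["geometry"], gj.get("properties", {}).get("name", "geofence")
    else:
        geom, name = gj, "geofence"
    if geom["type"] != "Polygon":
        raise FormatError(f"expected a Polygon geometry, got {geom['type']}")
    ring = geom["coordinates"][0]
    if ring[0] == ring[-1]:
        ring = ring[:-1]
    return GeofencePolygon(tuple(GeoPoint(lat, lon) for lon, lat in ring), name)


# -- config ------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError("config file must contain a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
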