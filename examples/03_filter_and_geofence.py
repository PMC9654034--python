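"""Plausibility filtering and geofence crossings.

False detections produce fixes far from the array; the filter keeps only
fixes within 200 m of at least one receiver.  The geofence watcher emits
an event whenever consecutive track points straddle a polygon boundary.
"""

import pandas as pd

from aquapos import FilterPolicy, GeofencePolygon, filter_positions, geofence_events
from aquapos.filtering import retention_percent
from aquapos.geo import GeoPoint, LocalPoint
from aquapos.simulator import equilateral_array
from aquapos.tdoa import PositionFix

receivers = equilateral_array(spacing=270.0, n=3)

fixes = [
    PositionFix("tag", float(t), LocalPoint(x, y), 3, 0.0, True)
    for t, (x, y) in enumerate([(0, 0), (50, -30), (-80, 40),   # plausible
                                (900, 900), (-1200, 300)])       # implausible
]
retained, removed = filter_positions(fixes, receivers, FilterPolicy(radius_m=200.0))
print(f"retained {len(retained)}/{len(fixes)} fixes "
      f"({retention_percent(len(fixes), len(retained))}%); "
      f"removed fixes were {len(removed)}")

# A protected square; the track enters and then leaves it.
fence = GeofencePolygon((
    GeoPoint(42.550, 9.480), GeoPoint(42.550, 9.490),
    GeoPoint(42.558, 9.490), GeoPoint(42.558, 9.480)), name="reserve")
track = pd.DataFrame({
    "time": [0.0, 60.0, 120.0, 180.0],
    "lat": [42.545, 42.552, 42.555, 42.560],
    "lon": [9.485, 9.485, 9.485, 9.485],
})
events = geofence_events(track, fence)
print(events.to_string(index=False))
# One "in" event as the animal enters the reserve, one "out" as it exits;
# the field system turns these into e-mail alerts.
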