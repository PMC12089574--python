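"""Great-circle geometry on the WGS84 mean-radius sphere.

All distances are kilometres on a sphere of radius 6371.0088 km (the IUGG
mean Earth radius); coordinates are decimal degrees, longitude/latitude
order, WGS84.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points (arrays broadcast)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def destination_point(lon, lat, bearing_deg, distance_km):
    """Point reached from (lon, lat) travelling ``distance_km`` along the
    initial bearing (degrees clockwise from north) on a great circle."""
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    theta = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    lat2 = np.arcsin(np.sin(lat) * np.cos(delta)
                     + np.cos(lat) * np.sin(delta) * np.cos(theta))
    lon2 = lon + np.arctan2(np.sin(theta) * np.sin(delta) * np.cos(lat),
                            np.cos(delta) - np.sin(lat) * np.sin(lat2))
    lon2 = (np.degrees(lon2) + 180.0) % 360.0 - 180.0
    return lon2, np.degrees(lat2)


def pairwise_min_distance_km(lons, lats, hub_lons, hub_lats):
    """For each query point, the minimum haversine distance to any hub point.

    Chunked over query points to bound memory on large hubs.
    """
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    hub_lons = np.asarray(hub_lons, dtype=float)
    hub_lats = np.asarray(hub_lats, dtype=float)
    if hub_lons.size == 0:
        raise ValueError("hub is empty")
    out = np.empty(lons.shape[0])
    chunk = max(1, int(2_000_000 / max(1, hub_lons.size)))
    for start in range(0, lons.shape[0], chunk):
        sl = slice(start, start + chunk)
        d = haversine_km(lons[sl][:, None], lats[sl][:, None],
                         hub_lons[None, :], hub_lats[None, :])
        out[sl] = d.min(axis=1)
    return out


def spherical_centroid(polygon):
    """Area-weighted centroid of a shapely polygon in lon/lat degrees.

    Computed in a local equirectangular frame scaled by cos(mean latitude),
    which makes the planar area element proportional to spherical area for
    the region sizes used here (member states, synthetic regions).
    """
    from shapely import affinity

    lat0 = polygon.centroid.y  # first guess from the unweighted centroid
    cos0 = max(np.cos(np.radians(lat0)), 1e-9)
    projected = affinity.scale(polygon, xfact=cos0, yfact=1.0, origin=(0, 0))
    c = projected.centroid
    return c.x / cos0, c.y
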