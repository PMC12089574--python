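"""Migration-extent analysis.

Transient occurrence records (cells with EI = 0 but GI_A > 0) are
interpreted as seasonal populations founded each year by migration from
the nearest area of permanent establishment ("hub": all cells with
EI > 0). The distances from each transient record to the nearest hub cell
form an empirical distribution whose percentiles delimit dispersal
frequency zones, and whose ECDF converts a region's distance from the hub
into an annual presence probability PP = 1 - F(D).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import Point, shape, mapping
from shapely.ops import unary_union

from fawrisk.geo import (
    haversine_km,
    destination_point,
    pairwise_min_distance_km,
    spherical_centroid,
)

POPULATION_CLASSES = ("permanent", "transient", "outside", "excluded")


# ---------------------------------------------------------------------------
# population classification
# ---------------------------------------------------------------------------

def _sample_raster(da: xr.DataArray, lons, lats):
    """Nearest-cell raster values at points; NaN where outside the extent."""
    lat = da["lat"].values
    lon = da["lon"].values
    dlat = np.abs(np.diff(lat)).mean() if lat.size > 1 else 1.0
    dlon = np.abs(np.diff(lon)).mean() if lon.size > 1 else 1.0
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    inside = (
        (lats >= lat.min() - dlat / 2) & (lats <= lat.max() + dlat / 2)
        & (lons >= lon.min() - dlon / 2) & (lons <= lon.max() + dlon / 2)
    )
    values = np.full(lats.shape, np.nan)
    if inside.any():
        sel = da.sel(
            lat=xr.DataArray(lats[inside], dims="pt"),
            lon=xr.DataArray(lons[inside], dims="pt"),
            method="nearest",
        )
        values[inside] = sel.values
    return values, inside


def classify_population(
    records: pd.DataFrame,
    ei: xr.DataArray,
    gia: xr.DataArray,
    lon_col: str = "decimalLongitude",
    lat_col: str = "decimalLatitude",
) -> pd.DataFrame:
    """Append a ``population_class`` column from the EI/GI_A cell values.

    permanent: EI > 0; transient: EI = 0 and GI_A > 0; outside: both 0.
    Records outside the raster extent (or over no-data cells) are flagged
    ``no_coverage`` instead of being classified.
    """
    out = records.copy()
    ei_vals, inside = _sample_raster(ei, out[lon_col].values, out[lat_col].values)
    gia_vals, _ = _sample_raster(gia, out[lon_col].values, out[lat_col].values)
    cls = np.where(ei_vals > 0, "permanent",
                   np.where(gia_vals > 0, "transient", "outside"))
    cls = np.where(inside & ~np.isnan(ei_vals) & ~np.isnan(gia_vals),
                   cls, "no_coverage")
    out["population_class"] = cls
    out["EI"] = ei_vals
    out["GIA"] = gia_vals
    return out


def apply_exclusions(records: pd.DataFrame, exclusion_geometries,
                     lon_col: str = "decimalLongitude",
                     lat_col: str = "decimalLatitude"):
    """Split records into (kept, excluded) by a list of exclusion polygons.

    Generalises the removal of records from isolated areas (e.g. oceanic
    islands inside the hub) whose inclusion would inflate the apparent
    overseas flight distances.
    """
    geoms = [shape(g) if isinstance(g, dict) else g for g in (exclusion_geometries or [])]
    if not geoms:
        return records.copy(), records.iloc[0:0].copy()
    union = unary_union(geoms)
    pts = [Point(x, y) for x, y in zip(records[lon_col], records[lat_col])]
    mask = np.array([union.covers(pt) for pt in pts], dtype=bool)
    return records[~mask].copy(), records[mask].copy()


# ---------------------------------------------------------------------------
# hub distances and the ECDF
# ---------------------------------------------------------------------------

def hub_cells(ei: xr.DataArray) -> pd.DataFrame:
    """Cell centres of the permanent-establishment hub (EI > 0)."""
    lat2d, lon2d = np.meshgrid(ei["lat"].values, ei["lon"].values, indexing="ij")
    mask = ei.values > 0
    return pd.DataFrame({"lon": lon2d[mask], "lat": lat2d[mask]})


def distance_to_nearest_hub(lons, lats, hub_lons, hub_lats) -> np.ndarray:
    """Great-circle distance (km) from each point to its nearest hub cell centre."""
    return pairwise_min_distance_km(lons, lats, hub_lons, hub_lats)


@dataclass
class DistanceDistribution:
    """Sorted hub distances with their right-continuous empirical CDF."""

    distances: np.ndarray  # sorted ascending, km
    n: int = field(init=False)

    def __post_init__(self):
        d = np.sort(np.asarray(self.distances, dtype=float))
        if d.size == 0:
            raise ValueError("cannot build an ECDF from an empty sample")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        self.distances = d
        self.n = int(d.size)

    def ecdf(self, d) -> np.ndarray:
        """F(d): proportion of observed distances <= d (step function)."""
        idx = np.searchsorted(self.distances, np.asarray(d, dtype=float),
                              side="right")
        return idx / self.n

    def percentile(self, p) -> np.ndarray:
        """p-th percentile (0..100), linear interpolation between order
        statistics (numpy's inclusive convention); percentile(50) is the
        sample median."""
        p_arr = np.asarray(p, dtype=float)
        if np.any((p_arr < 0) | (p_arr > 100)):
            raise ValueError("percentile must lie in [0, 100]")
        return np.percentile(self.distances, p)

    def presence_probability(self, d) -> np.ndarray:
        """PP = 1 - F(d): annual probability that migration reaches distance d."""
        if np.any(np.asarray(d, dtype=float) < 0):
            raise ValueError("distance must be non-negative")
        return 1.0 - self.ecdf(d)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "distance_km": self.distances,
            "F": self.ecdf(self.distances),
        })


def build_ecdf(distances) -> DistanceDistribution:
    """Build the empirical distance distribution from a sample of hub distances."""
    return DistanceDistribution(np.asarray(distances, dtype=float))


# ---------------------------------------------------------------------------
# dispersal frequency zones
# ---------------------------------------------------------------------------

def _geodesic_circle(lon: float, lat: float, radius_km: float,
                     n_vertices: int = 64):
    bearings = np.linspace(0.0, 360.0, n_vertices, endpoint=False)
    xs, ys = destination_point(lon, lat, bearings, radius_km)
    from shapely.geometry import Polygon
    return Polygon(zip(xs, ys))


def buffer_zones(hub_geometry, radii_km, percentiles=None, n_vertices: int = 64):
    """Nested geodesic buffer zones around the hub at the given radii (km).

    ``hub_geometry`` may be a shapely geometry or a DataFrame of hub cell
    centres (columns lon/lat). Buffers are unions of geodesic circles
    around the geometry's vertices/points, merged with the hub itself, so
    every zone contains the hub and zones nest by construction. Intended
    for display/export; distance arithmetic stays on the raster hub.
    """
    import pandas as pd  # noqa: F811 (local clarity)
    radii = list(radii_km)
    if radii != sorted(radii):
        raise ValueError("radii must be sorted ascending")
    if isinstance(hub_geometry, pd.DataFrame):
        points = list(zip(hub_geometry["lon"], hub_geometry["lat"]))
        base = unary_union([Point(x, y) for x, y in points])
    else:
        base = hub_geometry
        if base.geom_type == "Polygon":
            points = list(base.exterior.coords)
        elif base.geom_type == "MultiPoint":
            points = [(g.x, g.y) for g in base.geoms]
        elif base.geom_type == "Point":
            points = [(base.x, base.y)]
        else:
            points = [(x, y) for geom in getattr(base, "geoms", [base])
                      for x, y in geom.exterior.coords]
    labels = percentiles if percentiles is not None else radii
    zones = []
    for radius, label in zip(radii, labels):
        if radius == 0:
            zones.append({"percentile": label, "radius_km": 0.0, "geometry": base})
            continue
        circles = [_geodesic_circle(x, y, radius, n_vertices) for x, y in points]
        geom = unary_union(circles + [base])
        zones.append({"percentile": label, "radius_km": float(radius),
                      "geometry": geom})
    return zones


def zones_to_geojson(zones, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"percentile": z["percentile"],
                           "radius_km": z["radius_km"]},
            "geometry": mapping(z["geometry"]),
        }
        for z in zones
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# ---------------------------------------------------------------------------
# regional presence probability
# ---------------------------------------------------------------------------

def region_hub_distance(region_geometry, hub_lons, hub_lats) -> float:
    """Great-circle distance (km) from a region's centroid to the nearest hub cell."""
    if isinstance(region_geometry, dict):
        region_geometry = shape(region_geometry)
    if region_geometry.is_empty:
        raise ValueError("region geometry is empty")
    if region_geometry.geom_type == "Point":
        lon, lat = region_geometry.x, region_geometry.y
    else:
        lon, lat = spherical_centroid(region_geometry)
    return float(pairwise_min_distance_km([lon], [lat], hub_lons, hub_lats)[0])


def presence_probability_table(regions: dict, hub: pd.DataFrame,
                               dist: DistanceDistribution) -> pd.DataFrame:
    """PP per named region: distance from its centroid to the hub, then 1 - F(D)."""
    rows = []
    for name, geom in regions.items():
        d = region_hub_distance(geom, hub["lon"].values, hub["lat"].values)
        rows.append({"region": name, "D_km": d,
                     "PP": float(dist.presence_probability(d))})
    return pd.DataFrame(rows)
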