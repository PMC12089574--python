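"""Synthetic fixtures: a designed climate world, occurrence records with a
known dispersal kernel, and economic panels with known parameters.

The synthetic world is a 40 x 80 cell grid at 0.5° resolution spanning
latitudes 0-20° with four designed latitudinal climate bands:

* **tropical** (0-5°): warm and moist year-round — built to yield EI > 30
  (permanent, optimal);
* **mediterranean** (5-10°): mild winters, warm summers, adequate rain —
  permanent establishment with modest cold-stress accumulation. Its
  westernmost columns form a **dry stripe** (desert rainfall, irrigated
  mask set) that is unsuitable rainfed but suitable under irrigation;
* **continental** (10-15°): warm moist summers but winters far below the
  cold-stress threshold — transient only (EI = 0, GI_A > 0);
* **polar** (15-20°): summers below the development threshold — GI_A = 0.

These constructions target the engine's qualitative regimes, not any real
geography. Occurrences are placed at distances drawn from a right-skewed
two-component gamma mixture (multimodal, like observed seasonal migration
distance distributions) due north of the hub's northern edge, so the
sampled draw is also the realized nearest-hub distance; a stated fraction
of records is replaced by truth-labelled dirty rows exercising every
cleaning filter. All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xarray as xr
from scipy import optimize, stats

from fawrisk.geo import destination_point

ZONE_NAMES = ("tropical", "mediterranean", "mediterranean_dry",
              "continental", "polar")
#: intended engine outcome per zone
ZONE_INTENT = {
    "tropical": "permanent",
    "mediterranean": "permanent",
    "mediterranean_dry": "irrigation_dependent",
    "continental": "transient",
    "polar": "unsuitable",
}


@dataclass(frozen=True)
class SyntheticWorldSpec:
    """Deterministic description of the synthetic climate world."""

    nlat: int = 40
    nlon: int = 80
    resolution_deg: float = 0.5
    lat_origin: float = 0.0   # southern grid edge
    lon_origin: float = 0.0   # western grid edge
    #: band boundaries in degrees latitude (south to north)
    band_edges: tuple = (5.0, 10.0, 15.0)
    #: number of westernmost columns of the mediterranean band forming the
    #: irrigated dry stripe
    dry_stripe_cols: int = 10
    temp_noise_sd: float = 0.3      # °C, per cell
    rain_noise_sd: float = 0.05     # lognormal sigma, per cell
    seed: int = 0


@dataclass(frozen=True)
class DispersalKernelSpec:
    """Right-skewed, bimodal mixture of gamma components (distances in km)."""

    weights: tuple = (0.7, 0.3)
    shapes: tuple = (2.0, 6.0)
    scales: tuple = (150.0, 200.0)

    def __post_init__(self):
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=self.weights)
        out = np.empty(n)
        for k, (a, s) in enumerate(zip(self.shapes, self.scales)):
            mask = comp == k
            out[mask] = rng.gamma(a, s, size=int(mask.sum()))
        return out

    def cdf(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        return sum(w * stats.gamma.cdf(d, a, scale=s)
                   for w, a, s in zip(self.weights, self.shapes, self.scales))

    def quantile(self, p: float) -> float:
        """True mixture quantile by numeric inversion (|CDF error| < 1e-6)."""
        if not 0.0 < p < 1.0:
            raise ValueError("p must lie in (0, 1)")
        hi = max(stats.gamma.ppf(p, a, scale=s) + 1.0
                 for a, s in zip(self.shapes, self.scales)) + 1e4
        return float(optimize.brentq(lambda d: self.cdf(d) - p, 0.0, hi,
                                     xtol=1e-8))


# ---------------------------------------------------------------------------
# climate world
# ---------------------------------------------------------------------------

# per band: mean annual Tavg at the band's southern edge (°C), within-band
# latitudinal trend (°C per degree), seasonal amplitude (°C), monthly rain
# (mm) and mean relative humidity (%)
_BAND_CLIMATE = {
    "tropical":          dict(t0=27.0, slope=-0.3, amp=3.0, rain=140.0, rh=78.0),
    "mediterranean":     dict(t0=20.0, slope=-0.2, amp=6.0, rain=80.0, rh=65.0),
    "mediterranean_dry": dict(t0=20.0, slope=-0.2, amp=6.0, rain=5.0, rh=40.0),
    "continental":       dict(t0=8.0, slope=-0.2, amp=14.0, rain=75.0, rh=70.0),
    "polar":             dict(t0=-12.0, slope=-0.4, amp=8.0, rain=40.0, rh=80.0),
}
#: half daily range: Tmin = Tavg - 5, Tmax = Tavg + 5
_DIURNAL_HALF_RANGE = 5.0


def _zone_of(lat: float, lon: float, spec: SyntheticWorldSpec) -> str:
    e1, e2, e3 = spec.band_edges
    if lat < e1:
        return "tropical"
    if lat < e2:
        stripe_end = spec.lon_origin + spec.dry_stripe_cols * spec.resolution_deg
        return "mediterranean_dry" if lon < stripe_end else "mediterranean"
    if lat < e3:
        return "continental"
    return "polar"


def gen_climate_grid(spec: SyntheticWorldSpec = None):
    """Generate the synthetic world.

    Returns ``(monthly, irrigation_mask, zone_truth)``: a monthly climate
    Dataset (tmin, tmax, prec, rh09, rh15 on dims month/lat/lon), a 0/1
    irrigation mask, and a zone-truth DataArray of band names.
    """
    spec = spec or SyntheticWorldSpec()
    if spec.nlat < 1 or spec.nlon < 1:
        raise ValueError("degenerate grid extent")
    rng = np.random.default_rng(spec.seed)
    res = spec.resolution_deg
    lats = spec.lat_origin + (np.arange(spec.nlat) + 0.5) * res
    lons = spec.lon_origin + (np.arange(spec.nlon) + 0.5) * res

    months = np.arange(12)
    # seasonal cycle peaking mid-year (northern-hemisphere-like)
    season = -np.cos(2 * np.pi * (months + 0.5) / 12.0)

    shape = (12, spec.nlat, spec.nlon)
    tavg = np.zeros(shape)
    prec = np.zeros(shape)
    rh = np.zeros(shape)
    mask = np.zeros((spec.nlat, spec.nlon))
    zones = np.empty((spec.nlat, spec.nlon), dtype=object)

    t_noise = rng.normal(0.0, spec.temp_noise_sd, size=(spec.nlat, spec.nlon))
    r_noise = np.exp(rng.normal(0.0, spec.rain_noise_sd,
                                size=(spec.nlat, spec.nlon)))

    for i, lat in enumerate(lats):
        for j, lon in enumerate(lons):
            zone = _zone_of(lat, lon, spec)
            zones[i, j] = zone
            band = _BAND_CLIMATE[zone]
            band_start = {"tropical": 0.0, "mediterranean": spec.band_edges[0],
                          "mediterranean_dry": spec.band_edges[0],
                          "continental": spec.band_edges[1],
                          "polar": spec.band_edges[2]}[zone]
            t_mean = band["t0"] + band["slope"] * (lat - band_start) + t_noise[i, j]
            tavg[:, i, j] = t_mean + band["amp"] * season
            prec[:, i, j] = band["rain"] * r_noise[i, j]
            rh[:, i, j] = band["rh"]
            if zone == "mediterranean_dry":
                mask[i, j] = 1.0

    coords = {"month": months + 1, "lat": lats, "lon": lons}
    monthly = xr.Dataset(
        {
            "tmin": (("month", "lat", "lon"), tavg - _DIURNAL_HALF_RANGE),
            "tmax": (("month", "lat", "lon"), tavg + _DIURNAL_HALF_RANGE),
            "prec": (("month", "lat", "lon"), prec),
            "rh09": (("month", "lat", "lon"), np.clip(rh + 5.0, 0, 100)),
            "rh15": (("month", "lat", "lon"), np.clip(rh - 5.0, 0, 100)),
        },
        coords=coords,
        attrs={"crs": "EPSG:4326", "title": "fawrisk synthetic world"},
    )
    irrigation = xr.DataArray(mask, coords={"lat": lats, "lon": lons},
                              dims=("lat", "lon"), name="irrigated")
    zone_truth = xr.DataArray(zones, coords={"lat": lats, "lon": lons},
                              dims=("lat", "lon"), name="zone")
    return monthly, irrigation, zone_truth


# ---------------------------------------------------------------------------
# occurrences
# ---------------------------------------------------------------------------

_DIRTY_KINDS = (
    "null_island", "missing_coordinates", "pre_cutoff_year", "fossil_basis",
    "absent_status", "high_uncertainty", "centroid_flag", "capital_flag",
    "zoo_flag", "ocean_flag", "duplicate",
)


def northern_edge(hub: pd.DataFrame) -> pd.DataFrame:
    """Northernmost hub cell per longitude column (the hub's leading edge)."""
    return hub.loc[hub.groupby("lon")["lat"].idxmax()].reset_index(drop=True)


def northern_front(hub: pd.DataFrame, tol: float = 1e-6) -> pd.DataFrame:
    """Edge cells at the hub's overall northernmost latitude.

    Launching migrants from this flat front guarantees that no hub cell
    lies north of any origin, so a due-north flight of distance d ends
    exactly d from its nearest hub cell.
    """
    edge = northern_edge(hub)
    return edge[edge["lat"] >= edge["lat"].max() - tol].reset_index(drop=True)


def gen_occurrences(
    hub: pd.DataFrame,
    kernel: DispersalKernelSpec = None,
    n: int = 1000,
    dirty_fraction: float = 0.1,
    seed: int = 0,
    bearing_jitter_deg: float = 2.0,
) -> pd.DataFrame:
    """Generate an occurrence table of ``n`` rows with truth labels.

    Clean rows are placed at kernel-sampled distances from random cells of
    the hub's northernmost front, on bearings within ``bearing_jitter_deg``
    of due north so the sampled distance equals the realized nearest-hub
    distance (to within the bearing geometry error). ``round(dirty_fraction
    * n)`` rows are dirty, cycling through every cleaning-filter category;
    column ``truth_dirty`` marks them and ``truth_reason`` names the filter
    expected to remove each one (duplicates fall to deduplication).
    """
    if hub.empty:
        raise ValueError("hub is empty")
    kernel = kernel or DispersalKernelSpec()
    rng = np.random.default_rng(seed)
    n_dirty = int(round(dirty_fraction * n))
    n_clean = n - n_dirty

    edge = northern_front(hub)
    origins = edge.sample(n=n_clean, replace=True,
                          random_state=rng.integers(2**31)).reset_index(drop=True)
    distances = kernel.sample(n_clean, rng)
    bearings = rng.uniform(-bearing_jitter_deg, bearing_jitter_deg, size=n_clean)
    lon, lat = destination_point(origins["lon"].values, origins["lat"].values,
                                 bearings, distances)
    clean = pd.DataFrame({
        "decimalLongitude": lon,
        "decimalLatitude": lat,
        "year": rng.integers(2005, 2024, size=n_clean),
        "basisOfRecord": "HUMAN_OBSERVATION",
        "occurrenceStatus": "PRESENT",
        "coordinateUncertaintyInMeters": rng.uniform(10, 1000, size=n_clean),
        "source": "synthetic_survey",
        "is_centroid": False,
        "is_capital": False,
        "is_zoo_herbarium": False,
        "in_ocean": False,
        "truth_dirty": False,
        "truth_reason": "",
        "truth_distance_km": distances,
    })

    dirty_rows = []
    for k in range(n_dirty):
        kind = _DIRTY_KINDS[k % len(_DIRTY_KINDS)]
        base_idx = int(rng.integers(n_clean)) if n_clean else 0
        base = clean.iloc[base_idx].to_dict() if n_clean else {
            "decimalLongitude": 10.0, "decimalLatitude": 10.0, "year": 2020,
            "coordinateUncertaintyInMeters": 100.0,
        }
        row = {
            "decimalLongitude": float(base["decimalLongitude"]) + 0.01 * (k + 1),
            "decimalLatitude": float(base["decimalLatitude"]),
            "year": 2015,
            "basisOfRecord": "HUMAN_OBSERVATION",
            "occurrenceStatus": "PRESENT",
            "coordinateUncertaintyInMeters": 100.0,
            "source": "synthetic_dirty",
            "is_centroid": False, "is_capital": False,
            "is_zoo_herbarium": False, "in_ocean": False,
            "truth_dirty": True, "truth_reason": kind,
            "truth_distance_km": np.nan,
        }
        if kind == "null_island":
            row["decimalLongitude"] = 0.0
            row["decimalLatitude"] = 0.0
        elif kind == "missing_coordinates":
            row["decimalLongitude"] = np.nan
            row["decimalLatitude"] = np.nan
        elif kind == "pre_cutoff_year":
            row["year"] = int(rng.integers(1900, 1950))
        elif kind == "fossil_basis":
            row["basisOfRecord"] = "FOSSIL_SPECIMEN"
        elif kind == "absent_status":
            row["occurrenceStatus"] = "ABSENT"
        elif kind == "high_uncertainty":
            row["coordinateUncertaintyInMeters"] = 50_000.0
        elif kind == "centroid_flag":
            row["is_centroid"] = True
        elif kind == "capital_flag":
            row["is_capital"] = True
        elif kind == "zoo_flag":
            row["is_zoo_herbarium"] = True
        elif kind == "ocean_flag":
            row["in_ocean"] = True
        elif kind == "duplicate":
            # exact duplicate key of an existing clean record, other source
            row["decimalLongitude"] = float(base["decimalLongitude"])
            row["decimalLatitude"] = float(base["decimalLatitude"])
            row["year"] = int(base["year"])
            row["source"] = "synthetic_duplicate"
        dirty_rows.append(row)

    # dirty rows follow the clean block so duplicate keys resolve keep-first
    # to the clean original; clean rows are shuffled deterministically
    order = rng.permutation(n_clean)
    frames = [clean.iloc[order].reset_index(drop=True)]
    if dirty_rows:
        frames.append(pd.DataFrame(dirty_rows))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# economics
# ---------------------------------------------------------------------------

def gen_econ_panel(
    n_states: int = 5,
    n_years: int = 5,
    seed: int = 0,
    revenue_range=(500.0, 1500.0),
    margin_range=(0.2, 0.6),
    area_range=(50_000.0, 1_000_000.0),
    distance_range=(100.0, 700.0),
):
    """Generate (panel, yield_losses, distances, truth) for the economics stage.

    Revenues per state-year vary around a state mean; operating costs are a
    state-specific fraction of revenue (so gross margins stay positive);
    yield-loss percentile triplets are ordered by construction. State hub
    distances are drawn within the synthetic world's transient reach (its
    continental band ends ~750 km from the hub edge), mirroring assessments
    where every region at risk lies inside the maximal observed migration
    distance. ``truth`` records every generating parameter plus the
    realized panel means, so closed-form identity checks can be exact.
    """
    if n_states < 1 or n_years < 1:
        raise ValueError("need at least one state and one year")
    rng = np.random.default_rng(seed)
    states = [f"State{chr(65 + i)}" for i in range(n_states)]
    rows, yl_rows, d_rows = [], [], []
    truth = {"seed": seed, "states": {}}
    for s in states:
        r_mean = rng.uniform(*revenue_range)
        cost_frac = 1.0 - rng.uniform(*margin_range)
        area = rng.uniform(*area_range)
        revenues = r_mean * (1.0 + rng.normal(0.0, 0.05, size=n_years))
        costs = cost_frac * revenues * (1.0 + rng.normal(0.0, 0.03, size=n_years))
        for t, (r, c) in enumerate(zip(revenues, costs)):
            rows.append({"state": s, "year": 2010 + t, "revenue": r,
                         "cost": c, "area": area})
        p50 = rng.uniform(5.0, 40.0)
        best = p50 * rng.uniform(0.05, 0.3)
        worst = p50 + (100.0 - p50) * rng.uniform(0.3, 0.8)
        yl_rows.append({"state": s, "best": best, "moderate": p50,
                        "worst": worst})
        d_km = rng.uniform(*distance_range)
        d_rows.append({"state": s, "D_km": d_km})
        truth["states"][s] = {
            "revenue_mean_generating": float(r_mean),
            "cost_fraction": float(cost_frac),
            "area_ha": float(area),
            "revenue_mean_realized": float(np.mean(revenues)),
            "cost_mean_realized": float(np.mean(costs)),
            "yield_loss": {"best": float(best), "moderate": float(p50),
                           "worst": float(worst)},
            "D_km": float(d_km),
        }
    return (pd.DataFrame(rows), pd.DataFrame(yl_rows), pd.DataFrame(d_rows),
            truth)


def world_spec_dict(spec: SyntheticWorldSpec) -> dict:
    return asdict(spec)
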