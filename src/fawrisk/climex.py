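"""Process-based climatic niche engine (CLIMEX-style Compare Locations).

For every grid cell the engine computes, from a 52-week climatology:

* a weekly Temperature Index TI (trapezoid over DV0..DV3) and Moisture
  Index MI (trapezoid over SM0..SM3 on a soil-moisture bucket),
* the annual Growth Index ``GI_A = 100 * mean(TI*MI)``,
* four accumulated stress indices (cold, heat, dry, wet) on a 0-100 scale
  where 100 is lethal,
* the annual degree-day sum above DV0, and
* the Ecoclimatic Index ``EI = GI_A * prod(1 - S/100)``, forced to zero
  when any stress saturates or the degree-day sum falls short of the
  minimum generation requirement PDD.

EI > 0 marks cells where the species can persist year-round (permanent
populations); EI = 0 with GI_A > 0 marks cells that support only seasonal,
migration-founded (transient) populations.

The exact internals of the commercial CLIMEX binary are proprietary;
this engine implements the published semantics (trapezoidal growth
indices, multiplicative stress discounting, weekly stress accumulation)
and is validated through invariants and constructed climate profiles, not
bit-comparison. See docs/methods.md for the choices made where the
published description is silent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from fawrisk.climate import (
    N_WEEKS,
    DAYS_PER_WEEK,
    CLIMATE_VARIABLES,
    monthly_to_weekly,
)
from fawrisk.params import SpeciesParameters

#: suitability classes in increasing order of the Ecoclimatic Index
SUITABILITY_CLASSES = ("unsuitable", "marginal", "moderate", "suitable", "optimal")

#: default soil bucket size, mm
SOIL_CAPACITY_MM = 100.0
#: evapotranspiration demand coefficient, mm water per °C per week
ET_COEFFICIENT = 1.0
#: upper clamp on the soil-moisture index (super-saturation states)
SATURATION_CAP = 3.0


# ---------------------------------------------------------------------------
# growth indices
# ---------------------------------------------------------------------------

def _trapezoid(x, lo, opt_lo, opt_hi, hi):
    """Piecewise-linear response: 0 outside [lo, hi], 1 on [opt_lo, opt_hi]."""
    x = np.asarray(x, dtype=float)
    rising = np.clip((x - lo) / (opt_lo - lo), 0.0, 1.0)
    falling = np.clip((hi - x) / (hi - opt_hi), 0.0, 1.0) if hi > opt_hi else 1.0
    return np.minimum(rising, falling)


def temperature_index(tavg, p: SpeciesParameters = None):
    """Weekly temperature index TI in [0, 1] from mean temperature (°C)."""
    p = p or SpeciesParameters()
    return _trapezoid(tavg, p.DV0, p.DV1, p.DV2, p.DV3)


def moisture_index(sm, p: SpeciesParameters = None):
    """Weekly moisture index MI in [0, 1] from the soil-moisture index."""
    p = p or SpeciesParameters()
    return _trapezoid(sm, p.SM0, p.SM1, p.SM2, p.SM3)


def annual_growth_index(ti, mi) -> np.ndarray:
    """GI_A = 100 * mean of the weekly growth index TI*MI over 52 weeks.

    ``ti``/``mi`` have the week axis first; extra axes broadcast.
    """
    ti = np.asarray(ti, dtype=float)
    mi = np.asarray(mi, dtype=float)
    if ti.shape != mi.shape:
        raise ValueError(f"TI and MI shapes differ: {ti.shape} vs {mi.shape}")
    if ti.shape[0] != N_WEEKS:
        raise ValueError(f"expected {N_WEEKS} weeks, got {ti.shape[0]}")
    return 100.0 * (ti * mi).sum(axis=0) / N_WEEKS


def annual_degree_days(tavg, dv0: float) -> np.ndarray:
    """Annual degree-day sum above ``dv0``: sum of weekly max(0, Tavg-DV0)*7."""
    tavg = np.asarray(tavg, dtype=float)
    if tavg.shape[0] != N_WEEKS:
        raise ValueError(f"expected {N_WEEKS} weeks, got {tavg.shape[0]}")
    return np.maximum(0.0, tavg - dv0).sum(axis=0) * DAYS_PER_WEEK


# ---------------------------------------------------------------------------
# soil moisture
# ---------------------------------------------------------------------------

@dataclass
class SoilMoistureState:
    """Converged weekly soil-moisture series for one or more cells.

    ``index`` is the weekly soil-moisture index on the fraction-of-capacity
    scale the MI/stress thresholds use (0 dry, 1 at field capacity, above 1
    transient super-saturation up to :data:`SATURATION_CAP`); ``storage`` is
    the carried-over water store as a fraction of capacity in [0, 1].
    """

    index: np.ndarray    # (52, ...) in [0, SATURATION_CAP]
    storage: np.ndarray  # (52, ...) in [0, 1]
    capacity_mm: float
    cycles: int


def evapotranspiration_demand(tavg, rh_mean, et_coefficient: float = ET_COEFFICIENT):
    """Weekly evapotranspiration demand (mm): k * max(0, Tavg) * (1 - RH/100)."""
    tavg = np.asarray(tavg, dtype=float)
    rh_mean = np.asarray(rh_mean, dtype=float)
    return et_coefficient * np.maximum(0.0, tavg) * (1.0 - rh_mean / 100.0)


def soil_moisture_series(
    prec,
    tavg,
    rh_mean,
    capacity_mm: float = SOIL_CAPACITY_MM,
    et_coefficient: float = ET_COEFFICIENT,
    tol: float = 1e-6,
    max_cycles: int = 500,
    cell_label: str = "grid",
) -> SoilMoistureState:
    """Iterate the weekly bucket over repeated annual cycles to its fixed point.

    Weekly balance: inflow = precipitation, outflow = evapotranspiration
    demand. The carried storage is clamped to [0, capacity] (runoff below /
    above the bucket); the reported index is the pre-runoff balance, so a
    week whose inflow would overfill the bucket shows super-saturation
    (index > 1) without that excess persisting into later weeks.
    """
    prec = np.asarray(prec, dtype=float)
    if prec.shape[0] != N_WEEKS:
        raise ValueError(f"expected {N_WEEKS} weeks, got {prec.shape[0]}")
    if capacity_mm <= 0:
        raise ValueError("soil capacity must be positive")
    demand = evapotranspiration_demand(tavg, rh_mean, et_coefficient)
    net = (prec - demand) / capacity_mm  # fraction of capacity per week

    storage = np.full(prec.shape[1:], 0.5, dtype=float)
    index = np.zeros_like(net)
    store_series = np.zeros_like(net)
    prev_series = None
    for cycle in range(1, max_cycles + 1):
        for w in range(N_WEEKS):
            balance = storage + net[w]
            index[w] = np.clip(balance, 0.0, SATURATION_CAP)
            storage = np.clip(balance, 0.0, 1.0)
            store_series[w] = storage
        if prev_series is not None:
            delta = np.nanmax(np.abs(store_series - prev_series)) if store_series.size else 0.0
            if delta < tol:
                return SoilMoistureState(index.copy(), store_series.copy(),
                                         capacity_mm, cycle)
        prev_series = store_series.copy()
    raise RuntimeError(
        f"soil-moisture spin-up did not converge within {max_cycles} cycles "
        f"for cell(s) {cell_label!r}"
    )


# ---------------------------------------------------------------------------
# stress accumulation
# ---------------------------------------------------------------------------

def _episode_lengths(breach: np.ndarray) -> np.ndarray:
    """Elapsed-week count within each contiguous stress episode (periodic year).

    ``breach`` is boolean with the week axis first. Episodes that wrap from
    week 52 into week 1 continue their count; a year breaching in every week
    counts 1..52.
    """
    tiled = np.concatenate([breach, breach], axis=0).astype(float)
    counts = np.zeros_like(tiled)
    running = np.zeros(breach.shape[1:], dtype=float)
    for w in range(2 * N_WEEKS):
        running = np.where(tiled[w] > 0, running + 1, 0.0)
        counts[w] = running
    out = counts[N_WEEKS:]
    always = breach.all(axis=0)
    if np.any(always):
        ramp = np.arange(1, N_WEEKS + 1, dtype=float)
        ramp = ramp.reshape((N_WEEKS,) + (1,) * (breach.ndim - 1))
        out = np.where(always, ramp, out)
    return out


def stress_index(
    driver,
    threshold: float,
    rate: float,
    direction: str,
    ramp: str = "linear",
) -> np.ndarray:
    """Accumulate one annual stress index on the 0-100 scale.

    Weekly deficit: amount by which the driver falls below (``direction=
    'below'``) or exceeds (``'above'``) the threshold. The weekly increment
    is |rate| * deficit, expressed in percent; with the default linear time
    ramp each increment is additionally multiplied by the elapsed-week count
    of its stress episode, approximating the accelerating accumulation of
    prolonged stress. The annual sum is clipped to [0, 100]; 100 is lethal.
    """
    driver = np.asarray(driver, dtype=float)
    if driver.shape[0] != N_WEEKS:
        raise ValueError(f"expected {N_WEEKS} weeks, got {driver.shape[0]}")
    if direction == "below":
        deficit = np.maximum(0.0, threshold - driver)
    elif direction == "above":
        deficit = np.maximum(0.0, driver - threshold)
    else:
        raise ValueError("direction must be 'below' or 'above'")
    if ramp == "linear":
        factor = _episode_lengths(deficit > 0)
    elif ramp == "flat":
        factor = 1.0
    else:
        raise ValueError("ramp must be 'linear' or 'flat'")
    increments = abs(rate) * deficit * 100.0 * factor
    return np.clip(increments.sum(axis=0), 0.0, 100.0)


# ---------------------------------------------------------------------------
# irrigation and integration
# ---------------------------------------------------------------------------

def apply_irrigation(weekly_prec, irrigated, topup_mm_day: float, mode: str = "topup"):
    """Apply the irrigation scenario to weekly precipitation (mm/week).

    On irrigated cells the effective daily water supply is raised to the
    top-up rate wherever rainfall falls short of it (``mode='topup'``,
    i.e. max(rain, top-up)); rainfall already at or above the top-up is
    left unchanged. ``mode='additive'`` instead adds the full top-up.
    Non-irrigated cells are never modified.
    """
    if topup_mm_day < 0:
        raise ValueError("top-up must be non-negative")
    weekly_prec = np.asarray(weekly_prec, dtype=float)
    irrigated = np.asarray(irrigated, dtype=bool)
    if mode == "topup":
        adjusted = np.maximum(weekly_prec, topup_mm_day * DAYS_PER_WEEK)
    elif mode == "additive":
        adjusted = weekly_prec + topup_mm_day * DAYS_PER_WEEK
    else:
        raise ValueError("mode must be 'topup' or 'additive'")
    return np.where(irrigated, adjusted, weekly_prec)


def ecoclimatic_index(gia, cs, hs, ds, ws, dd, pdd: float) -> np.ndarray:
    """EI = GI_A discounted by each stress, zeroed by lethal stress or DD < PDD."""
    gia = np.asarray(gia, dtype=float)
    stresses = [np.asarray(s, dtype=float) for s in (cs, hs, ds, ws)]
    ei = gia.copy()
    for s in stresses:
        ei = ei * (1.0 - s / 100.0)
    lethal = np.zeros(np.shape(gia), dtype=bool)
    for s in stresses:
        lethal |= s >= 100.0
    ei = np.where(lethal | (np.asarray(dd, dtype=float) < pdd), 0.0, ei)
    return np.clip(ei, 0.0, 100.0)


def classify_suitability(ei):
    """Map EI to the five-class suitability scale.

    unsuitable: EI = 0; marginal: 0 < EI <= 5; moderate: 5 < EI <= 15;
    suitable: 15 < EI <= 30; optimal: EI > 30. Returns integer codes
    0..4 indexing :data:`SUITABILITY_CLASSES` (scalar in, scalar out).
    """
    ei_arr = np.asarray(ei, dtype=float)
    code = np.digitize(ei_arr, [0.0, 5.0, 15.0, 30.0], right=True)
    code = np.where(ei_arr <= 0.0, 0, code)
    if np.isscalar(ei) or np.ndim(ei) == 0:
        return int(code)
    return code.astype(int)


@dataclass
class SuitabilityResult:
    """Full engine output for a single cell (weekly series kept for inspection)."""

    cell_id: object
    lon: float
    lat: float
    TI: np.ndarray
    MI: np.ndarray
    GI_W: np.ndarray
    GI_A: float
    CS: float
    HS: float
    DS: float
    WS: float
    DD: float
    EI: float
    suitability: str


def _compute_arrays(weekly: dict, p: SpeciesParameters, irrigated,
                    scenario: str, ramp: str = "linear") -> dict:
    """Vectorised engine core on arrays with the week axis first."""
    if scenario not in ("rainfed", "irrigated"):
        raise ValueError("scenario must be 'rainfed' or 'irrigated'")
    tavg = (weekly["tmin"] + weekly["tmax"]) / 2.0
    rh_mean = (weekly["rh09"] + weekly["rh15"]) / 2.0
    prec = weekly["prec"]
    if scenario == "irrigated":
        prec = apply_irrigation(prec, irrigated, p.irrigation_topup)

    sm = soil_moisture_series(prec, tavg, rh_mean)
    ti = temperature_index(tavg, p)
    mi = moisture_index(sm.index, p)
    gia = annual_growth_index(ti, mi)
    cs = stress_index(weekly["tmin"], p.TTCS, p.THCS, "below", ramp)
    hs = stress_index(weekly["tmax"], p.TTHS, p.THHS, "above", ramp)
    ds = stress_index(sm.index, p.SMDS, p.HDS, "below", ramp)
    ws = stress_index(sm.index, p.SMWS, p.HWS, "above", ramp)
    dd = annual_degree_days(tavg, p.DV0)
    ei = ecoclimatic_index(gia, cs, hs, ds, ws, dd, p.PDD)
    return {"TI": ti, "MI": mi, "GI_W": ti * mi, "GIA": gia, "CS": cs,
            "HS": hs, "DS": ds, "WS": ws, "DD": dd, "EI": ei}


def suitability_for_cell(
    weekly: dict,
    p: SpeciesParameters = None,
    irrigated: bool = False,
    scenario: str = "rainfed",
    cell_id=None,
    lon: float = np.nan,
    lat: float = np.nan,
    ramp: str = "linear",
) -> SuitabilityResult:
    """Run the engine for one cell given 52-week series (dict of 1-D arrays)."""
    p = p or SpeciesParameters()
    arrays = {k: np.asarray(v, dtype=float)[:, None] for k, v in weekly.items()}
    r = _compute_arrays(arrays, p, np.array([irrigated]), scenario, ramp)
    ei = float(r["EI"][0])
    return SuitabilityResult(
        cell_id=cell_id, lon=lon, lat=lat,
        TI=r["TI"][:, 0], MI=r["MI"][:, 0], GI_W=r["GI_W"][:, 0],
        GI_A=float(r["GIA"][0]), CS=float(r["CS"][0]), HS=float(r["HS"][0]),
        DS=float(r["DS"][0]), WS=float(r["WS"][0]), DD=float(r["DD"][0]),
        EI=ei, suitability=SUITABILITY_CLASSES[classify_suitability(ei)],
    )


def run_grid(
    monthly: xr.Dataset,
    irrigation_mask: xr.DataArray = None,
    p: SpeciesParameters = None,
    scenario: str = "rainfed",
    ramp: str = "linear",
) -> xr.Dataset:
    """Run the engine over a gridded monthly climatology.

    Parameters
    ----------
    monthly : Dataset with dims (month, lat, lon) and the variables
        tmin, tmax (°C), prec (mm/month), rh09, rh15 (%).
    irrigation_mask : optional 0/1 DataArray on the same (lat, lon) grid;
        required for the irrigated scenario.
    scenario : 'rainfed' or 'irrigated'.

    Returns a Dataset on (lat, lon) with EI, GIA, CS, HS, DS, WS, DD and a
    suitability class code; cells with any missing weekly input are NaN
    (class code -1).
    """
    p = p or SpeciesParameters()
    missing = [v for v in CLIMATE_VARIABLES if v not in monthly]
    if missing:
        raise ValueError(f"climate dataset lacks variables: {missing}")
    if scenario == "irrigated" and irrigation_mask is None:
        raise ValueError("irrigated scenario requires an irrigation mask")
    if irrigation_mask is not None:
        for dim in ("lat", "lon"):
            if not np.array_equal(irrigation_mask[dim].values, monthly[dim].values):
                raise ValueError(
                    f"irrigation mask grid mismatch on {dim!r}: "
                    f"mask has {irrigation_mask.sizes.get(dim)} values "
                    f"[{float(irrigation_mask[dim].min())}..{float(irrigation_mask[dim].max())}], "
                    f"climate has {monthly.sizes.get(dim)} "
                    f"[{float(monthly[dim].min())}..{float(monthly[dim].max())}]"
                )

    weekly_ds = monthly_to_weekly(monthly)
    nlat, nlon = monthly.sizes["lat"], monthly.sizes["lon"]
    ncell = nlat * nlon
    weekly = {
        v: weekly_ds[v].transpose("week", "lat", "lon").values.reshape(N_WEEKS, ncell)
        for v in CLIMATE_VARIABLES
    }
    valid = np.ones(ncell, dtype=bool)
    for arr in weekly.values():
        valid &= ~np.isnan(arr).any(axis=0)

    if irrigation_mask is not None:
        irrigated = irrigation_mask.values.reshape(ncell).astype(bool)
    else:
        irrigated = np.zeros(ncell, dtype=bool)

    out = {k: np.full(ncell, np.nan) for k in ("EI", "GIA", "CS", "HS", "DS", "WS", "DD")}
    if valid.any():
        sub = {k: v[:, valid] for k, v in weekly.items()}
        r = _compute_arrays(sub, p, irrigated[valid], scenario, ramp)
        for k in out:
            out[k][valid] = r[k]

    code = np.full(ncell, -1, dtype=int)
    code[valid] = classify_suitability(out["EI"][valid])

    coords = {"lat": monthly["lat"].values, "lon": monthly["lon"].values}
    data = {k: (("lat", "lon"), v.reshape(nlat, nlon)) for k, v in out.items()}
    data["suitability_code"] = (("lat", "lon"), code.reshape(nlat, nlon))
    result = xr.Dataset(data, coords=coords)
    result.attrs.update({
        "scenario": scenario,
        "crs": "EPSG:4326",
        "classes": ",".join(SUITABILITY_CLASSES),
    })
    return result
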