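"""Monthly climatologies on a grid, and their conversion to the weekly
series the niche engine consumes.

The engine's model year has 52 weeks = 364 days, divided into 12 equal
months of 364/12 days. Point variables (temperature, relative humidity) are
interpolated from month midpoints to week midpoints with a periodic cosine
scheme: smooth, free of overshoot beyond neighbouring monthly values, and
exactly constant-preserving. Accumulated variables (precipitation) are
redistributed by day-overlap between weeks and equal-length months, which
conserves the annual total exactly.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

N_WEEKS = 52
N_MONTHS = 12
DAYS_PER_WEEK = 7.0
#: length of one model month in days (equal-month calendar)
MONTH_LEN = N_WEEKS * DAYS_PER_WEEK / N_MONTHS

#: variables holding weekly/monthly totals rather than instantaneous values
TOTAL_VARIABLES = {"prec"}

#: monthly climate variables the engine expects
CLIMATE_VARIABLES = ("tmin", "tmax", "prec", "rh09", "rh15")


def _check_monthly(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape[0] != N_MONTHS:
        raise ValueError(
            f"expected {N_MONTHS} monthly values along the first axis, "
            f"got {values.shape[0]}"
        )
    return values


def monthly_to_weekly_point(values: np.ndarray) -> np.ndarray:
    """Interpolate 12 monthly point values to 52 weekly values.

    Periodic cosine interpolation between month midpoints, evaluated at
    week midpoints. Works on any array whose first axis is the month axis;
    remaining axes (e.g. grid cells) are broadcast.
    """
    values = _check_monthly(values)
    # periodic sample points: month midpoints on the unit circle of the year
    t_month = (np.arange(N_MONTHS) + 0.5) / N_MONTHS
    u_week = (np.arange(N_WEEKS) + 0.5) / N_WEEKS

    # index of the month midpoint at or before each week midpoint (periodic)
    pos = u_week * N_MONTHS - 0.5
    m0 = np.floor(pos).astype(int) % N_MONTHS
    m1 = (m0 + 1) % N_MONTHS
    frac = pos - np.floor(pos)
    weight = (1.0 - np.cos(np.pi * frac)) / 2.0

    shape_tail = (1,) * (values.ndim - 1)
    w = weight.reshape((N_WEEKS,) + shape_tail)
    return values[m0] * (1.0 - w) + values[m1] * w


def monthly_to_weekly_total(values: np.ndarray) -> np.ndarray:
    """Redistribute 12 monthly totals into 52 weekly totals.

    Each model month spans 364/12 days; each week receives every month's
    total in proportion to the day overlap, so the annual sum is conserved
    to machine precision.
    """
    values = _check_monthly(values)
    weekly_weights = np.zeros((N_WEEKS, N_MONTHS))
    for w in range(N_WEEKS):
        w_start, w_end = w * DAYS_PER_WEEK, (w + 1) * DAYS_PER_WEEK
        for m in range(N_MONTHS):
            m_start, m_end = m * MONTH_LEN, (m + 1) * MONTH_LEN
            overlap = min(w_end, m_end) - max(w_start, m_start)
            if overlap > 0:
                weekly_weights[w, m] = overlap / MONTH_LEN
    return np.tensordot(weekly_weights, values, axes=(1, 0))


def monthly_to_weekly(monthly: xr.Dataset) -> xr.Dataset:
    """Convert a monthly climate Dataset (dim ``month``) to weekly (dim ``week``).

    Variables listed in :data:`TOTAL_VARIABLES` are treated as totals;
    everything else as instantaneous point values.
    """
    if "month" not in monthly.dims:
        raise ValueError("dataset has no 'month' dimension")
    if monthly.sizes["month"] != N_MONTHS:
        raise ValueError(
            f"'month' dimension must have length {N_MONTHS}, "
            f"got {monthly.sizes['month']}"
        )
    out = {}
    for name, da in monthly.data_vars.items():
        da = da.transpose("month", ...)
        if name in TOTAL_VARIABLES:
            weekly = monthly_to_weekly_total(da.values)
        else:
            weekly = monthly_to_weekly_point(da.values)
        dims = ("week",) + da.dims[1:]
        out[name] = (dims, weekly)
    coords = {k: v for k, v in monthly.coords.items() if "month" not in v.dims}
    coords["week"] = np.arange(1, N_WEEKS + 1)
    return xr.Dataset(out, coords=coords, attrs=dict(monthly.attrs))


def validate_weekly(weekly: xr.Dataset) -> None:
    """Sanity-check a weekly climate Dataset (52 weeks, Tmin<=Tmax, P>=0, RH in [0,100])."""
    if weekly.sizes.get("week") != N_WEEKS:
        raise ValueError("weekly dataset must have exactly 52 weeks")
    tmin, tmax = weekly["tmin"].values, weekly["tmax"].values
    valid = ~(np.isnan(tmin) | np.isnan(tmax))
    if np.any(tmin[valid] > tmax[valid] + 1e-9):
        raise ValueError("Tmin exceeds Tmax in at least one week/cell")
    prec = weekly["prec"].values
    if np.any(prec[~np.isnan(prec)] < -1e-9):
        raise ValueError("negative precipitation")
    for rh in ("rh09", "rh15"):
        if rh in weekly:
            v = weekly[rh].values
            v = v[~np.isnan(v)]
            if v.size and (v.min() < -1e-9 or v.max() > 100 + 1e-9):
                raise ValueError(f"{rh} outside [0, 100]")
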