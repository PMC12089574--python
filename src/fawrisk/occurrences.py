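"""Occurrence-record quality control.

Raw occurrence tables (Darwin-Core-like columns) are passed through an
ordered filter cascade — missing/invalid coordinates, the (0,0) "null
island", absent/fossil/living records, country centroids and capitals,
pre-1950 dates, known-default or high-uncertainty coordinates,
zoo/herbarium locations, and ocean points — followed by deduplication on
rounded coordinates plus year. Each removed record is attributed to the
first filter that catches it, and the cleaning report reconciles exactly:
input = output + sum of removals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

LON_COL = "decimalLongitude"
LAT_COL = "decimalLatitude"

#: cascade order; each record is charged to the first filter that removes it
FILTER_ORDER = (
    "missing_or_invalid_coordinates",
    "null_island",
    "status_basis",
    "country_centroid",
    "country_capital",
    "pre_cutoff_year",
    "default_or_uncertain_coordinates",
    "zoo_herbarium",
    "ocean",
)


@dataclass
class CleaningConfig:
    """Tunable knobs of the filter cascade."""

    min_year: int = 1950
    #: records with stated coordinate uncertainty above this are dropped (m)
    max_uncertainty_m: float = 25_000.0
    #: basis-of-record values excluded (case-insensitive substring match)
    excluded_basis: tuple = ("fossil", "living")
    #: occurrence-status values excluded
    excluded_status: tuple = ("absent",)
    #: known inaccurate default coordinates, matched after rounding
    coordinate_blacklist: tuple = ()
    #: decimal places defining the blacklist / duplicate key (~11 m at 4)
    coordinate_precision: int = 4


@dataclass
class CleaningReport:
    input_count: int
    output_count: int
    removals: dict = field(default_factory=dict)
    quarantined: int = 0

    def total_removed(self) -> int:
        return sum(self.removals.values()) + self.quarantined

    def to_json(self, path: str | Path = None) -> str:
        payload = {
            "input_count": self.input_count,
            "output_count": self.output_count,
            "quarantined": self.quarantined,
            "removals": self.removals,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _coerce_numeric(series: pd.Series):
    """Numeric coercion; returns (values, unparseable mask)."""
    coerced = pd.to_numeric(series, errors="coerce")
    bad = coerced.isna() & series.notna() & (series.astype(str).str.strip() != "")
    return coerced, bad


def _bool_col(df: pd.DataFrame, name: str) -> np.ndarray:
    if name in df.columns:
        return df[name].fillna(False).astype(bool).values
    return np.zeros(len(df), dtype=bool)


def _matches_any(series: pd.Series, tokens) -> np.ndarray:
    if series is None:
        return np.zeros(0, dtype=bool)
    text = series.fillna("").astype(str).str.lower()
    mask = np.zeros(len(text), dtype=bool)
    for token in tokens:
        mask |= text.str.contains(token.lower(), regex=False).values
    return mask


def clean_records(
    records: pd.DataFrame,
    config: CleaningConfig = None,
    land_mask=None,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Run the filter cascade; returns (clean records, report).

    Centroid/capital/zoo-herbarium/ocean tests use precomputed boolean
    columns (``is_centroid``, ``is_capital``, ``is_zoo_herbarium``,
    ``in_ocean``) when present. Alternatively ``land_mask`` (a 0/1
    lat/lon DataArray, 1 = land) resolves the ocean test; records without
    mask coverage are retained. Rows whose coordinate or year fields fail
    to parse are quarantined (counted separately, not silently dropped);
    their row labels are stored in ``report`` via the ``quarantined``
    count and returned DataFrame attribute ``quarantined_index``.
    """
    config = config or CleaningConfig()
    df = records.copy()
    n_in = len(df)

    lon, bad_lon = _coerce_numeric(df.get(LON_COL, pd.Series(index=df.index, dtype=float)))
    lat, bad_lat = _coerce_numeric(df.get(LAT_COL, pd.Series(index=df.index, dtype=float)))
    year, bad_year = _coerce_numeric(df.get("year", pd.Series(index=df.index, dtype=float)))
    unc, bad_unc = _coerce_numeric(
        df.get("coordinateUncertaintyInMeters", pd.Series(index=df.index, dtype=float)))
    quarantine = (bad_lon | bad_lat | bad_year | bad_unc).values

    lon_v, lat_v = lon.values, lat.values
    year_v, unc_v = year.values, unc.values

    masks = {}
    masks["missing_or_invalid_coordinates"] = (
        np.isnan(lon_v) | np.isnan(lat_v)
        | (np.abs(lon_v) > 180) | (np.abs(lat_v) > 90)
    )
    masks["null_island"] = (lon_v == 0.0) & (lat_v == 0.0)
    masks["status_basis"] = (
        _matches_any(df.get("occurrenceStatus"), config.excluded_status)
        | _matches_any(df.get("basisOfRecord"), config.excluded_basis)
    )
    masks["country_centroid"] = _bool_col(df, "is_centroid")
    masks["country_capital"] = _bool_col(df, "is_capital")
    masks["pre_cutoff_year"] = ~np.isnan(year_v) & (year_v < config.min_year)

    prec = config.coordinate_precision
    blacklist = {(round(float(x), prec), round(float(y), prec))
                 for x, y in config.coordinate_blacklist}
    if blacklist:
        keys = list(zip(np.round(lon_v, prec), np.round(lat_v, prec)))
        on_blacklist = np.array([k in blacklist for k in keys], dtype=bool)
    else:
        on_blacklist = np.zeros(n_in, dtype=bool)
    masks["default_or_uncertain_coordinates"] = (
        on_blacklist | (~np.isnan(unc_v) & (unc_v > config.max_uncertainty_m))
    )
    masks["zoo_herbarium"] = _bool_col(df, "is_zoo_herbarium")

    ocean = _bool_col(df, "in_ocean")
    if land_mask is not None and "in_ocean" not in df.columns:
        from fawrisk.migration import _sample_raster
        land, covered = _sample_raster(land_mask, lon_v, lat_v)
        ocean = covered & ~np.isnan(land) & (land < 0.5)
    masks["ocean"] = ocean

    removed = quarantine.copy()
    removals = {}
    for name in FILTER_ORDER:
        hit = masks[name] & ~removed
        removals[name] = int(hit.sum())
        removed |= hit

    clean = df.loc[~removed].copy()
    clean[LON_COL] = lon_v[~removed]
    clean[LAT_COL] = lat_v[~removed]
    clean.attrs["quarantined_index"] = list(df.index[quarantine])

    report = CleaningReport(
        input_count=n_in,
        output_count=len(clean),
        removals=removals,
        quarantined=int(quarantine.sum()),
    )
    assert report.input_count == report.output_count + report.total_removed()
    return clean, report


def deduplicate(
    records: pd.DataFrame,
    precision: int = 4,
    source_priority: list | None = None,
) -> pd.DataFrame:
    """Keep one record per (rounded lon, rounded lat, year) key.

    Rounding precision defaults to 4 decimal places (~11 m). With a
    ``source_priority`` list the highest-priority source wins; otherwise
    the first record in input order is kept (stable).
    """
    if records.empty:
        return records.copy()
    df = records.copy()
    key_lon = df[LON_COL].round(precision)
    key_lat = df[LAT_COL].round(precision)
    key_year = df["year"] if "year" in df.columns else pd.Series(np.nan, index=df.index)
    keys = pd.DataFrame({"_lon": key_lon, "_lat": key_lat, "_year": key_year})
    if source_priority and "source" in df.columns:
        rank = {s: i for i, s in enumerate(source_priority)}
        order = df["source"].map(lambda s: rank.get(s, len(rank)))
        idx = order.sort_values(kind="stable").index
        df = df.loc[idx]
        keys = keys.loc[idx]
    kept = ~keys.duplicated(keep="first")
    out = df.loc[kept]
    return out.sort_index()
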