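"""Partial-budgeting model of the direct economic impact on grain maize.

Per member state *i* and yield-loss scenario *s* (best / moderate / worst,
i.e. the 2.25th / 50th / 97.5th percentile of the expert-elicited yield
loss distribution):

    GM_i^baseline = (1/n) * sum_t (R_{i,t} - OC_{i,t})          (€/ha)
    GM_{i,s}^FAW  = R̄_i * (1 - PP_i * YL_{i,s}/100) - OC̄_i     (€/ha)
    PP_i          = 1 - F(D_i)                                  (probability)
    DEI_{i,s}     = GM_i^baseline - GM_{i,s}^FAW                (€/ha)

with R̄/OC̄ the same panel means that enter the baseline, PP the annual
presence probability from the migration ECDF at the state's hub distance
D, and YL the scenario yield-loss percentage. National figures scale the
per-hectare values by the cultivated area (million €). Under the
"no-control" assumption operating costs are unchanged by the pest, so the
identities PP = 0 => DEI = 0 and DEI = R̄ * PP * YL/100 hold exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SCENARIOS = ("best", "moderate", "worst")
#: yield-loss percentile behind each scenario
SCENARIO_PERCENTILES = {"best": 2.25, "moderate": 50.0, "worst": 97.5}


def baseline_gross_margin(revenues, costs) -> float:
    """Mean annual gross margin €/ha over a matched panel of years."""
    r = np.asarray(revenues, dtype=float)
    c = np.asarray(costs, dtype=float)
    if r.shape != c.shape:
        raise ValueError(f"revenue/cost year mismatch: {r.shape} vs {c.shape}")
    if r.size == 0:
        raise ValueError("panel must contain at least one year")
    return float(np.mean(r - c))


def faw_gross_margin(mean_revenue: float, mean_cost: float,
                     pp: float, yl_pct: float) -> float:
    """Gross margin €/ha under pest presence (yield-loss-discounted revenue)."""
    if not 0.0 <= pp <= 1.0:
        raise ValueError(f"presence probability must lie in [0, 1], got {pp}")
    if not 0.0 <= yl_pct <= 100.0:
        raise ValueError(f"yield loss must lie in [0, 100] %, got {yl_pct}")
    return mean_revenue * (1.0 - pp * yl_pct / 100.0) - mean_cost


def direct_economic_impact(gm_baseline, gm_faw):
    """DEI €/ha: baseline gross margin minus gross margin under pest presence."""
    return np.asarray(gm_baseline, dtype=float) - np.asarray(gm_faw, dtype=float)


def national_scale(per_ha, area_ha):
    """Scale a €/ha value to national million € by the cultivated area."""
    area = np.asarray(area_ha, dtype=float)
    if np.any(area < 0):
        raise ValueError("area must be non-negative")
    return np.asarray(per_ha, dtype=float) * area / 1e6


def run_scenarios(
    panel: pd.DataFrame,
    yield_losses: pd.DataFrame,
    presence: pd.DataFrame,
) -> pd.DataFrame:
    """Full scenario table per member state, plus a cross-state summary row.

    Parameters
    ----------
    panel : columns ``state, year, revenue, cost, area`` (€/ha, €/ha, ha);
        area may vary by year, the multi-year mean is used.
    yield_losses : columns ``state, best, moderate, worst`` (yield loss %).
    presence : columns ``state, D_km, PP``.

    Returns one row per state with baseline and per-scenario gross margins
    and impacts, both €/ha and national million €, followed by a summary
    row (label ``Average/Sum``) holding per-ha means and national sums.
    States lacking yield-loss or presence data are skipped with a warning.
    Values are carried at full precision; rounding is presentation-only
    (see :func:`format_per_ha_table` / :func:`format_national_table`).
    """
    import warnings

    yl = yield_losses.set_index("state")
    pp = presence.set_index("state")
    rows = []
    for state, grp in panel.groupby("state", sort=True):
        if state not in yl.index or state not in pp.index:
            warnings.warn(f"state {state!r} lacks yield-loss or presence data; skipped")
            continue
        r_mean = float(grp["revenue"].mean())
        oc_mean = float(grp["cost"].mean())
        gm_base = baseline_gross_margin(grp["revenue"].values, grp["cost"].values)
        area = float(grp["area"].mean())
        pp_i = float(pp.loc[state, "PP"])
        row = {
            "state": state,
            "D_km": float(pp.loc[state, "D_km"]),
            "PP": pp_i,
            "area_ha": area,
            "gm_baseline": gm_base,
            "gm_baseline_national": float(national_scale(gm_base, area)),
        }
        for s in SCENARIOS:
            yl_is = float(yl.loc[state, s])
            gm_faw = faw_gross_margin(r_mean, oc_mean, pp_i, yl_is)
            dei = float(direct_economic_impact(gm_base, gm_faw))
            row[f"yl_{s}"] = yl_is
            row[f"gm_{s}"] = gm_faw
            row[f"dei_{s}"] = dei
            row[f"gm_{s}_national"] = float(national_scale(gm_faw, area))
            row[f"dei_{s}_national"] = float(national_scale(dei, area))
        rows.append(row)
    if not rows:
        raise ValueError("no state had complete panel, yield-loss and presence data")
    table = pd.DataFrame(rows)

    summary = {"state": "Average/Sum"}
    for col in table.columns:
        if col == "state":
            continue
        if col.endswith("_national"):
            summary[col] = float(table[col].sum())
        elif col.startswith(("gm_", "dei_")):
            summary[col] = float(table[col].mean())
        else:
            summary[col] = np.nan
    return pd.concat([table, pd.DataFrame([summary])], ignore_index=True)


def format_per_ha_table(results: pd.DataFrame) -> pd.DataFrame:
    """Presentation table: €/ha figures rounded to integers."""
    cols = ["state", "gm_baseline"] + [f"gm_{s}" for s in SCENARIOS] \
        + [f"dei_{s}" for s in SCENARIOS]
    out = results[cols].copy()
    for c in cols[1:]:
        out[c] = out[c].round(0).astype(int)
    return out


def format_national_table(results: pd.DataFrame) -> pd.DataFrame:
    """Presentation table: national figures in million €, one decimal."""
    cols = ["state", "gm_baseline_national"] \
        + [f"gm_{s}_national" for s in SCENARIOS] \
        + [f"dei_{s}_national" for s in SCENARIOS]
    out = results[cols].copy()
    for c in cols[1:]:
        out[c] = out[c].round(1)
    return out
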