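"""Jurisdictional flux ledger: zone x permit x disturbance accounting.

Rows carry spatial-plan zone (APL non-forest, HP/HPT production forest,
HL protection forest), permit type (HGU oil palm, PKP2B coal, HA
selective logging, HTI fiber, or none), disturbance type, annualized
areas, gross emissions, gross sequestration, net emissions (Tg CO2/yr)
and each row's percent share of total net emissions. Internal
arithmetic is full precision; display rounding (2 decimals for Tg,
1 for percent) is applied only by :func:`format_ledger`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["build_ledger", "format_ledger", "ZONE_ORDER"]

ZONE_ORDER = ["APL", "HP/HPT", "HL"]

_REQUIRED = ["zone", "permit", "disturbance", "gross_Tg", "seq_Tg"]


def build_ledger(rows: pd.DataFrame) -> pd.DataFrame:
    """Aggregate labelled flux cells into the ledger.

    ``rows`` needs columns ``zone``, ``permit``, ``disturbance``,
    ``gross_Tg``, ``seq_Tg`` and may carry ``net_Tg`` (defaults to
    gross - sequestration) plus any area columns (``land_area_ha``,
    ``forest_area_ha``, ``area_disturbed_ha_yr``, ``regrowth_ha_yr``),
    which are summed into the totals row. Rows are sorted by zone (APL,
    HP/HPT, HL) then net emissions descending; a totals row is appended
    and percent shares are computed on net emissions.
    """
    missing = [c for c in _REQUIRED if c not in rows.columns]
    if missing:
        raise ValueError(f"ledger rows missing required columns: {missing}")
    if rows[["zone", "permit", "disturbance"]].isna().any().any():
        bad = rows[rows[["zone", "permit", "disturbance"]].isna().any(axis=1)]
        raise ValueError(f"unlabeled ledger cells at rows {list(bad.index)}")

    out = rows.copy()
    if "net_Tg" not in out.columns:
        out["net_Tg"] = out["gross_Tg"] - out["seq_Tg"]
    zone_rank = {z: i for i, z in enumerate(ZONE_ORDER)}
    out["_zr"] = out["zone"].map(lambda z: zone_rank.get(z, len(zone_rank)))
    out = (out.sort_values(["_zr", "net_Tg"], ascending=[True, False])
              .drop(columns="_zr").reset_index(drop=True))

    total_net = float(out["net_Tg"].sum())
    out["pct_net"] = (out["net_Tg"] / total_net * 100.0) if total_net != 0 else 0.0

    numeric = out.select_dtypes(include=[np.number]).columns
    totals = {c: float(out[c].sum()) for c in numeric}
    totals.update({"zone": "Total", "permit": "", "disturbance": ""})
    totals["pct_net"] = 100.0 if total_net != 0 else 0.0
    out = pd.concat([out, pd.DataFrame([totals])], ignore_index=True)
    return out


def format_ledger(ledger: pd.DataFrame) -> pd.DataFrame:
    """Display-rounded copy: 2 decimals for Tg CO2/yr, 1 for percent."""
    out = ledger.copy()
    for c in out.columns:
        if c.endswith("_Tg"):
            out[c] = out[c].round(2)
        elif c == "pct_net":
            out[c] = out[c].round(1)
        elif c.endswith("_ha") or c.endswith("_ha_yr"):
            out[c] = out[c].round(0)
    return out
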