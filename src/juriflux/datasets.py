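"""Reference accounts for the Berau jurisdiction (eastern Borneo).

The 2001-2010 zone/permit/disturbance flux table and the headline flux
figures for Berau Regency, Indonesia — a frontier Dipterocarp-forest
jurisdiction and an early REDD+ pilot — as printed accounting inputs.
They drive the arithmetic-reproduction checks: re-deriving totals and
percentage shares from the row-level figures through the ledger and
flux-identity operations.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["berau_ledger_rows", "berau_headline"]

_ROWS = [
    # zone, permit, disturbance, land_ha, forest_ha, dist_ha_yr, regrow_ha_yr,
    # gross, seq, net, pct
    ("APL", "HGU", "Oil Palm", 206_683, 194_513, 4_509, 1_379, 2.38, 0.130, 2.25, 25.3),
    ("APL", "none", "Oil Palm", None, None, 477, 74, 0.27, 0.007, 0.26, 2.9),
    ("APL", "none", "Agriculture/Other", None, None, 3_786, 1_306, 2.79, 0.313, 2.48, 27.8),
    ("APL", "HGU", "Agriculture/Other", 206_683, 194_513, 1_050, 328, 0.56, 0.031, 0.53, 5.9),
    ("APL", "PKP2B", "Mining", 117_745, 102_312, 351, 79, 0.18, 0.007, 0.17, 2.0),
    ("APL", "none", "Mining", None, None, 111, 15, 0.05, 0.001, 0.05, 0.6),
    ("HP/HPT", "HA", "Skidding/Felling", 898_725, 888_438, 8_654, 8_654, 1.32, 0.076, 1.25, 14.0),
    ("HP/HPT", "HA", "Logging Roads", 898_725, 888_438, 690, 259, 0.28, 0.024, 0.25, 2.8),
    ("HP/HPT", "HTI", "Fiber Plantation", 266_351, 242_322, 2_025, 2_029, 1.02, 0.191, 0.82, 9.2),
    ("HP/HPT", "HA", "Agriculture/Other", 898_725, 888_438, 1_380, 314, 0.79, 0.030, 0.77, 8.6),
    ("HP/HPT", "HTI", "Mining", 266_351, 242_322, 104, 20, 0.06, 0.002, 0.06, 0.7),
    ("HL", "none", "Agriculture/Other", None, None, 65, 49, 0.04, 0.00, 0.03, 0.4),
]

#: printed totals and results-level flux figures (Tg CO2/yr unless noted)
berau_headline = {
    "gross_total_Tg": 9.73,
    "sequestration_total_Tg": 0.82,
    "net_total_Tg": 8.91,
    "net_ci_Tg": 1.99,
    "gross_ci_Tg": 1.95,
    "sequestration_ci_Tg": 0.41,
    "forest_loss_gross_Tg": 8.13,
    "biomass_loss_gross_Tg": 8.67,       # above+belowground tree biomass only
    "logging_gross_Tg": 1.60,
    "logging_felling_Tg": 0.97,
    "logging_skidding_Tg": 0.35,
    "logging_haul_Tg": 0.28,
    "logging_products_Tg": 0.11,
    "regrowth_sequestration_Tg": 0.71,
    "logging_sequestration_Tg": 0.11,
    "forest_carbon_stock_2000_TgC": 427.0,
    "area_disturbed_ha_yr": 23_203,
    "area_regrowth_ha_yr": 14_506,
    "legal_harvest_ha_yr": 9_344,
    "legal_harvest_m3_yr": 297_766,
    "reference_period_years": 10,
}


def berau_ledger_rows() -> pd.DataFrame:
    """Row-level Berau accounts as ledger input (printed precision)."""
    return pd.DataFrame(
        _ROWS,
        columns=["zone", "permit", "disturbance", "land_area_ha",
                 "forest_area_ha", "area_disturbed_ha_yr", "regrowth_ha_yr",
                 "gross_Tg", "seq_Tg", "net_Tg", "pct_net_printed"],
    )
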