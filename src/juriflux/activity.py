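"""Activity data: areas undergoing loss, gain, and logging per unit time.

Converts aligned rasters and government logging records into the area
terms of the gain-loss equation: stratified forest loss ``AFd_h`` by
disturbance attribution, wetland loss ``AWd``, annualized regrowth
``Ar`` by secondary-forest type, and legally logged area ``Asl``.
Includes the haul-road segregation rule (loss corridors inside licensed
logging concessions no more than 3 pixels wide are roads, detected here
with a deterministic morphological criterion) and the annual linear
trend test on the loss series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .rasters import RasterBundle

__all__ = [
    "ActivitySummary",
    "extract_loss",
    "annualize_gain",
    "classify_logging_roads",
    "summarize_logging_records",
    "trend_test",
]


@dataclass
class ActivitySummary:
    """Annualized activity quantities for one reference period.

    Areas are totals over the period (ha) unless stated otherwise;
    ``annual_loss`` is the per-year loss series (ha/yr, years 1..tp).
    """

    afd: dict = field(default_factory=dict)        # (stratum, attribution) -> ha
    road_afd: dict = field(default_factory=dict)   # stratum -> haul-road loss ha
    awd: dict = field(default_factory=dict)        # wetland type -> ha
    ar: dict = field(default_factory=dict)         # regrowth type -> ha
    asl: float = 0.0                               # logged area, ha over period
    harvest_volume: float | None = None            # m3 over period
    annual_loss: np.ndarray = field(default_factory=lambda: np.zeros(0))
    tp: int = 10

    def afd_by_stratum(self) -> dict:
        out: dict = {}
        for (h, _attr), area in self.afd.items():
            out[h] = out.get(h, 0.0) + area
        return out

    def afd_by_attribution(self) -> dict:
        out: dict = {}
        for (_h, attr), area in self.afd.items():
            out[attr] = out.get(attr, 0.0) + area
        return out

    def total_loss_area(self) -> float:
        """Total loss-pixel area: conversion plus haul roads (ha)."""
        return float(sum(self.afd.values()) + sum(self.road_afd.values()))

    def validate(self) -> None:
        if any(a < 0 for a in self.afd.values()):
            raise ValueError("negative stratified loss area")
        if self.annual_loss.size and not np.isclose(
            self.annual_loss.sum(), self.total_loss_area(), rtol=1e-9, atol=1e-6
        ):
            raise ValueError("annual loss series does not sum to total loss area")


def extract_loss(
    bundle: RasterBundle,
    period: tuple[int, int] | None = None,
    attribution_codes: Mapping[int, str] | None = None,
) -> tuple[dict, np.ndarray]:
    """Cross-tabulate loss area by stratum and disturbance attribution.

    Returns ``(afd, annual_series)`` where ``afd`` maps
    ``(stratum id, attribution label)`` to ha over the period and
    ``annual_series[t-1]`` is the ha lost in year index ``t``. Loss-year
    values outside ``period`` (inclusive year indices, default the full
    band range) are excluded.
    """
    bundle.validate_alignment()
    loss = bundle["loss_year"]
    stratum = bundle["stratum"]
    dist = bundle["disturbance"]
    codes = attribution_codes or {v: k for k, v in
                                  bundle.codes.get("disturbance", {}).items()}
    lo, hi = period if period is not None else (1, int(loss.max(initial=1)))
    in_period = (loss >= lo) & (loss <= hi)

    present = np.unique(dist[in_period])
    unknown = [int(c) for c in present if int(c) not in codes]
    if unknown:
        raise KeyError(f"unknown disturbance attribution codes: {unknown}")

    px = bundle.pixel_area_ha
    afd: dict = {}
    ys, xs = np.nonzero(in_period)
    for h, c in zip(stratum[ys, xs], dist[ys, xs]):
        key = (int(h), codes[int(c)])
        afd[key] = afd.get(key, 0.0) + px
    annual = np.array([
        float(np.count_nonzero(loss == t)) * px for t in range(lo, hi + 1)
    ])
    return afd, annual


def wetland_loss(bundle: RasterBundle,
                 period: tuple[int, int] | None = None) -> dict[str, float]:
    """AWd: loss area intersecting the wetland mask, by wetland type (ha)."""
    loss = bundle["loss_year"]
    lo, hi = period if period is not None else (1, int(loss.max(initial=1)))
    in_period = (loss >= lo) & (loss <= hi)
    wet = bundle["wetland"]
    return {
        "peat": bundle.area_ha(in_period & (wet == 1)),
        "mangrove": bundle.area_ha(in_period & (wet == 2)),
    }


def annualize_gain(
    gain_area_ha: float | Mapping[str, float],
    source_period_years: float,
    reference_period_years: float,
) -> float | dict[str, float]:
    """Scale gain detected over the source period to the reference period.

    The gain band is not annual, so the same annual rate is assumed:
    ``Ar(ref) = gain * ref_length / source_length``. Accepts a total or a
    per-regrowth-type mapping.
    """
    if source_period_years <= 0:
        raise ValueError("source period length must be > 0")
    factor = reference_period_years / source_period_years
    if isinstance(gain_area_ha, Mapping):
        return {k: v * factor for k, v in gain_area_ha.items()}
    return gain_area_ha * factor


def partition_gain(bundle: RasterBundle) -> dict[str, float]:
    """Split gain area by permit overlay into regrowth types (ha).

    Gain inside a fiber-plantation permit is typed ``fiber``, inside an
    oil-palm permit ``oil_palm``, anywhere else ``native`` — regardless
    of the surrounding matrix.
    """
    gain = bundle["gain"].astype(bool)
    permit = bundle["permit"]
    pcodes = bundle.codes.get("permit", {})
    fiber = permit == pcodes.get("HTI", -1)
    palm = permit == pcodes.get("HGU", -1)
    return {
        "fiber": bundle.area_ha(gain & fiber),
        "oil_palm": bundle.area_ha(gain & palm & ~fiber),
        "native": bundle.area_ha(gain & ~fiber & ~palm),
    }


def classify_logging_roads(
    loss_mask: np.ndarray,
    concession_mask: np.ndarray,
) -> np.ndarray:
    """Label in-concession loss pixels as haul roads or conversion.

    A loss pixel inside a licensed logging concession is a road where it
    belongs to a structure no more than 3 pixels wide: mechanically, the
    pixels deleted by a binary opening with a 4x4 square structuring
    element (which preserves exactly the parts at least 4 pixels wide).
    Returns an int raster: 0 = not in-concession loss, 1 = road,
    2 = conversion.
    """
    loss_mask = np.asarray(loss_mask, dtype=bool)
    concession_mask = np.asarray(concession_mask, dtype=bool)
    if loss_mask.shape != concession_mask.shape:
        raise ValueError("loss and concession grids are misaligned")
    inside = loss_mask & concession_mask
    wide = ndimage.binary_opening(inside, structure=np.ones((4, 4), dtype=bool))
    out = np.zeros(loss_mask.shape, dtype=np.uint8)
    out[inside & ~wide] = 1
    out[inside & wide] = 2
    return out


def summarize_logging_records(
    records: pd.DataFrame,
    reference_period_years: int,
    completeness: float = 1.0,
    scale_mode: str = "proportional",
) -> dict[str, float]:
    """Annual legal harvest from permit-year records.

    ``records`` carries columns ``permit``, ``year``, ``area_ha`` and
    optionally ``volume_m3``. With record coverage ``completeness``
    (fraction of all permit-years with records), ``"proportional"``
    scale-up divides the observed annual totals by the completeness;
    ``"observed_mean"`` reports the observed totals unscaled.

    Returns ``asl_ha_yr``, ``volume_m3_yr`` (NaN when volumes are
    missing), and the period totals.
    """
    if scale_mode not in ("proportional", "observed_mean"):
        raise ValueError(f"unknown scale mode {scale_mode!r}")
    if not (0 < completeness <= 1):
        raise ValueError("completeness must lie in (0, 1]")
    if len(records) == 0:
        warnings.warn("no logging records; Asl = 0")
        return {"asl_ha_yr": 0.0, "volume_m3_yr": 0.0,
                "asl_ha_period": 0.0, "volume_m3_period": 0.0}
    years = records["year"].nunique()
    span = max(years, 1)
    area_yr = float(records["area_ha"].sum()) / span
    if "volume_m3" in records and records["volume_m3"].notna().any():
        if records["volume_m3"].isna().any():
            warnings.warn("some records are missing harvest volume; "
                          "volume rate uses recorded rows only")
        vol_yr = float(records["volume_m3"].dropna().sum()) / span
    else:
        vol_yr = float("nan")
    if scale_mode == "proportional":
        area_yr /= completeness
        vol_yr = vol_yr / completeness
    return {
        "asl_ha_yr": area_yr,
        "volume_m3_yr": vol_yr,
        "asl_ha_period": area_yr * reference_period_years,
        "volume_m3_period": vol_yr * reference_period_years,
    }


def trend_test(annual_series) -> dict[str, float]:
    """OLS linear trend of an annual series on the year index.

    Returns slope, intercept, R^2, the regression F statistic
    (``t^2`` for the single predictor) with its degrees of freedom, and
    the p-value.
    """
    y = np.asarray(annual_series, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 years for a trend test")
    x = np.arange(1, y.size + 1, dtype=float)
    res = stats.linregress(x, y)
    r2 = res.rvalue ** 2
    if not np.isfinite(r2):
        r2 = 0.0  # constant series: no variance to explain
    df = y.size - 2
    if np.isnan(res.stderr) or res.stderr == 0:
        f = 0.0 if res.slope == 0 else float("inf")
        p = 1.0 if res.slope == 0 else 0.0
    else:
        t = res.slope / res.stderr
        f = t ** 2
        p = res.pvalue
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r_squared": float(r2), "F": float(f), "df1": 1, "df2": int(df),
            "p": float(p)}
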