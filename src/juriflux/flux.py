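"""The gain-loss carbon flux engine.

Net flux over a reference period of ``tp`` years is

    dC = dCl - dCg

with carbon losses and gains

    dCl = ( sum_h AFd_h * Cd_h * LFd_h  +  AWd * SEFd  +  Asl * EFsl ) / tp
    dCg = ( Ar * SFr  +  Asl * SFsl ) / tp

where ``AFd_h`` is forest area lost in biomass stratum ``h`` (ha over the
period), ``Cd_h`` the stratum's aboveground live carbon density (MgC/ha),
``LFd_h`` a dimensionless loss factor (emissions committed within the
period as a proportion of ``Cd_h``), ``AWd`` wetland forest area lost,
``SEFd`` soil carbon emissions per ha of wetland loss, ``Asl`` area
legally logged, ``EFsl`` logging emissions per ha, ``Ar`` regrowth area
and ``SFr``/``SFsl`` sequestration factors.

The loss factor is process based: cleared biomass (above- plus
below-ground plus necromass, minus extracted roundwood) is partly burned
at clearing and the remainder decays linearly; cohorts of dead wood are
created year by year over the period, so the within-period emitted
fraction is a cohort average. All computations run in MgC internally;
conversion to CO2 (factor 44/12) happens only at reporting.

Every function accepts NumPy arrays in place of scalars, so one code
path serves both the deterministic estimate and vectorized Monte Carlo
evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "CO2_PER_C",
    "LossFactorInputs",
    "SoilParams",
    "LoggingFactors",
    "SequestrationRates",
    "FluxResult",
    "decay_fraction_in_window",
    "mean_decay_fraction",
    "loss_factor",
    "forest_loss_emissions",
    "wetland_soil_emissions",
    "logging_emissions",
    "sequestration",
    "net_flux",
]

#: molecular weight ratio of CO2 to carbon
CO2_PER_C = 44.0 / 12.0


def _check_fraction(name: str, value) -> None:
    v = np.asarray(value, dtype=float)
    if np.any(v < 0) or np.any(v > 1):
        raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class LossFactorInputs:
    """Components of the process-based forest loss factor.

    All fractions are relative to aboveground live carbon ``Cd_h`` except
    ``combustion_completeness`` and ``charcoal_frac`` which act on the
    burned pool, and may be scalars or arrays (Monte Carlo draws).
    """

    root_shoot: float = 0.37            # belowground / aboveground live
    necromass_frac: float = 0.10        # standing+lying dead, of aboveground live
    burned_frac: float = 0.60           # fraction of cleared area burned
    combustion_completeness: float = 0.50
    charcoal_frac: float = 0.08         # combusted C retained as charcoal
    extraction_frac: float = 0.10       # roundwood removed at clearing
    product_half_life: float = 20.0     # yr, first-order wood-product decay
    wood_density: float = 0.60          # Mg/m3 (volume -> biomass conversions)
    carbon_frac: float = 0.47           # MgC per Mg biomass
    decay_rate: float = 0.24            # 1/yr linear dead-wood decay

    def validate(self) -> None:
        for fname in ("root_shoot", "necromass_frac", "burned_frac",
                      "combustion_completeness", "charcoal_frac",
                      "extraction_frac", "carbon_frac"):
            _check_fraction(fname, getattr(self, fname))
        if np.any(np.asarray(self.decay_rate) <= 0):
            raise ValueError("decay_rate must be > 0")
        if np.any(np.asarray(self.product_half_life) <= 0):
            raise ValueError("product_half_life must be > 0")


@dataclass
class SoilParams:
    """Wetland (anoxic) soil carbon stocks and loss rules.

    Peat: cleared (and assumed burned) peat loses ``peat_loss_frac`` of
    the carbon in the drained layer, i.e. down to
    ``min(drainage_depth, peat_depth)``. Mangrove: conversion loses
    ``top_loss_frac`` of the top-layer stock and ``deep_loss_frac`` of
    the remainder.
    """

    peat_depth: float = 200.0            # cm
    peat_c_density: float = 0.55         # MgC/ha per cm of depth
    drainage_depth: float = 60.0         # cm
    peat_loss_frac: float = 1.0
    mangrove_top_depth: float = 30.0     # cm (documentation; stocks are direct)
    mangrove_top_stock: float = 115.0    # MgC/ha in top layer
    mangrove_deep_stock: float = 190.0   # MgC/ha below top layer
    mangrove_top_loss_frac: float = 0.75
    mangrove_deep_loss_frac: float = 0.35

    def validate(self) -> None:
        for fname in ("peat_loss_frac", "mangrove_top_loss_frac",
                      "mangrove_deep_loss_frac"):
            _check_fraction(fname, getattr(self, fname))
        for fname in ("peat_depth", "drainage_depth", "mangrove_top_depth"):
            if np.any(np.asarray(getattr(self, fname)) <= 0):
                raise ValueError(f"{fname} must be > 0")

    def peat_emission_per_ha(self):
        """MgC emitted per ha of peat forest loss."""
        drained = np.minimum(self.drainage_depth, self.peat_depth)
        return self.peat_loss_frac * drained * self.peat_c_density

    def mangrove_emission_per_ha(self):
        """MgC emitted per ha of mangrove forest loss."""
        return (self.mangrove_top_loss_frac * self.mangrove_top_stock
                + self.mangrove_deep_loss_frac * self.mangrove_deep_stock)


@dataclass
class LoggingFactors:
    """Per-ha selective-logging degradation factors (MgC/ha logged)."""

    felling_ef: float = 28.3
    skidding_ef: float = 10.2
    product_ef: float = 3.2
    sf_sl: float = 0.368   # post-logging sequestration, MgC/ha logged

    def validate(self) -> None:
        for fname in ("felling_ef", "skidding_ef", "product_ef", "sf_sl"):
            if np.any(np.asarray(getattr(self, fname)) < 0):
                raise ValueError(f"{fname} must be >= 0")


@dataclass
class SequestrationRates:
    """Regrowth sequestration rates by secondary-forest type (MgC/ha/yr)."""

    fiber: float = 9.8
    oil_palm: float = 2.97
    native: float = 3.85

    def rate(self, regrowth_type: str):
        try:
            return getattr(self, regrowth_type)
        except AttributeError:
            raise KeyError(f"unknown regrowth type {regrowth_type!r}") from None


@dataclass
class FluxResult:
    """Net flux and its per-component breakdown.

    All component values are annual MgC/yr; ``co2`` properties convert
    with the 44/12 molecular-weight ratio.
    """

    gross_loss: float          # dCl (MgC/yr)
    gross_gain: float          # dCg (MgC/yr)
    components: dict[str, float] = field(default_factory=dict)

    @property
    def net(self) -> float:
        return self.gross_loss - self.gross_gain

    @property
    def net_co2(self) -> float:
        return self.net * CO2_PER_C

    @property
    def gross_loss_co2(self) -> float:
        return self.gross_loss * CO2_PER_C

    @property
    def gross_gain_co2(self) -> float:
        return self.gross_gain * CO2_PER_C

    def components_co2(self) -> dict[str, float]:
        return {k: v * CO2_PER_C for k, v in self.components.items()}


# ---------------------------------------------------------------------------
# decay model
# ---------------------------------------------------------------------------

def decay_fraction_in_window(t, decay_rate, tp: int):
    """Fraction of a dead-wood cohort emitted within the reference period.

    The cohort is created by clearing at the *end* of year ``t``
    (1-based) of a ``tp``-year period and decays linearly at
    ``decay_rate`` per year, so the fraction emitted by the end of the
    period is ``min(1, decay_rate * (tp - t))``.
    """
    t_arr = np.asarray(t)
    if np.any(t_arr < 1) or np.any(t_arr > tp):
        raise ValueError(f"cohort year must lie in [1, {tp}]")
    if np.any(np.asarray(decay_rate) <= 0):
        raise ValueError("decay rate must be > 0")
    out = np.minimum(1.0, np.asarray(decay_rate, dtype=float) * (tp - t_arr))
    return out if out.ndim else float(out)


def mean_decay_fraction(decay_rate, tp: int):
    """Cohort-mean emitted fraction for uniform clearing over years 1..tp."""
    rate = np.asarray(decay_rate, dtype=float)
    total = sum(np.minimum(1.0, rate * (tp - t)) for t in range(1, tp + 1))
    out = total / tp
    return out if out.ndim else float(out)


def _mean_product_decay(half_life, tp: int):
    """Cohort-mean first-order emitted fraction for wood products."""
    lam = np.log(2.0) / np.asarray(half_life, dtype=float)
    total = sum(1.0 - np.exp(-lam * (tp - t)) for t in range(1, tp + 1))
    out = total / tp
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# emission / sequestration factors and terms
# ---------------------------------------------------------------------------

def loss_factor(inputs: LossFactorInputs, tp: int):
    """Forest loss factor ``LFd_h``: within-period emissions as a
    proportion of aboveground live carbon ``Cd_h``.

    The committed on-site dead pool, relative to ``Cd_h``, is
    ``(1 - extraction) + root_shoot + necromass``. Of the cleared area a
    fraction burns: combusted carbon (completeness x pool) is emitted
    immediately except for the share converted to charcoal, which is
    treated as stored. Everything not combusted decays linearly, cohort
    averaged over the period. Extracted roundwood enters the wood-product
    pool and decays first-order with the stated half-life.
    """
    inputs.validate()
    pool = (1.0 - inputs.extraction_frac) + inputs.root_shoot + inputs.necromass_frac
    combusted = inputs.burned_frac * inputs.combustion_completeness
    immediate = combusted * (1.0 - inputs.charcoal_frac)
    decayed = (1.0 - combusted) * mean_decay_fraction(inputs.decay_rate, tp)
    site = pool * (immediate + decayed)
    products = inputs.extraction_frac * _mean_product_decay(
        inputs.product_half_life, tp)
    out = site + products
    return out if np.ndim(out) else float(out)


def forest_loss_emissions(afd_h: Mapping, cd_h: Mapping, lfd_h) -> float:
    """Biomass emissions from forest loss: sum_h AFd_h * Cd_h * LFd_h (MgC
    over the period).

    ``lfd_h`` may be a mapping keyed like the others or a single value
    applied to every stratum.
    """
    missing = set(afd_h) - set(cd_h)
    if missing:
        raise KeyError(f"strata without carbon density: {sorted(map(str, missing))}")
    total = 0.0
    for h, area in afd_h.items():
        if np.any(np.asarray(area) < 0):
            raise ValueError(f"negative loss area for stratum {h!r}")
        lfd = lfd_h[h] if isinstance(lfd_h, Mapping) else lfd_h
        total = total + area * cd_h[h] * lfd
    return total if np.ndim(total) else float(total)


def wetland_soil_emissions(awd: Mapping[str, float], soil: SoilParams):
    """Soil carbon emissions from wetland forest loss (MgC over period).

    ``awd`` maps wetland type (``"peat"`` or ``"mangrove"``) to area lost
    in ha.
    """
    soil.validate()
    per_ha = {"peat": soil.peat_emission_per_ha(),
              "mangrove": soil.mangrove_emission_per_ha()}
    total = 0.0
    for wtype, area in awd.items():
        if wtype not in per_ha:
            raise KeyError(f"unknown wetland type {wtype!r}")
        if np.any(np.asarray(area) < 0):
            raise ValueError(f"negative wetland loss area for {wtype!r}")
        total = total + area * per_ha[wtype]
    return total if np.ndim(total) else float(total)


def logging_emissions(
    asl: float,
    factors: LoggingFactors,
    road_afd: Mapping | None = None,
    road_cd: Mapping | None = None,
    road_lfd=None,
) -> dict[str, float]:
    """Selective-logging degradation emissions by component (MgC over period).

    Felling and skidding scale with logged area ``asl``; haul-road
    construction removes forest cover entirely and is charged with the
    same stratified loss computation as deforestation over road-labelled
    pixels; wood products removed from the concession follow their own
    per-ha factor. Components are reported separately and summed.
    """
    factors.validate()
    if np.any(np.asarray(asl) < 0):
        raise ValueError("logged area must be >= 0")
    haul = 0.0
    if road_afd:
        haul = forest_loss_emissions(road_afd, road_cd or {}, road_lfd)
    parts = {
        "felling": asl * factors.felling_ef,
        "skidding": asl * factors.skidding_ef,
        "haul_roads": haul,
        "wood_products": asl * factors.product_ef,
    }
    parts["total"] = sum(parts.values())
    return parts


def sequestration(
    ar: Mapping[str, float],
    rates: SequestrationRates,
    asl: float = 0.0,
    sf_sl: float | None = None,
    accrual_years: float = 1.0,
) -> float:
    """Carbon sequestered by regrowth and post-logging recovery (MgC over
    the period).

    ``ar`` maps regrowth type (fiber / oil_palm / native) to area in ha;
    each ha accrues its type's rate for ``accrual_years`` years (the
    cohort-mean convention for a non-annual gain band uses tp/2).
    Post-logging sequestration is ``asl * sf_sl`` (a per-ha total, not a
    rate).
    """
    total = 0.0
    for rtype, area in ar.items():
        if np.any(np.asarray(area) < 0):
            raise ValueError(f"negative regrowth area for {rtype!r}")
        total = total + area * rates.rate(rtype) * accrual_years
    if sf_sl is None:
        sf_sl = 0.0
    total = total + asl * sf_sl
    return total if np.ndim(total) else float(total)


def net_flux(gross_loss: float, gross_gain: float,
             components: dict[str, float] | None = None) -> FluxResult:
    """Combine annual gross loss and gain (MgC/yr) into a FluxResult."""
    return FluxResult(gross_loss=gross_loss, gross_gain=gross_gain,
                      components=dict(components or {}))
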