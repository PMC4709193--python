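"""Full flux-equation evaluation from a named parameter vector.

One function, :func:`compute_fluxes`, maps a dict of parameter values
(scalars or aligned NumPy arrays of Monte Carlo draws) plus measured
activity areas to annual flux components. The deterministic estimate,
the synthetic-truth bookkeeping, and every Monte Carlo iteration all go
through this same code path, so the uncertainty analysis propagates
through exactly the arithmetic that produces the point estimate.

Activity areas enter as measured values multiplied by unit-mean scale
parameters (``afd_scale``, ``awd_scale``, ``ar_scale``, ``asl_scale``)
so that activity-data uncertainty is part of the parameter vector.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from . import flux
from .activity import ActivitySummary

__all__ = ["compute_fluxes", "flux_result_from_components"]


def _loss_factor_inputs(p: Mapping[str, float]) -> flux.LossFactorInputs:
    return flux.LossFactorInputs(
        root_shoot=p["root_shoot"],
        necromass_frac=p["necromass_frac"],
        burned_frac=p["burned_frac"],
        combustion_completeness=p["combustion_completeness"],
        charcoal_frac=p["charcoal_frac"],
        extraction_frac=p["extraction_frac"],
        product_half_life=p["product_half_life"],
        wood_density=p.get("wood_density", 0.60),
        carbon_frac=p.get("carbon_frac", 0.47),
        decay_rate=p["decay_rate"],
    )


def _soil_params(p: Mapping[str, float]) -> flux.SoilParams:
    return flux.SoilParams(
        peat_depth=p["peat_depth"],
        peat_c_density=p["peat_c_density"],
        drainage_depth=p["peat_drainage_depth"],
        peat_loss_frac=p["peat_loss_frac"],
        mangrove_top_depth=p["mangrove_top_depth"],
        mangrove_top_stock=p["mangrove_top_stock"],
        mangrove_deep_stock=p["mangrove_deep_stock"],
        mangrove_top_loss_frac=p["mangrove_top_loss_frac"],
        mangrove_deep_loss_frac=p["mangrove_deep_loss_frac"],
    )


def compute_fluxes(
    activity: ActivitySummary,
    params: Mapping[str, float],
    road_afd: Mapping | None = None,
    accrual_years: float | None = None,
) -> dict[str, float]:
    """Annual flux components (MgC/yr) from activity data and parameters.

    ``params`` must contain the physical parameters of
    :func:`juriflux.params.default_parameters` plus one ``cd_<h>`` entry
    per stratum appearing in ``activity.afd`` (and in ``road_afd``, the
    stratified haul-road loss areas in ha over the period). Values may be
    scalars or aligned arrays of draws.

    ``accrual_years`` is the regrowth accumulation convention: the number
    of years an average regrowth cohort accrues its sequestration rate;
    default ``tp / 2`` (cohort-mean for a non-annual gain band).
    """
    tp = activity.tp
    if accrual_years is None:
        accrual_years = tp / 2.0
    if road_afd is None:
        road_afd = activity.road_afd

    cd = {h: params[f"cd_{h}"] for h in
          {h for h, _ in activity.afd} | set(road_afd or {})}

    lfd = flux.loss_factor(_loss_factor_inputs(params), tp)

    afd_scale = params.get("afd_scale", 1.0)
    afd = {h: a * afd_scale for h, a in activity.afd_by_stratum().items()}
    loss_biomass = flux.forest_loss_emissions(afd, cd, lfd)

    awd_scale = params.get("awd_scale", 1.0)
    awd = {k: v * awd_scale for k, v in activity.awd.items()}
    soil = flux.wetland_soil_emissions(awd, _soil_params(params))

    asl_scale = params.get("asl_scale", 1.0)
    asl = activity.asl * asl_scale
    factors = flux.LoggingFactors(
        felling_ef=params["felling_ef"],
        skidding_ef=params["skidding_ef"],
        product_ef=params["logging_product_ef"],
        sf_sl=params["sf_sl"],
    )
    road_afd_scaled = {h: a * afd_scale for h, a in (road_afd or {}).items()}
    logging = flux.logging_emissions(asl, factors, road_afd_scaled, cd, lfd)

    ar_scale = params.get("ar_scale", 1.0)
    ar = {k: v * ar_scale for k, v in activity.ar.items()}
    rates = flux.SequestrationRates(
        fiber=params["sfr_fiber"],
        oil_palm=params["sfr_oil_palm"],
        native=params["sfr_native"],
    )
    seq_regrowth = flux.sequestration(ar, rates, asl=0.0,
                                      accrual_years=accrual_years)
    seq_logging = asl * params["sf_sl"]

    out = {
        "forest_loss_biomass": loss_biomass / tp,
        "wetland_soil": soil / tp,
        "logging_felling": logging["felling"] / tp,
        "logging_skidding": logging["skidding"] / tp,
        "logging_haul": logging["haul_roads"] / tp,
        "logging_products": logging["wood_products"] / tp,
        "seq_regrowth": seq_regrowth / tp,
        "seq_logging": seq_logging / tp,
    }
    out["logging_total"] = (out["logging_felling"] + out["logging_skidding"]
                            + out["logging_haul"] + out["logging_products"])
    out["gross_loss"] = (out["forest_loss_biomass"] + out["wetland_soil"]
                         + out["logging_total"])
    out["gross_gain"] = out["seq_regrowth"] + out["seq_logging"]
    out["net"] = out["gross_loss"] - out["gross_gain"]
    return out


def flux_result_from_components(components: Mapping[str, float]) -> flux.FluxResult:
    """Package scalar components into a :class:`juriflux.flux.FluxResult`."""
    comp = {k: float(v) for k, v in components.items()
            if k not in ("gross_loss", "gross_gain", "net")}
    return flux.net_flux(float(components["gross_loss"]),
                         float(components["gross_gain"]), comp)
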