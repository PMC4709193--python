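"""End-to-end jurisdictional accounting run.

Chains the stages: synthetic jurisdiction (or pre-built rasters) ->
footprint stratification -> activity extraction -> deterministic flux ->
Monte Carlo uncertainty (optionally with source attribution) -> zone /
permit / disturbance ledger, with a JSON run manifest (seed, version,
parameter hash) for reproducibility. Stage failures surface with the
stage name attached.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity import (ActivitySummary, classify_logging_roads, extract_loss,
                       annualize_gain, partition_gain,
                       summarize_logging_records, trend_test, wetland_loss)
from .biomass import (StratificationResult, StratumRecord, evaluate_strata,
                      fit_stratum_means, build_benchmark_map)
from .flux import CO2_PER_C
from .ledger import build_ledger
from .model import compute_fluxes
from .montecarlo import AttributionResult, MCResult, attribute_uncertainty, \
    run_monte_carlo
from .params import ParameterSet, default_parameters, stratum_parameters
from .synthetic import (DISTURBANCE_CODES, Landscape, SyntheticConfig,
                        generate_footprints, generate_landscape,
                        generate_logging_records)

__all__ = ["PipelineResult", "run_pipeline"]

TG = 1e6  # Mg per Tg

_DISTURBANCE_ROW = {
    "oil_palm": "Oil Palm",
    "agriculture": "Agriculture/Other",
    "fiber": "Fiber Plantation",
    "mining": "Mining",
}


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class PipelineResult:
    landscape: Landscape
    footprints: pd.DataFrame
    stratification: StratificationResult
    stratum_records: list[StratumRecord]
    cd_means: dict
    cd_sems: dict
    activity: ActivitySummary
    road_afd: dict
    components: dict                     # deterministic annual MgC/yr
    mc: MCResult
    attribution: AttributionResult | None
    ledger: pd.DataFrame
    loss_trend: dict
    benchmark_map: np.ndarray
    manifest: dict


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("strata")
def _fit_strata(footprints: pd.DataFrame):
    strat = evaluate_strata(footprints, by="stratum")
    # per final stratum, mean and SEM; map back to each original id
    final_records = {
        str(r.stratum): r
        for r in fit_stratum_means(
            footprints.assign(
                final=footprints["stratum"].map(
                    lambda h: strat.assignment[h])),
            by="final")
    }
    cd_means, cd_sems = {}, {}
    for orig, final in strat.assignment.items():
        rec = final_records[str(final)]
        cd_means[orig] = rec.mean
        cd_sems[orig] = rec.sem
    return strat, list(final_records.values()), cd_means, cd_sems


@_stage("activity")
def _extract_activity(landscape: Landscape, completeness_mode: str):
    bundle = landscape.rasters
    cfg = landscape.config
    loss_mask = bundle["loss_year"] > 0
    roads = classify_logging_roads(loss_mask, bundle["concession"].astype(bool))

    # relabel detected road pixels before cross-tabulation
    dist = bundle["disturbance"].copy()
    dist[roads == 1] = DISTURBANCE_CODES["logging_roads"]
    # conversion loss inside the concession without a type keeps its label
    relabeled = bundle.layers | {"disturbance": dist}
    from .rasters import RasterBundle
    work = RasterBundle(pixel_size_m=bundle.pixel_size_m, layers=relabeled,
                        codes=bundle.codes)

    afd_all, annual = extract_loss(work, period=(1, cfg.tp))
    road_afd = {h: a for (h, d), a in afd_all.items() if d == "logging_roads"}
    afd = {(h, d): a for (h, d), a in afd_all.items() if d != "logging_roads"}
    awd = wetland_loss(work, period=(1, cfg.tp))

    gain_by_type = partition_gain(work)
    ar = annualize_gain(gain_by_type, cfg.gain_source_years, cfg.tp)

    conc_area = work.area_ha(work["concession"].astype(bool))
    records = generate_logging_records(cfg, conc_area)
    logging_summary = summarize_logging_records(
        records, cfg.tp, completeness=cfg.record_completeness,
        scale_mode=completeness_mode)

    activity = ActivitySummary(
        afd=afd, road_afd=road_afd, awd=awd, ar=ar,
        asl=logging_summary["asl_ha_period"],
        harvest_volume=logging_summary["volume_m3_period"],
        annual_loss=annual, tp=cfg.tp,
    )
    activity.validate()
    return activity, road_afd, records


def _zone_permit_crosstab(landscape: Landscape, road_detected: np.ndarray):
    """Loss pixel areas keyed by (zone, permit, row label, stratum, wetland)."""
    b = landscape.rasters
    px = b.pixel_area_ha
    loss = b["loss_year"] > 0
    inv_zone = {v: k for k, v in b.codes["zone"].items()}
    inv_permit = {v: k for k, v in b.codes["permit"].items()}
    inv_dist = {v: k for k, v in b.codes["disturbance"].items()}
    ys, xs = np.nonzero(loss)
    cells: dict = {}
    for y, x in zip(ys, xs):
        zone = inv_zone[int(b["zone"][y, x])]
        zone = "HP/HPT" if zone == "HP" else zone
        permit = inv_permit[int(b["permit"][y, x])]
        if road_detected[y, x] == 1:
            row = "Logging Roads"
        else:
            dcode = inv_dist.get(int(b["disturbance"][y, x]), "agriculture")
            row = _DISTURBANCE_ROW.get(dcode, "Agriculture/Other")
        key = (zone, permit, row, int(b["stratum"][y, x]),
               int(b["wetland"][y, x]))
        cells[key] = cells.get(key, 0.0) + px
    return cells


@_stage("ledger")
def _build_run_ledger(landscape: Landscape, activity: ActivitySummary,
                      cd_means: dict, components: dict,
                      params: dict, accrual_years: float) -> pd.DataFrame:
    from .flux import LossFactorInputs, SoilParams, loss_factor
    cfg = landscape.config
    tp = cfg.tp
    b = landscape.rasters
    road_detected = classify_logging_roads(b["loss_year"] > 0,
                                           b["concession"].astype(bool))
    cells = _zone_permit_crosstab(landscape, road_detected)

    lfi = LossFactorInputs(
        root_shoot=params["root_shoot"], necromass_frac=params["necromass_frac"],
        burned_frac=params["burned_frac"],
        combustion_completeness=params["combustion_completeness"],
        charcoal_frac=params["charcoal_frac"],
        extraction_frac=params["extraction_frac"],
        product_half_life=params["product_half_life"],
        decay_rate=params["decay_rate"])
    lfd = loss_factor(lfi, tp)
    soil = SoilParams(
        peat_depth=params["peat_depth"], peat_c_density=params["peat_c_density"],
        drainage_depth=params["peat_drainage_depth"],
        peat_loss_frac=params["peat_loss_frac"],
        mangrove_top_stock=params["mangrove_top_stock"],
        mangrove_deep_stock=params["mangrove_deep_stock"],
        mangrove_top_loss_frac=params["mangrove_top_loss_frac"],
        mangrove_deep_loss_frac=params["mangrove_deep_loss_frac"])
    soil_per_ha = {0: 0.0, 1: soil.peat_emission_per_ha(),
                   2: soil.mangrove_emission_per_ha()}

    # gross emissions per (zone, permit, row)
    agg: dict = {}
    for (zone, permit, row, h, wet), area in cells.items():
        gross_c = area * cd_means[h] * lfd + area * soil_per_ha[wet]
        rec = agg.setdefault((zone, permit, row),
                             {"area": 0.0, "gross_c": 0.0})
        rec["area"] += area
        rec["gross_c"] += gross_c

    # skidding/felling emissions are concession-wide, not pixel-located
    asl = activity.asl
    sf_row = agg.setdefault(("HP/HPT", "HA", "Skidding/Felling"),
                            {"area": 0.0, "gross_c": 0.0})
    sf_row["area"] += asl
    sf_row["gross_c"] += asl * (params["felling_ef"] + params["skidding_ef"]
                                + params["logging_product_ef"])

    # regrowth: typed sequestration allocated to (zone, permit) of the gain
    px = b.pixel_area_ha
    gain = b["gain"].astype(bool)
    inv_zone = {v: k for k, v in b.codes["zone"].items()}
    inv_permit = {v: k for k, v in b.codes["permit"].items()}
    rates = {"HTI": params["sfr_fiber"], "HGU": params["sfr_oil_palm"]}
    seq_zp: dict = {}
    regrow_zp: dict = {}
    scale = tp / cfg.gain_source_years
    ys, xs = np.nonzero(gain)
    for y, x in zip(ys, xs):
        zone = inv_zone[int(b["zone"][y, x])]
        zone = "HP/HPT" if zone == "HP" else zone
        permit = inv_permit[int(b["permit"][y, x])]
        rate = rates.get(permit, params["sfr_native"])
        area = px * scale
        seq_zp[(zone, permit)] = (seq_zp.get((zone, permit), 0.0)
                                  + area * rate * accrual_years)
        regrow_zp[(zone, permit)] = regrow_zp.get((zone, permit), 0.0) + area
    seq_zp[("HP/HPT", "HA")] = (seq_zp.get(("HP/HPT", "HA"), 0.0)
                                + asl * params["sf_sl"])

    # distribute each (zone, permit) sequestration across its rows by area
    rows = []
    zp_area: dict = {}
    for (zone, permit, row), rec in agg.items():
        zp_area[(zone, permit)] = zp_area.get((zone, permit), 0.0) + rec["area"]
    for (zone, permit, row), rec in sorted(agg.items()):
        share = rec["area"] / zp_area[(zone, permit)]
        seq_c = seq_zp.get((zone, permit), 0.0) * share
        regrow = regrow_zp.get((zone, permit), 0.0) * share
        rows.append({
            "zone": zone, "permit": permit, "disturbance": row,
            "area_disturbed_ha_yr": rec["area"] / tp,
            "regrowth_ha_yr": regrow / tp,
            "gross_Tg": rec["gross_c"] / tp * CO2_PER_C / TG,
            "seq_Tg": seq_c / tp * CO2_PER_C / TG,
        })
    return build_ledger(pd.DataFrame(rows))


def run_pipeline(
    config: SyntheticConfig | None = None,
    n_iterations: int = 100_000,
    seed: int | None = None,
    n_per_stratum: int = 80,
    noise_cv: float = 0.10,
    completeness_mode: str = "proportional",
    accrual_years: float | None = None,
    with_attribution: bool = False,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full accounting chain on a synthetic jurisdiction.

    ``seed`` overrides the config seed for every stage. Outputs
    (rasters, tables, manifest) are written under ``outdir`` when given.
    """
    config = config or SyntheticConfig()
    if seed is not None:
        config.seed = int(seed)
    if accrual_years is None:
        accrual_years = config.tp / 2.0

    try:
        landscape = generate_landscape(config)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage 'synthetic' failed: {exc}") from exc

    footprints = generate_footprints(landscape, n_per_stratum=n_per_stratum,
                                     noise_cv=noise_cv)
    strat, records, cd_means, cd_sems = _fit_strata(footprints)
    activity, road_afd, log_records = _extract_activity(
        landscape, completeness_mode)

    pset = default_parameters()
    for spec in stratum_parameters(cd_means, cd_sems):
        pset.add(spec)
    pvals = pset.means()

    components = compute_fluxes(activity, pvals, road_afd=road_afd,
                                accrual_years=accrual_years)

    def model_fn(draws):
        return compute_fluxes(activity, draws, road_afd=road_afd,
                              accrual_years=accrual_years)

    try:
        mc = run_monte_carlo(pset, model_fn, n=n_iterations, seed=config.seed,
                             keep_draws=False)
        attribution = (attribute_uncertainty(pset, model_fn, n=n_iterations,
                                             seed=config.seed)
                       if with_attribution else None)
    except Exception as exc:
        raise StageError(f"stage 'uncertainty' failed: {exc}") from exc

    ledger = _build_run_ledger(landscape, activity, cd_means, components,
                               pvals, accrual_years)
    trend = trend_test(activity.annual_loss)
    benchmark = build_benchmark_map(landscape.rasters["stratum"], cd_means)

    param_text = "\n".join(
        f"{s.name}={s.mean!r}|{s.mode}|{s.category}|{s.sem!r}" for s in pset)
    manifest = {
        "seed": config.seed,
        "juriflux_version": __version__,
        "grid": list(config.shape),
        "pixel_size_m": config.pixel_size_m,
        "tp": config.tp,
        "n_iterations": n_iterations,
        "n_per_stratum": n_per_stratum,
        "noise_cv": noise_cv,
        "completeness_mode": completeness_mode,
        "accrual_years": accrual_years,
        "zone_permit_precedence": "permit label wins over zone label",
        "parameter_hash": hashlib.md5(param_text.encode()).hexdigest(),
        "n_final_strata": strat.n_strata,
        "net_Tg": components["net"] * CO2_PER_C / TG,
    }

    result = PipelineResult(
        landscape=landscape, footprints=footprints, stratification=strat,
        stratum_records=records, cd_means=cd_means, cd_sems=cd_sems,
        activity=activity, road_afd=road_afd, components=components,
        mc=mc, attribution=attribution, ledger=ledger, loss_trend=trend,
        benchmark_map=benchmark, manifest=manifest,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir), log_records)
    return result


def _write_outputs(result: PipelineResult, outdir: Path,
                   log_records: pd.DataFrame) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.landscape.rasters.write(outdir / "rasters")
    import tifffile
    tifffile.imwrite(outdir / "rasters" / "benchmark_biomass.tif",
                     result.benchmark_map.astype(np.float32))
    result.footprints.to_csv(outdir / "footprints.csv", index=False)
    log_records.to_csv(outdir / "logging_records.csv", index=False)
    from .biomass import records_frame
    records_frame(result.stratum_records).to_csv(outdir / "stratum_records.csv")
    result.ledger.to_csv(outdir / "ledger.csv", index=False)
    result.mc.summary.to_csv(outdir / "mc_summary.csv")
    if result.attribution is not None:
        result.attribution.normalized_pct.to_frame().join(
            result.attribution.raw_reduction_pct).to_csv(
                outdir / "attribution.csv")
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True))
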