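"""Synthetic jurisdiction with known true carbon fluxes.

Generates the complete input bundle the accounting pipeline consumes —
loss-year / gain / canopy / stratum / zone / permit / concession /
wetland rasters, lidar-footprint-style biomass samples, and permit-year
logging records — from a configuration whose quantities (stratum biomass
means, annual loss and gain fractions, wetland extents, logging
intensity) are known exactly, so every downstream stage can be tested
for recovery of a known truth.

The landscape emulates a frontier jurisdiction: spatial-plan zones in
column bands (non-forest APL, production forest HP, protection forest
HL), permit blocks within them (oil palm HGU, coal PKP2B, selective
logging HA, fiber HTI), 13 default biomass strata in row bands crossing
the zones, wetland (peat / mangrove) strata forming the wetland mask,
scattered conversion loss with uniformly distributed loss years, narrow
haul-road corridors plus compact conversion blocks inside the logging
concession, and a non-annual gain band.

Determinism: one global seed drives all sub-generators through a
documented splitting scheme — sub-generator ``k`` uses
``numpy.random.default_rng([seed, k])`` with fixed slot numbers
(0 = loss placement, 1 = gain placement, 2 = footprints, 3 = logging
records).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .activity import ActivitySummary
from .model import compute_fluxes
from .params import ParameterSet, default_parameters, stratum_parameters
from .rasters import RasterBundle, pixel_area_ha

__all__ = [
    "StratumSpec",
    "SyntheticConfig",
    "TruthRecord",
    "Landscape",
    "generate_landscape",
    "generate_footprints",
    "generate_logging_records",
]

ZONE_CODES = {"APL": 1, "HP": 2, "HL": 3}
PERMIT_CODES = {"none": 0, "HGU": 1, "PKP2B": 2, "HA": 3, "HTI": 4}
DISTURBANCE_CODES = {"none": 0, "oil_palm": 1, "agriculture": 2, "fiber": 3,
                     "mining": 4, "logging_roads": 5}
WETLAND_CODES = {"none": 0, "peat": 1, "mangrove": 2}

# RNG slot numbers for the seed-splitting scheme
_SLOT_LOSS, _SLOT_GAIN, _SLOT_FOOTPRINTS, _SLOT_RECORDS = 0, 1, 2, 3


@dataclass(frozen=True)
class StratumSpec:
    """One forest biomass stratum of the synthetic jurisdiction."""

    name: str
    disturbance: str        # primary | non_primary | secondary
    elevation: str          # lowland | highland
    substrate: str          # low_fertility | high_fertility | peat | mangrove
    biomass_mean: float     # true aboveground live C, MgC/ha
    area_fraction: float    # share of the grid (row band height)


def default_strata() -> list[StratumSpec]:
    """13 biomass classes with well-separated true means (MgC/ha)."""
    rows = [
        ("pri-high-fert", "primary", "highland", "high_fertility", 200.0, 0.12),
        ("pri-high-acid", "primary", "highland", "low_fertility", 186.0, 0.10),
        ("pri-low-fert", "primary", "lowland", "high_fertility", 172.0, 0.10),
        ("pri-low-acid", "primary", "lowland", "low_fertility", 158.0, 0.16),
        ("pri-peat", "primary", "lowland", "peat", 144.0, 0.03),
        ("pri-mangrove", "primary", "lowland", "mangrove", 130.0, 0.02),
        ("non-high-fert", "non_primary", "highland", "high_fertility", 116.0, 0.08),
        ("non-high-acid", "non_primary", "highland", "low_fertility", 102.0, 0.08),
        ("non-low-fert", "non_primary", "lowland", "high_fertility", 88.0, 0.08),
        ("non-low-acid", "non_primary", "lowland", "low_fertility", 74.0, 0.12),
        ("non-peat", "non_primary", "lowland", "peat", 60.0, 0.02),
        ("sec-lowland", "secondary", "lowland", "low_fertility", 46.0, 0.05),
        ("sec-highland", "secondary", "highland", "low_fertility", 32.0, 0.04),
    ]
    return [StratumSpec(*r) for r in rows]


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic jurisdiction.

    Loss fractions are annual fractions of total forest area converted
    per disturbance type; the logging fraction is the annual share of
    concession area selectively logged (felling/skidding, no canopy
    loss); haul roads are explicit narrow corridors.
    """

    shape: tuple[int, int] = (140, 140)
    pixel_size_m: float = 30.0
    tp: int = 10
    seed: int = 0
    strata: list[StratumSpec] = field(default_factory=default_strata)
    # annual conversion-loss fraction of forest area, by disturbance type
    loss_fracs: dict = field(default_factory=lambda: {
        "oil_palm": 0.005, "agriculture": 0.005, "fiber": 0.002,
        "mining": 0.0004,
    })
    # haul roads inside the logging concession
    n_roads: int = 8
    road_width_px: int = 2
    road_length_px: int = 36
    # compact (>= 4 px wide) conversion blocks inside the concession
    n_concession_blocks: int = 2
    concession_block_px: int = 5
    # forest gain
    gain_frac_yr: float = 0.003
    gain_source_years: float = 12.0
    gain_placement: str = "background"      # "background" | "on_loss"
    # legal selective logging
    n_permits: int = 20
    asl_frac_yr: float = 0.010              # of concession area
    volume_m3_per_ha: float = 31.9
    record_completeness: float = 0.57
    # zone column fractions
    zone_fracs: dict = field(default_factory=lambda: {
        "APL": 0.30, "HP": 0.55, "HL": 0.15})

    def validate(self) -> None:
        if self.tp < 1:
            raise ValueError("reference period tp must be >= 1 year")
        if any(f < 0 for f in self.loss_fracs.values()):
            raise ValueError("loss fractions must be >= 0")
        total_loss = sum(self.loss_fracs.values()) * self.tp
        if total_loss > 1.0:
            raise ValueError("loss over the period exceeds total forest area")
        if self.gain_frac_yr < 0 or self.asl_frac_yr < 0:
            raise ValueError("rates must be >= 0")
        if abs(sum(s.area_fraction for s in self.strata) - 1.0) > 1e-6:
            raise ValueError("stratum area fractions must sum to 1")
        if self.gain_placement not in ("background", "on_loss"):
            raise ValueError(f"unknown gain placement {self.gain_placement!r}")

    @property
    def pixel_area_ha(self) -> float:
        return pixel_area_ha(self.pixel_size_m)


@dataclass
class TruthRecord:
    """Ground-truth annual fluxes implied by the generated landscape.

    ``gross_emissions`` and ``gross_sequestration`` are Mg CO2/yr; the
    identity ``net = gross_emissions - gross_sequestration`` holds
    exactly by construction.
    """

    gross_emissions: float
    gross_sequestration: float
    components: dict = field(default_factory=dict)   # Mg CO2/yr

    @property
    def net(self) -> float:
        return self.gross_emissions - self.gross_sequestration


@dataclass
class Landscape:
    """A generated jurisdiction: rasters plus exact bookkeeping."""

    config: SyntheticConfig
    rasters: RasterBundle
    truth: TruthRecord
    true_activity: ActivitySummary
    true_road_afd: dict                      # stratum id -> ha over period
    stratum_means: dict                      # stratum id -> true MgC/ha
    stratum_specs: dict                      # stratum id -> StratumSpec

    @property
    def wetland_strata(self) -> dict[int, str]:
        return {h: s.substrate for h, s in self.stratum_specs.items()
                if s.substrate in ("peat", "mangrove")}


def _rng(seed: int, slot: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(slot)])


def _row_bands(n_rows: int, fractions: Sequence[float]) -> list[slice]:
    edges = np.floor(np.cumsum([0.0, *fractions]) * n_rows + 0.5).astype(int)
    edges[-1] = n_rows
    return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def generate_landscape(config: SyntheticConfig | None = None,
                       params: ParameterSet | None = None) -> Landscape:
    """Build the raster bundle and its exact truth record.

    Loss-pixel counts are deterministic (``round(eligible * fraction *
    tp)``); only their placement and year assignment use the seeded RNG,
    and loss years are spread as evenly as possible across 1..tp
    (no trend, by construction). The truth record is evaluated with the
    same flux arithmetic as the pipeline, at the true areas, true
    stratum means, and parameter-file central values.
    """
    config = config or SyntheticConfig()
    config.validate()
    rows, cols = config.shape
    tp = config.tp
    px = config.pixel_area_ha

    # --- static layers -------------------------------------------------
    zone = np.zeros((rows, cols), dtype=np.int16)
    zfr = config.zone_fracs
    c_apl = int(round(cols * zfr["APL"]))
    c_hp = c_apl + int(round(cols * zfr["HP"]))
    zone[:, :c_apl] = ZONE_CODES["APL"]
    zone[:, c_apl:c_hp] = ZONE_CODES["HP"]
    zone[:, c_hp:] = ZONE_CODES["HL"]

    permit = np.zeros((rows, cols), dtype=np.int16)
    # oil-palm estates in the western APL band, coal block in its north-east
    permit[:, : int(c_apl * 0.6)] = PERMIT_CODES["HGU"]
    permit[: int(rows * 0.4), int(c_apl * 0.6): c_apl] = PERMIT_CODES["PKP2B"]
    # selective-logging concessions over most production forest, fiber below
    r_ha = int(rows * 0.7)
    permit[:r_ha, c_apl:c_hp] = PERMIT_CODES["HA"]
    permit[r_ha:, c_apl:c_hp] = PERMIT_CODES["HTI"]
    concession = (permit == PERMIT_CODES["HA"]).astype(np.uint8)

    stratum = np.zeros((rows, cols), dtype=np.int16)
    specs = {i + 1: s for i, s in enumerate(config.strata)}
    for (h, s), band in zip(specs.items(),
                            _row_bands(rows, [s.area_fraction
                                              for s in config.strata])):
        stratum[band, :] = h

    wetland = np.zeros((rows, cols), dtype=np.int16)
    for h, s in specs.items():
        if s.substrate in ("peat", "mangrove"):
            wetland[stratum == h] = WETLAND_CODES[s.substrate]

    canopy2000 = np.ones((rows, cols), dtype=np.uint8)
    forest_px_total = int(canopy2000.sum())

    # --- forest loss ---------------------------------------------------
    loss_year = np.zeros((rows, cols), dtype=np.int16)
    disturbance = np.zeros((rows, cols), dtype=np.int16)
    rng_loss = _rng(config.seed, _SLOT_LOSS)
    in_conc = concession.astype(bool)

    eligibility = {
        "oil_palm": (zone == ZONE_CODES["APL"]),
        "agriculture": ~in_conc,
        "fiber": permit == PERMIT_CODES["HTI"],
        "mining": permit == PERMIT_CODES["PKP2B"],
    }

    def _take(mask: np.ndarray, n: int, label: str) -> np.ndarray:
        free = mask & (loss_year == 0) & canopy2000.astype(bool)
        idx = np.flatnonzero(free)
        if n > idx.size:
            raise ValueError(
                f"grid too small: {label} needs {n} pixels, "
                f"{idx.size} eligible")
        return rng_loss.choice(idx, size=n, replace=False)

    def _assign_years(flat_idx: np.ndarray) -> None:
        # spread loss years 1..tp as evenly as possible (no trend)
        years = (np.arange(flat_idx.size) % tp) + 1
        rng_loss.shuffle(years)
        loss_year.ravel()[flat_idx] = years

    for dtype, frac in config.loss_fracs.items():
        n = int(round(forest_px_total * frac * tp))
        if n == 0:
            continue
        chosen = _take(eligibility[dtype], n, dtype)
        _assign_years(chosen)
        disturbance.ravel()[chosen] = DISTURBANCE_CODES[dtype]

    # haul-road corridors inside the concession (width <= 3 px rule)
    road_rows_avail = np.arange(2, r_ha - config.road_width_px - 2)
    if config.n_roads > 0:
        if road_rows_avail.size < config.n_roads * (config.road_width_px + 3):
            raise ValueError("grid too small to place requested haul roads")
        picks = rng_loss.choice(
            road_rows_avail[:: config.road_width_px + 3],
            size=config.n_roads, replace=False)
        for k, r0 in enumerate(sorted(int(r) for r in picks)):
            c0 = c_apl + 2 + (k * 7) % max(1, (c_hp - c_apl
                                               - config.road_length_px - 4))
            sl = (slice(r0, r0 + config.road_width_px),
                  slice(c0, c0 + config.road_length_px))
            road_free = (loss_year[sl] == 0) & in_conc[sl]
            yr = int(rng_loss.integers(1, tp + 1))
            loss_year[sl][road_free] = yr
            disturbance[sl][road_free] = DISTURBANCE_CODES["logging_roads"]

    # compact conversion blocks inside the concession (>= 4 px wide)
    b = config.concession_block_px
    for k in range(config.n_concession_blocks):
        r0 = 3 + (k * (b + 9)) % max(1, r_ha - b - 4)
        c0 = c_apl + 8 + (k * (b + 11)) % max(1, c_hp - c_apl - b - 10)
        sl = (slice(r0, r0 + b), slice(c0, c0 + b))
        free = (loss_year[sl] == 0) & in_conc[sl]
        years = (np.arange(int(free.sum())) % tp) + 1
        loss_year[sl][free] = years
        disturbance[sl][free] = DISTURBANCE_CODES["agriculture"]

    # --- forest gain ---------------------------------------------------
    gain = np.zeros((rows, cols), dtype=np.uint8)
    rng_gain = _rng(config.seed, _SLOT_GAIN)
    n_gain = int(round(forest_px_total * config.gain_frac_yr
                       * config.gain_source_years))
    if n_gain:
        if config.gain_placement == "on_loss":
            pool = np.flatnonzero(loss_year > 0)
        else:
            pool = np.flatnonzero(loss_year == 0)
        if n_gain > pool.size:
            raise ValueError("grid too small to place requested gain pixels")
        gain.ravel()[rng_gain.choice(pool, size=n_gain, replace=False)] = 1

    rasters = RasterBundle(
        pixel_size_m=config.pixel_size_m,
        layers={
            "loss_year": loss_year, "gain": gain, "canopy2000": canopy2000,
            "stratum": stratum, "disturbance": disturbance, "zone": zone,
            "permit": permit, "concession": concession, "wetland": wetland,
        },
        codes={"zone": ZONE_CODES, "permit": PERMIT_CODES,
               "disturbance": DISTURBANCE_CODES, "wetland": WETLAND_CODES},
    )

    # --- exact truth bookkeeping ---------------------------------------
    road_code = DISTURBANCE_CODES["logging_roads"]
    lost = loss_year > 0
    afd_true: dict = {}
    road_afd_true: dict = {}
    for h in specs:
        in_h = lost & (stratum == h)
        for dtype, code in DISTURBANCE_CODES.items():
            if code == 0:
                continue
            n = int(np.count_nonzero(in_h & (disturbance == code)))
            if n == 0:
                continue
            if code == road_code:
                road_afd_true[h] = n * px
            else:
                afd_true[(h, dtype)] = n * px
    awd_true = {
        "peat": float(np.count_nonzero(lost & (wetland == 1))) * px,
        "mangrove": float(np.count_nonzero(lost & (wetland == 2))) * px,
    }
    scale = tp / config.gain_source_years
    gain_b = gain.astype(bool)
    fiber_m = permit == PERMIT_CODES["HTI"]
    palm_m = permit == PERMIT_CODES["HGU"]
    ar_true = {
        "fiber": float(np.count_nonzero(gain_b & fiber_m)) * px * scale,
        "oil_palm": float(np.count_nonzero(gain_b & palm_m)) * px * scale,
        "native": float(np.count_nonzero(gain_b & ~fiber_m & ~palm_m)) * px * scale,
    }
    conc_area = float(concession.sum()) * px
    asl_true = conc_area * config.asl_frac_yr * tp
    annual = np.array([float(np.count_nonzero(loss_year == t)) * px
                       for t in range(1, tp + 1)])

    true_activity = ActivitySummary(
        afd=afd_true, road_afd=road_afd_true, awd=awd_true, ar=ar_true,
        asl=asl_true,
        harvest_volume=asl_true * config.volume_m3_per_ha,
        annual_loss=annual, tp=tp,
    )
    stratum_means = {h: s.biomass_mean for h, s in specs.items()}

    pset = params or default_parameters()
    pvals = pset.means()
    pvals.update({f"cd_{h}": m for h, m in stratum_means.items()})
    comp = compute_fluxes(true_activity, pvals, road_afd=road_afd_true)
    from .flux import CO2_PER_C
    truth = TruthRecord(
        gross_emissions=comp["gross_loss"] * CO2_PER_C,
        gross_sequestration=comp["gross_gain"] * CO2_PER_C,
        components={k: v * CO2_PER_C for k, v in comp.items()},
    )

    return Landscape(config=config, rasters=rasters, truth=truth,
                     true_activity=true_activity, true_road_afd=road_afd_true,
                     stratum_means=stratum_means, stratum_specs=specs)


def generate_footprints(
    landscape: Landscape,
    n_per_stratum: int = 80,
    noise_cv: float = 0.10,
    seed: int | None = None,
    loss_screen_year: int = 9,
) -> pd.DataFrame:
    """Draw lidar-footprint-style biomass samples from the landscape.

    Samples are restricted to pixels forested in year 2000 with no
    forest loss before ``loss_screen_year`` (screening out locations
    whose biomass the footprint could no longer represent). Noise is
    multiplicative lognormal with coefficient of variation ``noise_cv``,
    mean-corrected so the sample mean is an unbiased estimate of the
    stratum's true mean; ``noise_cv = 0`` returns the true mean exactly.

    Strata with no eligible pixels are omitted with a warning.
    """
    if n_per_stratum < 2:
        raise ValueError("need at least 2 footprints per stratum")
    cfg = landscape.config
    seed = cfg.seed if seed is None else seed
    rng = _rng(seed, _SLOT_FOOTPRINTS)
    loss = landscape.rasters["loss_year"]
    stratum = landscape.rasters["stratum"]
    canopy = landscape.rasters["canopy2000"].astype(bool)
    eligible = canopy & ((loss == 0) | (loss >= loss_screen_year))

    sigma = np.sqrt(np.log1p(noise_cv ** 2))
    parts = []
    for h, spec in landscape.stratum_specs.items():
        idx = np.flatnonzero(eligible & (stratum == h))
        if idx.size == 0:
            warnings.warn(f"stratum {spec.name!r} has no eligible pixels; omitted")
            continue
        replace = idx.size < n_per_stratum
        chosen = rng.choice(idx, size=n_per_stratum, replace=replace)
        ys, xs = np.unravel_index(chosen, loss.shape)
        if noise_cv > 0:
            noise = np.exp(rng.normal(-0.5 * sigma ** 2, sigma,
                                      size=n_per_stratum))
        else:
            noise = np.ones(n_per_stratum)
        parts.append(pd.DataFrame({
            "x": xs.astype(int), "y": ys.astype(int), "stratum": h,
            "disturbance": spec.disturbance, "elevation": spec.elevation,
            "substrate": spec.substrate,
            "biomass": spec.biomass_mean * noise,
        }))
    if not parts:
        return pd.DataFrame(columns=["x", "y", "stratum", "disturbance",
                                     "elevation", "substrate", "biomass"])
    return pd.concat(parts, ignore_index=True)


def generate_logging_records(
    config: SyntheticConfig,
    concession_area_ha: float,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permit-year legal logging records (area ha, volume m3).

    ``n_permits`` permits each report one row per year 1..tp; the annual
    jurisdiction harvest (``concession area x asl_frac_yr``) is split
    evenly across permits so the recorded total conserves the configured
    intensity. A seeded subset of ``record_completeness`` of all
    permit-years is retained, emulating incomplete government records.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, _SLOT_RECORDS)
    asl_yr = concession_area_ha * config.asl_frac_yr
    per_permit = asl_yr / max(config.n_permits, 1)
    rows = [
        {"permit": f"HA-{p + 1:02d}", "year": y,
         "area_ha": per_permit,
         "volume_m3": per_permit * config.volume_m3_per_ha}
        for p in range(config.n_permits)
        for y in range(1, config.tp + 1)
    ]
    table = pd.DataFrame(rows)
    keep = int(round(len(table) * config.record_completeness))
    if keep < len(table):
        idx = np.sort(rng.choice(len(table), size=keep, replace=False))
        table = table.iloc[idx].reset_index(drop=True)
    return table
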