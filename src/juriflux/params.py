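"""Emission-equation parameters and their uncertainty specifications.

Every scalar input to the gain-loss flux equation is described by a
:class:`ParameterSpec`: a mean value, units, and an uncertainty mode.
Parameters with sufficient empirical data carry a standard error of the
mean (SEM) directly; the rest are assigned a default uncertainty
category expressed as a percent error at the 95% confidence level,
converted to an SEM by dividing by 1.96 (central limit theorem).

Categories and their assigned percent errors (at +/-95% CI):

========== ===============
category   percent error
========== ===============
VeryHigh   100
High        50
Medium      20
Low         10
========== ===============

The parameter file format is flat ``key = value`` text, one line per
field, with dotted keys (``<name>.value``, ``<name>.units``,
``<name>.mode``, ``<name>.category``, ``<name>.sem``, ``<name>.group``,
``<name>.lower``, ``<name>.upper``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import math

__all__ = [
    "CATEGORY_PERCENT_ERROR",
    "ParameterSpec",
    "ParameterSet",
    "assign_sem",
    "default_parameters",
]

#: percent error at the 95% confidence level per default uncertainty category
CATEGORY_PERCENT_ERROR: dict[str, float] = {
    "VeryHigh": 100.0,
    "High": 50.0,
    "Medium": 20.0,
    "Low": 10.0,
}

#: 95% two-sided normal quantile used to convert CI half-widths to SEMs
Z95 = 1.96


@dataclass
class ParameterSpec:
    """One scalar input to the flux equation.

    Parameters
    ----------
    name:
        Identifier used in the parameter file and in Monte Carlo draws.
    mean:
        Central value, in ``units``.
    units:
        Unit string, for documentation and reports.
    mode:
        ``"category"`` (default percent-error class) or ``"empirical"``
        (SEM estimated from sample data).
    category:
        One of ``VeryHigh | High | Medium | Low``; required when
        ``mode == "category"``.
    sem:
        Standard error of the mean; required when ``mode == "empirical"``.
    group:
        Attribution group for uncertainty source analysis.
    lower, upper:
        Physical truncation bounds for sampling (e.g. fractions live in
        [0, 1]); ``None`` leaves that side unbounded.
    """

    name: str
    mean: float
    units: str = ""
    mode: str = "category"
    category: str | None = None
    sem: float | None = None
    group: str = "other"
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("category", "empirical"):
            raise ValueError(f"unknown uncertainty mode {self.mode!r}")
        if self.mode == "category":
            if self.category not in CATEGORY_PERCENT_ERROR:
                raise ValueError(
                    f"parameter {self.name!r}: category mode requires a "
                    f"category in {sorted(CATEGORY_PERCENT_ERROR)}"
                )
        else:
            if self.sem is None:
                raise ValueError(
                    f"parameter {self.name!r}: empirical mode requires an SEM"
                )
            if self.sem < 0:
                raise ValueError(f"parameter {self.name!r}: SEM must be >= 0")
        if not math.isfinite(self.mean):
            raise ValueError(f"parameter {self.name!r}: mean must be finite")

    @property
    def sampling_sem(self) -> float:
        return assign_sem(self)


def assign_sem(spec: ParameterSpec) -> float:
    """Return the SEM that drives Monte Carlo sampling for *spec*.

    Category mode converts the assigned percent error at the 95%
    confidence level into an SEM: ``mean * (percent/100) / 1.96``.
    Empirical mode passes the stated SEM through unchanged.
    """
    if spec.mode == "empirical":
        return float(spec.sem)  # type: ignore[arg-type]
    pct = CATEGORY_PERCENT_ERROR[spec.category]  # type: ignore[index]
    return abs(spec.mean) * (pct / 100.0) / Z95


@dataclass
class ParameterSet:
    """An ordered collection of :class:`ParameterSpec`, keyed by name."""

    specs: dict[str, ParameterSpec] = field(default_factory=dict)

    @classmethod
    def from_specs(cls, specs: Iterable[ParameterSpec]) -> "ParameterSet":
        out = cls()
        for s in specs:
            out.add(s)
        return out

    def add(self, spec: ParameterSpec) -> None:
        if spec.name in self.specs:
            raise ValueError(f"duplicate parameter {spec.name!r}")
        self.specs[spec.name] = spec

    def __getitem__(self, name: str) -> ParameterSpec:
        return self.specs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.specs

    def __iter__(self):
        return iter(self.specs.values())

    def __len__(self) -> int:
        return len(self.specs)

    def names(self) -> list[str]:
        return list(self.specs)

    def means(self) -> dict[str, float]:
        return {s.name: s.mean for s in self}

    def groups(self) -> dict[str, list[str]]:
        """Attribution groups as ``{group: [parameter names]}``."""
        out: dict[str, list[str]] = {}
        for s in self:
            out.setdefault(s.group, []).append(s.name)
        return out

    def with_updates(self, **mean_overrides: float) -> "ParameterSet":
        """New set with some parameter means replaced (specs otherwise kept)."""
        out = ParameterSet()
        for s in self:
            if s.name in mean_overrides:
                out.add(replace(s, mean=mean_overrides[s.name]))
            else:
                out.add(replace(s))
        unknown = set(mean_overrides) - set(self.specs)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        return out

    # -- flat key-value file round trip ---------------------------------

    def write(self, path: str | Path) -> None:
        lines = ["# juriflux parameter file (flat key = value)"]
        for s in self:
            lines.append(f"{s.name}.value = {s.mean!r}")
            lines.append(f"{s.name}.units = {s.units}")
            lines.append(f"{s.name}.mode = {s.mode}")
            if s.category is not None:
                lines.append(f"{s.name}.category = {s.category}")
            if s.sem is not None:
                lines.append(f"{s.name}.sem = {s.sem!r}")
            lines.append(f"{s.name}.group = {s.group}")
            if s.lower is not None:
                lines.append(f"{s.name}.lower = {s.lower!r}")
            if s.upper is not None:
                lines.append(f"{s.name}.upper = {s.upper!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "ParameterSet":
        raw: dict[str, dict[str, str]] = {}
        order: list[str] = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if "." not in key:
                raise ValueError(f"line {lineno}: expected dotted key, got {key!r}")
            name, fieldname = key.rsplit(".", 1)
            if name not in raw:
                raw[name] = {}
                order.append(name)
            raw[name][fieldname] = value
        specs = []
        for name in order:
            f = raw[name]
            specs.append(
                ParameterSpec(
                    name=name,
                    mean=float(f["value"]),
                    units=f.get("units", ""),
                    mode=f.get("mode", "category"),
                    category=f.get("category"),
                    sem=float(f["sem"]) if "sem" in f else None,
                    group=f.get("group", "other"),
                    lower=float(f["lower"]) if "lower" in f else None,
                    upper=float(f["upper"]) if "upper" in f else None,
                )
            )
        return cls.from_specs(specs)


def default_parameters() -> ParameterSet:
    """Default flux-equation parameter set.

    Physical-process parameters carry literature-plausible central values
    for a Bornean moist-forest frontier and default uncertainty
    categories; activity areas and stratum carbon densities are supplied
    at run time (areas as unit-mean scale factors here, densities
    appended per stratum with empirical SEMs).
    """
    frac = dict(lower=0.0, upper=1.0)
    pos = dict(lower=0.0)
    specs = [
        # dead-wood decay
        ParameterSpec("decay_rate", 0.24, "1/yr", category="High",
                      group="decay", **pos),
        # loss-factor composition
        ParameterSpec("root_shoot", 0.37, "fraction of aboveground live C",
                      category="Medium", group="roots", **frac),
        ParameterSpec("necromass_frac", 0.10, "fraction of aboveground live C",
                      category="High", group="necromass", **frac),
        ParameterSpec("burned_frac", 0.60, "fraction of cleared area burned",
                      category="High", group="fire", **frac),
        ParameterSpec("combustion_completeness", 0.50, "fraction of pool",
                      category="High", group="fire", **frac),
        ParameterSpec("charcoal_frac", 0.08, "elemental C fraction of combusted",
                      category="High", group="fire", **frac),
        ParameterSpec("extraction_frac", 0.10,
                      "roundwood fraction of aboveground live C",
                      category="High", group="wood_products", **frac),
        ParameterSpec("product_half_life", 20.0, "yr", category="High",
                      group="wood_products", **pos),
        ParameterSpec("wood_density", 0.60, "Mg/m3", category="Medium",
                      group="other", **pos),
        ParameterSpec("carbon_frac", 0.47, "MgC/Mg biomass", category="Low",
                      group="other", **frac),
        # wetland soils
        ParameterSpec("peat_depth", 200.0, "cm", category="VeryHigh",
                      group="wetland_soil", **pos),
        ParameterSpec("peat_c_density", 0.55, "MgC/ha per cm", category="High",
                      group="wetland_soil", **pos),
        ParameterSpec("peat_drainage_depth", 60.0, "cm", category="High",
                      group="wetland_soil", **pos),
        ParameterSpec("peat_loss_frac", 1.0, "fraction of drained-layer C",
                      category="Low", group="wetland_soil", **frac),
        ParameterSpec("mangrove_top_depth", 30.0, "cm", category="Low",
                      group="wetland_soil", **pos),
        ParameterSpec("mangrove_top_stock", 115.0, "MgC/ha (top layer)",
                      category="High", group="wetland_soil", **pos),
        ParameterSpec("mangrove_deep_stock", 190.0, "MgC/ha (below top layer)",
                      category="High", group="wetland_soil", **pos),
        ParameterSpec("mangrove_top_loss_frac", 0.75, "fraction",
                      category="High", group="wetland_soil", **frac),
        ParameterSpec("mangrove_deep_loss_frac", 0.35, "fraction",
                      category="High", group="wetland_soil", **frac),
        # logging degradation factors
        ParameterSpec("felling_ef", 28.3, "MgC/ha logged", category="High",
                      group="logging", **pos),
        ParameterSpec("skidding_ef", 10.2, "MgC/ha logged", category="High",
                      group="logging", **pos),
        ParameterSpec("logging_product_ef", 3.2, "MgC/ha logged",
                      category="High", group="logging", **pos),
        ParameterSpec("sf_sl", 0.368, "MgC/ha logged", category="High",
                      group="logging", **pos),
        # sequestration rates
        ParameterSpec("sfr_fiber", 9.8, "MgC/ha/yr", category="Medium",
                      group="regrowth_rate", **pos),
        ParameterSpec("sfr_oil_palm", 2.97, "MgC/ha/yr", category="Medium",
                      group="regrowth_rate", **pos),
        ParameterSpec("sfr_native", 3.85, "MgC/ha/yr", category="High",
                      group="regrowth_rate", **pos),
        # activity-area scale factors (unit mean; multiply measured areas)
        ParameterSpec("afd_scale", 1.0, "dimensionless", mode="empirical",
                      sem=0.01, group="forest_loss_area", **pos),
        ParameterSpec("awd_scale", 1.0, "dimensionless", category="Medium",
                      group="wetland_soil", **pos),
        ParameterSpec("ar_scale", 1.0, "dimensionless", category="High",
                      group="regrowth_area", **pos),
        ParameterSpec("asl_scale", 1.0, "dimensionless", category="Medium",
                      group="logging", **pos),
    ]
    return ParameterSet.from_specs(specs)


def stratum_parameters(
    stratum_means: Mapping[object, float],
    stratum_sems: Mapping[object, float],
) -> list[ParameterSpec]:
    """Per-stratum aboveground carbon density parameters (empirical SEMs)."""
    out = []
    for h, mean in stratum_means.items():
        out.append(
            ParameterSpec(
                f"cd_{h}", float(mean), "MgC/ha", mode="empirical",
                sem=float(stratum_sems[h]), group="aboveground_live",
                lower=0.0,
            )
        )
    return out
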