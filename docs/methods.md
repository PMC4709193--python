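# Methods

## Scope and model structure

`juriflux` estimates historic forest carbon fluxes for a sub-national
jurisdiction with the IPCC gain–loss method: annual net flux is gross
carbon stock loss minus gross gain, each the product of activity areas
and emission/sequestration factors over a reference period of `tp`
years (default 10). All arithmetic runs in MgC internally; conversion
to CO₂ uses the molecular-weight ratio 44/12 at reporting only. The
accounting covers harvested wood products, above- and below-ground tree
biomass, and dead organic matter; mineral (oxic) soils are assumed to
have no net carbon flux on conversion, while anoxic wetland soils (peat,
mangrove) emit on forest loss. Illegal logging, fuelwood collection and
escaped fires are out of scope, as are secondary→mature forest
transitions, which play a minimal role in an early frontier landscape.

## Loss factor (committed emissions with decay)

The forest loss factor `LFd_h` expresses within-period emissions per ha
of loss as a proportion of aboveground live carbon `Cd_h`. The
committed on-site dead pool, relative to `Cd_h`, is
`(1 − extraction) + root:shoot + necromass`. Of cleared area a fraction
burns: combusted carbon (combustion completeness × pool) is emitted
immediately except the share converted to charcoal, which is treated as
stored. All non-combusted dead wood decays linearly at `decay_rate`
(default 0.24 yr⁻¹). Clearing happens uniformly across years 1..tp,
each cohort created at the *end* of its clearing year, so the fraction
of a year-`t` cohort emitted within the window is
`min(1, rate · (tp − t))` and the cohort-mean at the default rate over
10 years is 0.74. End-of-year cohort timing is a convention (start- or
mid-year timing is not modelled; the choice shifts each cohort's decay
time by up to one year and is absorbed by the decay-rate uncertainty).
Extracted roundwood enters a wood-product pool decaying first-order
with a 20-year half-life, cohort-averaged the same way.

Note a physically real non-monotonicity at the margins: when charcoal
formation is large and decay is fast, burning can emit *less* within
the window than decay would; at the defaults (charcoal ≤ 0.15,
cohort-mean decay ≤ 0.9) the loss factor is monotone in burning, decay
rate, roots, and necromass, and the property tests assert it on those
physical ranges.

## Wetland soils

Peat: cleared peat is assumed drained (default depth 60 cm, the typical
small-scale agricultural value) and subsequently burned, losing 100% of
the carbon in the drained layer, bounded by actual peat depth. Peat
carbon density defaults to 0.55 MgC/ha per cm of depth. Mangrove:
conversion loses 75% of the top-30-cm stock (default 115 MgC/ha) and
35% of the deeper stock (default 190 MgC/ha). A loss pixel either is or
is not wetland (mask intersection, no sub-pixel fractions).

## Logging degradation

Felling and skidding emissions scale per ha legally logged
(`Asl × EF`); haul-road construction removes canopy entirely and is
charged through the same stratified loss computation as deforestation,
over road-labelled pixels. Roads are segregated mechanically: loss
pixels inside licensed concessions belonging to structures no more than
3 pixels (90 m) wide — operationally, pixels deleted by a binary
opening with a 4×4 square element. This is a deterministic analogue of
a manual digitization rule and is exact for corridors and compact
blocks; diagonal or braided road networks may classify partly as
conversion. Post-logging sequestration uses `SFsl` = 0.368 MgC/ha
logged. Wood products removed from concessions are reported as their
own component line; the default aggregation includes them in gross
logging emissions (configurable, since reporting practice varies on
whether products are a separate "additional" source).

Legal harvest rates come from permit-year government records; with
record coverage below 100% the default treatment scales the observed
annual totals proportionally (`observed ÷ completeness`), with an
`observed_mean` switch to report recorded totals unscaled.

## Benchmark biomass map

Stratum carbon densities are estimated by "stratify and multiply":
footprint-style biomass samples are grouped by candidate strata
(disturbance level × elevation class × substrate group); one-way ANOVA
with Tukey's HSD (α = 0.05) decides which candidates remain distinct.
Non-significant pairs are lumped greedily — the pair with the smallest
absolute mean difference merges first, then the test is recomputed —
until every retained pair differs. Competing stratification systems are
ranked by their ANOVA F statistic. Elevation class edges sit at
100/300/900/1500 m, closed on the left, open on the right (a value
exactly at an edge goes to the upper class). Final per-stratum means
carry SEM = sd/√n with sd the root-mean-square deviation (population
convention; at the sample sizes used, ≥ 80 per stratum, the distinction
from the n−1 convention is negligible). Each forest pixel then receives
its stratum's mean; non-forest pixels carry a declared no-data value.

## Monte Carlo uncertainty

Parameters carry either an empirical SEM or a default category
expressed as percent error at the ±95% CI — Very High 100%, High 50%,
Medium 20%, Low 10% — converted to an SEM by dividing by 1.96. Each
iteration draws every parameter independently from a normal
distribution truncated at zero for non-negative quantities and
additionally at one for fractions; out-of-range draws are redrawn (a
persistent failure after 200 redraw rounds raises, naming the
parameter). Truncation (rather than clipping) avoids probability mass
piling at the bounds; it does skew Very-High-category draws slightly
high, which is why CIs are percentile-based (2.5/97.5) rather than
mean ± 1.96 sd. Activity areas enter the parameter vector as unit-mean
multiplicative scale factors. The default iteration count is 10⁵ —
percentile CIs for the smooth, low-dimensional flux equation are stable
to well under a percent at that size — with more available by flag.

Each parameter draws from its own seeded substream keyed by a digest of
its name, making results bit-reproducible under a fixed seed,
independent of parameter ordering, and — crucially for attribution —
leaving all other parameters' draws unchanged when a group is fixed.

Source attribution fixes each group of parameters (grouped by carbon
pool / flux mechanism) at its means, re-runs the simulation, and takes
the reduction in net-flux CI half-width as that group's contribution,
normalized to sum to 100%. Raw un-normalized reductions are also
reported, since independent groups' reductions need not sum to 100%.
At small iteration counts, groups whose true contribution is below the
percentile estimator's noise floor can report zero. Overall uncertainty
is summarized as the relative CI half-width (half-width as a percent of
the mean estimate); this is the single headline figure, reported
without attempting to reconcile it against alternative summaries such
as the CI expressed relative to a rounded point estimate.

## Synthetic jurisdiction

The generator emulates the input stack of a frontier jurisdiction on a
single equal-area grid (default 140×140 pixels of 30 m; pixel area is
(pixel size)², no projection correction):

- spatial-plan zones in column bands (non-forest 30%, production forest
  55%, protection forest 15%) with permit blocks (oil-palm estates,
  a coal block, a selective-logging concession over 70% of production
  forest, fiber below it);
- 13 biomass strata in row bands (means 32–200 MgC/ha, spaced ≥ 14
  MgC/ha with 10% lognormal footprint noise so the default
  configuration supports a 13-class outcome); peat and mangrove strata
  double as the wetland mask;
- conversion loss at annual fractions of forest area (oil palm 0.5%,
  agriculture 0.5%, fiber 0.2%, mining 0.04%/yr, roughly 1.2%/yr total
  — a fast frontier), with deterministic pixel counts, seeded placement,
  and loss years spread evenly over 1..tp (no trend, matching a
  jurisdiction with no significant annual loss trend);
- eight 2-pixel-wide haul-road corridors plus ≥4-pixel-wide conversion
  blocks inside the concession, exercising the road/conversion
  segregation in both directions;
- a non-annual gain band (0.3%/yr over a 12-year source window,
  annualized to the 10-year reference period);
- 20 logging permits at 1%/yr of concession area and 31.9 m³/ha, with
  57% of permit-years retained as records.

Footprint samples are drawn only from pixels forested at baseline with
no loss before the footprint-era cutoff (year index 9), with mean-
corrected multiplicative lognormal noise (biomass is positive and
right-skewed), so stratum sample means are unbiased. The truth record
is computed from the placed pixel counts and true parameter means
through the same flux arithmetic as the pipeline, and satisfies
net = gross − sequestration exactly.

What passing recovery tests do show: the estimator chain (morphological
road detection, stratified cross-tabulation, footprint-based stratum
means, record scale-up, Monte Carlo coverage) is unbiased and
internally consistent under the generator's assumptions. What they do
not show: robustness to classification error in loss detection, permit
boundary misalignment, spatially structured biomass variation within
strata, or biased footprint placement — real-data failure modes the
generator deliberately does not simulate.

## Parameter defaults

Process parameters not estimable from the synthetic data ship in the
default parameter file with literature-plausible central values for a
Bornean moist-forest frontier and conservative categories: decay rate
0.24 yr⁻¹ (High), root:shoot 0.37 (Medium), necromass fraction 0.10
(High), burned fraction 0.60 / combustion completeness 0.50 / charcoal
fraction 0.08 (High), roundwood extraction 0.10 with 20-yr product
half-life (High), felling/skidding/product logging factors
28.3/10.2/3.2 MgC/ha (High; consistent with published per-ha logging
component fluxes at reported harvest rates), sequestration rates
9.8 (fiber), 2.97 (oil palm), 3.85 (native) MgC/ha/yr, and wetland soil
stocks as above. Forest-loss area carries a 1% empirical SEM (activity
maps are the best-constrained input); regrowth area is High — gain
detection is far weaker than loss detection.

## Regrowth accrual convention

The gain band is not annual, so a regrowth cohort's age is unknown. The
default accrual convention is cohort-mean: each regrowth ha accrues its
type's sequestration rate for `tp/2` years over the period (equivalent
to uniform gain timing). The convention is exposed as `accrual_years`
everywhere it matters; regrowth-area uncertainty (High) dominates the
convention's effect in the Monte Carlo.

## Ledger

The ledger aggregates flux cells by spatial-plan zone × permit ×
disturbance type, sorts by zone then net emissions descending, appends
a totals row, and computes percent-of-net shares. Permit labels win
over zone labels where layers conflict (recorded in the run manifest).
Sequestration within a zone/permit block is allocated to its
disturbance rows proportionally to disturbed area. Internal arithmetic
is full precision; display rounding is 2 decimals for Tg CO₂/yr and 1
for percent.

## Problem sizes

Default test and acceptance runs use a 140×140 (end-to-end replicates:
100×100) grid, 80 (or 40) footprints per stratum, 10³–10⁵ Monte Carlo
iterations depending on the check, 50 replicates for CI-coverage
estimation, and several hundred replicates for stratum-recovery
coverage — sizes at which every stochastic check's sampling noise is
comfortably below its decision margin while the full suite stays
desk-scale.

## Known limitations

- The road rule is a mechanical width criterion, not a reproduction of
  manual digitization; braided networks can split between classes.
- Attribution assumes independent parameters; correlated draws and
  variance-based global sensitivity indices (e.g. Sobol) are not
  implemented.
- The benchmark map is piecewise constant by stratum; no spatially
  continuous biomass model (kriging etc.) is provided.
- Rasters are written as plain single-band TIFFs with grid geometry in
  a sidecar JSON, not georeferenced GeoTIFFs; all geometry is pixel
  arithmetic on one shared grid.
- The stratification validates against the footprint sample itself;
  validation against independent field plots reports CI overlap only,
  with no pass/fail verdict.
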