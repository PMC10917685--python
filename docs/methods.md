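# Methods

This note documents the models implemented in `ecoflux`, the defaults and
units that matter, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Units and data contract

Canonical units are fixed at the data boundary (`ecoflux.community`): body
mass in mg fresh weight per individual, biomass in g fresh weight m⁻²,
density in individuals m⁻², temperature in °C in files (Kelvin internally),
energy flux in mW m⁻². Guild tables are long-format (one row per
plot × guild) with plot metadata keyed by `plot_id`, because body masses and
occupancies are plot-specific measurements. A missing body-mass SD defaults
to 0.5 × mean with a warning: the SD is required by the mass-overlap rule
and half the mean is a typical spread for field length–mass conversions.
Resource preferences are stored as a three-level factor (none / auxiliary /
main); they become numeric only inside reconstruction, which keeps the
omnivory relaxation well-defined.

Where litter and soil extractions of the same guild arrive as separate rows,
`merge_soil_litter_layers` sums biomass and abundance exactly, sets stratum
occupancy to the layer-wise abundance proportions, and pools body-mass
mean/SD by abundance weighting (total variance = within- + between-layer
components; only the pooled mean is contractually fixed, the SD treatment is
this package's choice).

## Food-web reconstruction

For each plot, the raw diet weight of predator *j* on animal prey *i* is

    w_ij = pref_ij · ovl_ij · space_ij · B_i · (1 − p_i),

the product of the preference weight (main = 1, auxiliary = `omnivory`,
none = 0), the body-mass overlap, the spatial overlap, prey biomass and the
protection discount; same-guild links are further multiplied by
`self_predation`. Basal-resource weights use the preference level only —
basal biomass is deliberately not part of the model, which targets
consumption rather than standing stocks. Columns are normalized to diet
shares, shares below `min_diet_fraction` (default 0.01) are pruned in a
single pass and the column renormalized. Single-pass pruning is a
deterministic rule; iterative pruning could cascade and make link counts
ambiguous.

*Mass rule.* Body-mass distributions are treated as normal on the log10
scale with σ = SD/(mean·ln 10) (delta method), floored at 0.1 log10 units to
avoid degenerate spikes. The predator's preferred-prey distribution is its
own distribution shifted down by `ppmr_log10_optimum × hunting_modifier`.
The default optimum of 2 (predator 100× prey) is a literature-scale value
for generalist arthropod predators; guild-level hunting modifiers express
web-building, venom, pack foraging (>1 shifts toward smaller prey, <1
toward larger, negative values model parasitoids attacking hosts larger than
themselves). The overlap statistic is the overlapping coefficient
∫ min(f₁, f₂), computed in closed form from the crossing points of the two
normal densities (the equal-σ case reduces to 2Φ(−|Δμ|/2σ)); it is
symmetric, bounded in [0, 1] and equals 1 only for identical distributions.
The closed form is verified in the tests against numerical quadrature.

*Spatial rule.* Overlap is Σ over the four strata of the pointwise minimum
occupancy. Canopy-foraging birds get full overlap with canopy arthropods:
fogging samples exactly the stratum those birds hunt in.

*Relaxation scalars.* The five sensitivity scalars interpolate linearly
between "rule fully applied" (0) and "rule ignored" (1). The endpoints are
contractual; the interior is unspecified by the rules themselves, and linear
interpolation is the least-structured interior that is monotone and
endpoint-exact.

A consumer with positive biomass whose permissible weights are all zero is
an error, not a silent drop — it signals inconsistent traits (e.g. a
specialist predator with no spatially co-occurring prey). Zero-biomass
guilds are excluded from the web.

## Energetics

Per-individual metabolic rates use group-specific regressions configured in
`data/metabolic_coeffs.yaml`: ectotherms via `ln I = ln x0 + a ln M −
E/(kT)` (I in J h⁻¹, M in mg, k = 8.617333×10⁻⁵ eV K⁻¹), endothermic birds
via a temperature-independent power law. Rates are converted to mW and
multiplied by density. The shipped coefficients follow the published general
invertebrate Arrhenius regression and a bird basal-metabolism allometry;
they are deliberately a config file, not code, so users can substitute the
exact coefficients of their preferred sources.

Assimilation efficiencies are diet-specific: basal resources from a lookup
(plants 0.21, litter 0.18, SOM 0.13, bacteria 0.96, fungi 0.36), animal prey
by default from prey nitrogen content, `e = clip(0.594·ln %N − 0.454, 0.01,
1)`. The equation coefficients are a calibration fixed once so that low-N
detritivore prey (≈6 % N, millipede-like) land near 0.61 and high-N prey
(≈11 % N, centipedes, earthworms) near 0.97 — the documented range for
animal food. A pure lookup mode (per guild id with an `animal` fallback) is
available when measured efficiencies exist.

The steady state — assimilated intake = metabolism + predation losses —
gives the linear system `(diag(ē) − P) G = X` with `P[j,k] = W_jk` the
consumer-block of the diet matrix. It is solved directly; the tests verify
the solution against an independent damped fixed-point iteration on ≥200
random feasible webs, the closed form `G = X/e` for single-resource
consumers and per-consumer balance to 1e−8 relative. Per-link efficiencies
enter through the diet-weighted mean `ē_j`, the standard way diet-specific
efficiencies appear in this formulation. A negative ingestion or singular
system raises an "energetically infeasible web" error rather than a warning:
the steady-state assumption is the analysis contract, and an infeasible web
means the topology or efficiencies are inconsistent. Faeces production is
Σ F_ij (1 − e_i), optionally restricted to a recipient subset.

## Indicators

Compartment membership is by major group: birds are always aboveground and
earthworms always belowground regardless of foraging strata, so compartments
partition consumers and aboveground + belowground totals equal whole-web
totals exactly. The trophic-hierarchy denominator counts *all* flux leaving
basal nodes — omnivores contribute to both numerator and denominator —
matching the definition of basal-resource consumption. The bacteria:fungi
and faeces:SOM ratios are computed only for whole-web and belowground
scopes. Ratios with zero denominator are reported as missing values (never
infinities) and excluded from means with an explicit excluded count; real
communities always define them, but synthetic edge cases need a
deterministic policy. Summaries are descriptive (mean, SD with n−1
denominator, n, percent change vs rainforest); inferential statistics are
out of scope.

## Sensitivity analyses

Sweeps are one-at-a-time over the default grid 0, 0.1, …, 1 — per-parameter
effects are the quantity of interest and a factorial grid would conflate
them. Plots that become infeasible at a grid value are recorded as missing
with the reason and the sweep continues.

The undersampling correction assumes fogging samples uniformly from 5 m up
to a maximum-efficiency height `h_max` (scanned 14–22 m) and misses
everything above. Per plot, assessed span = Σ max(0, min(h, h_max) − 5),
unassessed = Σ max(0, h − h_max), and canopy-arthropod biomass and density
are multiplied by (assessed + unassessed)/assessed. The total-over-assessed
form (not unassessed/assessed) is forced by the floor: stands entirely below
`h_max` must give exactly 1. Birds are not corrected — the bias is specific
to fogging. When individual tree heights are unavailable, a single
percentile height may be passed as a pseudo-tree.

## Synthetic communities

The generator emulates the *design* of a 32-site land-use survey: 4 systems
× 8 plots, balanced over two regions; 62 guilds per plot with trait values
spanning detritivores, microbivores, herbivores and predators across birds,
canopy arthropods, soil arthropods and earthworms; strict canopy/soil
stratum separation for specialist arthropods; earthworms feeding on soil
organic matter (main) with litter and bacteria auxiliary. Template
biomasses are invented calibration anchored to field magnitudes (rainforest
belowground ≈ 10–12 g m⁻² vs aboveground ≈ 1 g m⁻²; earthworms ≈ 10 % of
rainforest flux) — they are a plausible stand-in, not ground truth.
Per-system effect multipliers encode the emulated land-use contrasts
(earthworm biomass ×6–8 and canopy arthropod biomass ×0.2–0.55 in
plantations); plot-to-plot variation is lognormal (σ = 0.6) because field
biomasses are positive and right-skewed with SDs of the order of the means;
body masses are jittered ±10 %. Tree heights are normal per system with
90th percentiles near 29.5/21.0/17.0/12.7 m. PRNG streams are spawned per
(system, plot) from one master `SeedSequence`, so adding plots never
perturbs existing ones.

What passing tests show, and what they do not: the generator reproduces the
*qualitative* structure the pipeline is meant to detect (belowground flux
dominance, earthworm takeover, aboveground collapse, falling faeces:SOM
ratio in plantations, and a null configuration with no systematic system
differences). It does not emulate species-level diversity, seasonal
turnover, spatial autocorrelation within plots, or measurement error in
body-mass regressions — so green tests certify the pipeline's correctness
and sensitivity, not field-data conclusions.

## Problem sizes and determinism

Default analyses run 32 plots × 62 guilds; a full five-parameter sweep is
5 × 11 × 32 plot-level re-runs. All stages are deterministic given (config,
seed); the acceptance script derives every quantity from one seeded
landscape at run time. The test suite's stochastic checks use fixed seeds
(hypothesis runs derandomized) and its permutation-based null check uses 10
seeds × 499 permutations at α = 0.01.

## Known limitations

- Reconstruction constants (PPMR optimum, hunting modifiers, efficiency
  equation coefficients, metabolic regressions) are editable defaults;
  reproducing any *specific* published survey requires substituting that
  survey's constants via the YAML configs and its data via
  `ecoflux.benchmark`.
- The steady-state assumption ignores dynamics and seasonality; results are
  comparative snapshots.
- Diet shares are inferred, not observed; the sensitivity sweeps quantify,
  but cannot remove, that structural uncertainty.
- The trophic-hierarchy and link-count indicators depend on the pruning
  threshold; comparisons should hold `min_diet_fraction` fixed.
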