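# Methods

This note documents the models inside `grazecast`, their assumptions,
the parameter defaults that matter, and the limits of what the synthetic
components can and cannot show about real farms.

## Pipeline shape and cadence

The analysis runs on a monthly time step — the soil-carbon model and the
carbon accounting are monthly, so daily weather input is aggregated on
read (rain and pan evaporation summed; monthly mean temperature is the
mean of daily (tmax + tmin)/2). One scenario simulates 26 calendar
years; the first 6 are discarded as model spin-up and every reported
quantity (mean net emissions, production, profit inputs) is computed on
the remaining 20-year window. All randomness flows from a single
integer seed: the synthetic weather, the variability inflation and the
Monte Carlo price draws each use deterministic offsets of it, so a full
run is bit-reproducible.

## Climate futures

Future climates are built by the delta-change method: per calendar
month, an additive temperature shift and multiplicative rain and
evaporation factors, supplied as a 12-row table per horizon. Horizons
carry fixed atmospheric CO₂: 350 ppm (historical), 450 ppm (2030),
530 ppm (2050).

Interannual rainfall variability can be inflated: each year receives
one standard-normal draw z, and every month's rain in that year is
multiplied by max(0, 1 + inflation·z). This is a deliberately simple
stand-in for stochastic extreme-event generation — it widens the
distribution of annual totals without changing the mean (truncation at
zero is negligible at the inflations used) but does not create realistic
multi-year droughts, heatwaves or within-year storm restructuring. It
is not presented as a reimplementation of any published extreme-event
method.

The shipped factor sets (uniform +0.9 °C, rain ×0.97, evap ×1.03,
inflation 0.05 for 2030; +1.9 °C, ×0.93, ×1.07, 0.10 for 2050) are
package defaults representative of a high-emissions pathway in a cool
temperate region; real studies should supply their own monthly tables.

The synthetic historical generator draws annual rain totals from a
truncated normal with configurable mean and standard deviation
(defaults: 807 ± 139 mm for the high-rainfall beef site, 499 ± 103 mm
for the drier sheep site), spreads them over months by a climatological
fraction profile, and adds small seeded noise to the monthly temperature
profile. It reproduces annual totals and seasonality; it does not
reproduce daily structure, autocorrelation between years, or joint
rain–temperature anomalies.

## Synthetic farm production

The generator stands in for a daily pasture/livestock simulator and is
reduced to the quantities the downstream analysis actually consumes:
monthly pasture growth, herd intake, purchased supplement, product
output, nitrogen flows and carbon returns.

Pasture growth is multiplicative-limitation:

    growth = max_rate · f_T(tmean) · f_W(rain, evap) · f_CO2(co2) · days

* f_T is a piecewise-linear hat over cardinal temperatures (defaults
  3 / 15 / 22 / 35 °C).
* f_W = min(1, rain / (w_sens · pan_evap)) with w_sens 0.8 (beef) and
  0.58 (sheep; the drier site's swards extract relatively more of the
  rainfall, and the lower value keeps the fixture's feed balance in a
  realistic range).
* f_CO2 = 1 + β·ln(co2/350) with β = 0.06, chosen so 530 ppm raises
  annual growth by ≈2.5% — a modest CO₂ fertilisation response.

Livestock are classes of (head count, per-head intake demand, product,
per-head product mass, N excretion). The monthly feed balance closes
exactly: intake = min(demand, available pasture) + supplement, with
availability = growth × area × utilisation (0.55 beef, 0.60 sheep). The
feed-conversion-efficiency multiplier divides intake demand at fixed
product output, which is how FCE gains translate into enteric-methane
cuts downstream. Product output is head count × per-head mass ×
a product multiplier; there is no reproduction calendar, liveweight
trajectory or pasture-quality feedback.

Carbon returns to soil per grazed hectare:

* dung C = intake × (1 − digestibility) × C fraction
  (digestibility 0.70, C fraction of dry matter 0.40),
* litter C = ungrazed residue × 0.35 × C fraction (only part of
  standing residue detaches and reaches the soil litter pool within the
  year),
* root C = shoot production × 0.45 × C fraction, split 80/20 between
  the 0–30 cm and 30–100 cm layers.

These defaults put total topsoil C inputs near 4 Mg C/ha/yr on the
productive beef fixture — the right order for temperate improved
pasture — and were fixed once on that realism argument.

The two fixture farms are calibrated to the printed magnitudes of two
reference enterprises (a 569 ha beef herd around 367 breeding cows; a
3170 ha sheep operation around 24,750 head in wool and prime-lamb
flocks plus a small cattle herd) without claiming to reproduce them:
stocking structure, prices and costs are package stand-ins.

## Soil organic carbon

A five-pool RothC 26.3 implementation, monthly, per depth layer.

* Pools: DPM, RPM, BIO, HUM active; IOM inert and exactly constant.
* Rate constants (yr⁻¹, DPM/RPM/BIO/HUM): topsoil 10 / 0.17 / 0.66 /
  0.02; deep layer 0.33 / 0.01 / 0.02 / 0.00. The zero deep-HUM rate is
  treated literally: deep humus only accumulates.
* Initial pools: DPM = 1% and BIO = 2.2% of initial SOC (the microbial
  pool merges the 2% + 0.2% fast/slow sub-pools into the single BIO
  pool standard RothC carries), IOM fixed, and the remainder split
  RPM:HUM 1:2 by default (a config parameter — the split is regionally
  calibrated in field studies and shipped here as a documented
  default). If IOM crowds out the active stock entirely (SOC = IOM) the
  fast pools shrink proportionally to zero rather than erroring.
* Rate modifiers: temperature a = 47.91/(1 + exp(106.06/(t + 18.27)))
  (domain t > −18.27 °C); moisture b declining linearly from 1.0 to 0.2
  once the accumulated topsoil moisture deficit passes 0.444 of its
  maximum −(20 + 1.3·clay − 0.01·clay²)·depth/23, with the deficit
  accumulating as rain − 0.75·pan evaporation clamped to [max, 0]; soil
  cover c = 0.6 (vegetated) or 1.0 (bare). Pastures are treated as
  permanently covered.
* Monthly decomposition Δ = P·(1 − e^(−k·a·b·c/12)); the decomposed
  share splits CO₂ : (BIO + HUM) as x : 1 with
  x = 1.67·(1.85 + 1.60·e^(−0.0786·clay)), and the retained share 46%
  BIO / 54% HUM. Fresh plant C enters DPM/RPM by a 1.44 DPM:RPM ratio;
  dung C enters with the standard more-humified farmyard-manure split
  (49/49/2 DPM/RPM/HUM), the rationale being that excreted C is already
  partially stabilised.
* Carbon is conserved exactly each step: Δ(pools) = inputs − respired
  CO₂ (property-tested to 1e-9 relative).

The monthly update is linear in the pool vector, so the constant-forcing
steady state has a closed form, p* = (I − A)⁻¹u, used as an independent
oracle against long simulations. A pool with zero effective rate and
nonzero inflow (deep HUM under any active forcing) has no fixed point
and is reported as non-convergent rather than as a number. Note the
relaxation time of topsoil HUM under typical pasture modifiers exceeds
400 years; oracle comparisons at a few hundred simulated years therefore
use warm/wet/bare forcing where every pool relaxes quickly.

Warming raises the temperature modifier and therefore respiration, so
projected horizons accrue less soil carbon than the historical climate —
the mechanism, not its published magnitude, is what the implementation
guarantees.

## Tree carbon

Stand growth is a single-parameter saturating exponential,
stock(age) = perturbation × max_stock × (1 − e^(−rate·age)), with
strictly diminishing annual increments — removals peak early and decay
toward zero as stands mature, which is what makes tree-based insetting
a time-limited instrument. Two species profiles ship as package
defaults calibrated to typical temperate planting ranges (plantation
blue gum 180 Mg C/ha at maturity, rate 0.09 yr⁻¹; mixed environmental
planting 110 Mg C/ha, 0.06 yr⁻¹); they are illustrative, not the output
of any yield model. Annual removals convert increments at 44/12 Mg CO₂
per Mg C. No harvesting, fire loss or grazing beneath trees is
modelled, and soil beneath plantings is deliberately excluded so tree
and pasture soil carbon are never double-counted.

The multiplicative perturbation is bounded to the ±20% sensitivity
envelope cumulatively: each `perturb` step may use any factor whose
cumulative product stays inside [0.8, 1.2], so a −20% excursion can be
undone by a +25% relative correction.

## GHG inventory

Annual, by source: enteric CH₄ (per-class dry-matter intake × emission
factor × (1 − inhibition)), manure CH₄ (excreted dry matter × a low
temperate-grazing factor), direct and indirect N₂O from applied and
excreted N (leaching and volatilisation streams; N₂O-N → N₂O exactly
44/28), energy CO₂ (diesel, electricity) and embedded CO₂e (fertiliser
manufacture, purchased feed). Default emission factors (cattle
0.0204 / sheep 0.0188 kg CH₄ per kg DMI; fertiliser EF 0.01 and excreta
EF 0.004 kg N₂O-N/kg N; leach fraction 0.24 with EF 0.011; volatilised
fraction 0.15 with EF 0.01; diesel 2.70 kg CO₂e/L; electricity 0.20
kg CO₂e/kWh; fertiliser 3.0 kg CO₂e/kg N; feed 0.30 kg CO₂e/kg DM) are
configuration values indicative of national-inventory practice, not
asserted constants. N₂O from legume biological N fixation is excluded.

Gases convert at GWP₁₀₀ 28 (CH₄) and 265 (N₂O). The sequestration
ledger stores positive magnitudes and nets by explicit subtraction; a
year of soil-carbon loss enters with negative sign and adds to net
emissions symmetrically. Net-zero holds when the 20-year mean of annual
net emissions is within ±1 Mg CO₂e/yr of zero (the tolerance exists for
floating-point means; the definition itself is equality). Emissions
intensity allocates net emissions between meat and wool by protein mass
(defaults 0.18 and 0.60), which makes the intensity invariant to
splitting a product into sub-lots.

## Interventions

An intervention is a declarative set of (path, mode, value)
modifications on the scenario parameter tree plus economic deltas,
optional plantings and an optional enteric-inhibition fraction;
bundles are ordered stacks. Multiplicative modifications commute;
set-mode ones are order-sensitive and repeated sets are recorded as
provenance warnings (conflicting sets inside one stack are an error
unless explicitly allowed). Enteric inhibitions from several stacked
interventions compose conservatively as the maximum single fraction —
a feed additive and a vaccine act on the same rumen methanogenesis, so
independence is not assumed — with the independent-action form
1 − Π(1 − fᵢ) available behind a flag; either form is capped at 1.

Catalog items whose biophysical detail lives in a proprietary pasture
simulator are reduced to explicit config-visible levers and are
stand-ins by construction: calendar/selling-date optimisation (+2%
product), soil fertility (+3% growth), deeper-rooting species (+10%
deep-root fraction), lucerne renovation (+8% growth, legume fraction
0.35, 1.5× deep-root fraction), biochar (enteric CH₄ ×0.90, +5%
liveweight on the beef farm), land purchase (extra grazeable area at
60% productivity plus 15% more head), wind lease and vineyard (pure
economic deltas). Intervention costs, capex and adoptability scores
(ordinal 1–5, pass-through attributes) are likewise package stand-ins.

## Economics

Operating profit is EBIT: product income plus diversification income,
minus purchased feed (supplement × feed price), overheads, per-head
variable costs, intervention cost deltas and straight-line depreciation
of intervention capex over a 10-year default life. Price risk uses a
Gaussian copula: correlated standard normals (Cholesky) mapped through
each commodity's marginal inverse CDF; marginal families are normal,
lognormal and beta-PERT (shape 4). The shipped price model (meat PERT
2200/3000/4200 $/Mg liveweight; wool lognormal around 13,000 $/Mg
greasy; feed PERT 250/350/550 $/Mg; meat–wool correlation 0.6) is a
config stand-in. The default Monte Carlo is 10,000 iterations, seeded.

The hybrid carbon policy applies to the 20-year mean net position
(matching the net-zero definition, not year-by-year): tax = 80 ·
max(0, net), credit = 28 · max(0, −net) — mutually exclusive,
continuous at zero, and deliberately asymmetric so that reaching
net-zero is rewarded more strongly than overshooting it. Marginal
abatement cost curves use pre-carbon-price profits: cost per Mg =
(baseline profit − intervention profit) / (baseline net − intervention
net), sorted ascending; zero-abatement and emission-increasing
interventions are listed separately rather than plotted.

## Impact score and sensitivity

Each compared scenario receives production, profit and emissions
components normalised by the maximum over the compared set — scores are
set-relative by design (a comparison panel's worth of scenarios), so a
score is meaningless outside its set. The emissions component is
inverse-coded (1 − net/max-net) and clamped to [0, 1] so net-negative
scenarios cannot push the total past 3; negative profits floor at 0 and
are flagged. The total is the unweighted sum, 0–3; 3 is attained
exactly when a scenario is best-in-set on production and profit with
zero (or negative) mean net emissions. Ternary coordinates divide the
components by their sum.

The sensitivity engine re-runs the full pipeline over an enteric
inhibition × tree-perturbation grid (envelopes 0.10–0.99 and ±0.2,
overridable), sharing the seed across grid points so differences are
pure parameter effects. Net emissions are strictly decreasing along the
inhibition axis, and exactly linear along the tree axis because
removals scale multiplicatively with the perturbation.

## Problem sizes and numerical choices

Default runs simulate 26 years (312 months) per scenario and 10,000
Monte Carlo iterations; a full two-horizon, ten-bundle comparison
completes in well under a minute. Net-zero tree areas are found by
bisection on planted area (bounds 0–2000 ha, ≤60 iterations) against
the 20-year mean net. Steady-state solves report non-convergent pools
rather than pseudo-values; rate-modifier evaluation raises on
temperatures at or below −18.27 °C; degenerate inputs (zero head
counts, empty stand lists, zero-variance price marginals) yield zeros,
not errors.

## What passing tests do and do not show

The test suite establishes internal correctness (carbon conservation,
closed-form agreement, exact policy arithmetic, determinism) and the
qualitative mechanisms of the analysis (warming reduces soil accrual,
methane inhibition dominates abatement, tree removals diminish with
stand age, the hybrid policy rewards net-zero). Because the production
generator, emission factors, prices and costs are synthetic stand-ins,
absolute dollar values and emission totals are illustrative of a
plausible temperate grazing enterprise — they are not predictions for
any real farm, and agreement with any published farm-level totals is
neither claimed nor tested.
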