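# Methods

## Model structure

The model is a deterministic activity simulator wrapped in a Monte Carlo
over per-unit CO₂e rates.

**Baselines and historical variation.** Each (county, activity) record is
either an annual series (timber harvest volumes by ownership, 2003–2017;
post-wildfire replanting areas) or a single annual rate. Series records use
the series mean as the baseline rate *b* and the sample coefficient of
variation CV = s/x̄ (sample, n−1 denominator; the conservative, conventional
choice). Single-rate records use a conservative default CV of 0.10. The
historical variation HV = b·min(CV, 1) is capped at the baseline rate so a
volatile series can never imply more implementable growth than there is
activity. A zero-mean series degrades to the default CV on a zero rate
(HV = 0), which propagates to an all-zero trajectory.

**Scenarios.** Implementation enrolls new activity each year in proportion
to HV. With ramp fraction r (default 0.1), growth share g, and post-decade
share p, the year-t increment is `min(t·r,1)·g·HV` for t ≤ 1/r and `p·g·HV`
afterwards; cumulative enrollment is clipped at `cap_fraction·max_resource`,
with the capping-year increment trimmed so the additionality identity
`E(t) = E(t−1) + Δ(t)` holds exactly. Enrollment is interpreted as
cumulative stock — deferred stands stay deferred, restored hectares stay
restored — which is the only reading under which age-dependent cohort
pathways are coherent.

Registry defaults per scenario:

| scenario | general | extended rotations |
|---|---|---|
| limited | g=1, p=1 | p=0.5 (post-decade increments at half HV) |
| moderate | g=0.5, p=1 | g by ownership: private 0.30, state 0.15, federal/other 0.75 |
| ambitious | g=1, p=1 | caps by ownership: private 0.40, state 0.32, others 1.0 (west); all 1.0 east |

The timber values are the published feasibility figures. The *general*
moderate share of 0.5 is this package's own default: the per-pathway
moderate/ambitious growth coefficients were elicited from stakeholders and
published only in supplementary material, so the registry encodes a neutral
midpoint and treats every field as overridable through
`scenario_params.csv`. A consequence (shared with the source assessment) is
that the limited scenario can exceed the moderate one; with defaults, the
ambitious and limited rules coincide for non-timber pathways except for
resource caps. Counties flagged `timber_excluded` (majority high/extreme
wildfire-risk forestland) contribute zero extended-rotation HV.

**Flux.** Rates ρ are signed MT CO₂e per activity-unit per year, negative
for removals, and may differ west/east of the Cascade crest with a
statewide fallback (no interpolation; a fallback is only warned about when
the key is regionalized elsewhere). Units are carried as labels and a rate
combines with a baseline only when labels match. Stock-mode flux is
`E(t)·ρ`; pulse mode (`Δ(t)·ρ`, committed-emissions accounting) is
implemented and selectable per activity but the default registry keeps
avoided-conversion pathways in stock mode, consistent with reductions that
grow smoothly to 2050. Cohort pathways (replanting, added sequestration on
deferred private stands) weight each enrollment-year tranche by a step
age-profile — no interpolation between tabulated ages, terminal value held
past the table — stored as multipliers so a sampled rate scales the whole
profile. Extended-rotation net rates are the signed sum of five
components (harvest volume, below-ground biomass, unused mill residues,
commercial fuel, short-lived ≤20-yr wood products), computed per region by
`flux.timber_net_rate`; the pipeline consumes the resulting net rates.

**Monte Carlo.** 1,000 iterations by default. Each iteration draws one rate
per (activity, region) from an untruncated Normal(mean, sd) — truncation
would bias the mean; sign-flipped draws are retained — held constant across
years and counties sharing the rate, treating rate uncertainty as epistemic
rather than interannual. A per-year redraw variant (`per_year_draws`)
changes interval widths, not medians. Trajectories are rate-independent and
computed once; the cube is the outer product of unit series and draws. The
master seed spawns an independent substream per scenario
(`numpy.random.SeedSequence`), making runs bitwise-reproducible.

**Summaries.** Per-iteration sums over the requested grouping (statewide
total, pathway, county, county×pathway) are formed first; the median and
5th/95th percentiles are then taken over iterations with linear
interpolation between order statistics, and converted MT → MMT exactly
once. `p05`/`p95` are numeric quantiles: for net reductions (negative
values) `p05` is the most negative bound. The total is therefore never the
sum of pathway medians, and the test suite includes a fixture where the two
demonstrably differ. Display rounding (medians 2 dp, shares whole percent,
percent-of-goal 1 dp) applies to display columns only; machine outputs keep
full precision.

## Synthetic data

The generator emulates the structure of the statewide input tables: 39
counties (odd FIPS-style ids), roughly half west of the crest, a
configurable fraction of eastern counties flagged timber-excluded; timber
harvest series per ownership with exact target CVs; replanting series;
single-rate baselines elsewhere; finite resource caps (some binding, e.g.
untreated-cropland caps at 2–30× baseline); regionalized rates with
sd = 10 % of |mean| by default. Pathway-specific derivations are exercised
in generation: the tidal restoration rate is `0.00215 × lost wetland ha`
for unmapped Puget Sound counties capped at the lost area, grassland
conversion allocates a statewide rate (15,681 acres over a five-year
reference window) proportionally to county grassland shares, nutrient
management caps at 40 % of cropland, and one cover-crop census year is
reconstructed through the missing-county disaggregation rule.

Series are constructed, not sampled: a standardized template is scaled so
sample mean and CV hit their targets exactly, making the CV round-trip
exact. Statewide magnitudes are scaled so the ambitious statewide total
lands in single-digit MMT CO₂e yr⁻¹, which makes MT-vs-MMT unit mistakes
conspicuous. County values are synthetic throughout; passing tests
demonstrate correctness of the machinery on realistic structure, not
agreement with any real county's numbers. Features of real data the
generator does not emulate: spatial autocorrelation between neighboring
counties, correlated uncertainty across pathways, trends (as opposed to
variation) in baseline series, and the empirical ownership mix of
individual counties.

Two independent oracles back the tests: a closed form for flat-profile
stock activities (`min(Σ increments, cap) × rate`, e.g. 26.5·HV enrolled by
year 31 under the uncapped limited-general rule) and a plain per-cohort
loop for age-profile activities. Neither shares code with the pipeline.
With sd = 0 the pipeline reproduces them to ≤ 1e−9 relative error; with
sd > 0, medians fall within 3 Monte Carlo standard errors of the oracle in
≥ 95 % of randomized cases (20 six-county bundles at 400 iterations — sizes
chosen to keep the default suite quick while leaving >1,500 comparisons).

## Numerical and design choices

- Quantiles: linear interpolation (`numpy.quantile` default), fixed.
- Median standard error in recovery checks: asymptotic 1.2533·σ/√n.
- Cap handling trims the capping-year increment rather than rescaling the
  whole path, preserving additivity and the capped-at marker.
- Degenerate inputs: HV = 0 (constant series) yields exactly zero
  enrollment and flux under every scenario; empty result sets write
  header-only files; an empty iteration cube refuses to summarize.
- The `ncspath` CLI (`synth`, `run`, `report`) is a thin wrapper over the
  library; YAML config holds paths, iteration count, seed, and the goal
  baseline (default 99.57 MMT CO₂e yr⁻¹, the 2018 statewide inventory).

## Limitations

- The original statewide assessment's county-level inputs are not
  redistributed; end-to-end reproduction of its published Monte Carlo
  totals requires transcribing those tables into the documented schema
  (see `tests/data/original_inputs/` in the test suite). The shipped
  reference table carries only the published statewide medians/intervals
  used for arithmetic-consistency checks; the grassland row is omitted
  because its median is published only as a bound (<−0.01).
- No leakage, economic feasibility, or cross-pathway interaction
  modelling; agriculture sub-activities are additive and independent.
- No uncertainty on baseline activity or trajectory parameters — only
  per-unit rates vary, matching the source design.
- GIS preprocessing (forest-change intersection, fire-perimeter filtering,
  land-use overlays) is upstream of this artifact; county geography is
  attribute-only.
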