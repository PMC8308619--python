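# ncspath

County-level scenario model for the emissions-reduction potential of
**natural climate solutions** (NCS): land-management, restoration, and
avoided-conversion activities that increase carbon sequestration or avoid
greenhouse-gas emissions. The package targets analysts studying a
Washington-style statewide decarbonization question — how much can NCS
contribute toward a net-zero goal, and in which counties — but all inputs
are ordinary CSV tables, so any county system with the same structure works.

## Model

Eight pathways are tracked (several with sub-activities): extended timber
harvest rotations (four ownership classes plus added sequestration on
deferred private even-aged stands), cropland agriculture (cover crops,
no-till, nutrient management), avoided conversion of forest (to urban and
rural development), avoided sagebrush-steppe and grassland conversion,
riparian reforestation, post-wildfire replanting on federal land, and tidal
wetland restoration.

For each (county *c*, activity *a*) the baseline annual rate *b* and its
historical variation are derived from the input record:

```
HV = b · min(CV, 1),     CV = s/x̄ of the annual series (or 0.10 default)
```

Three implementation scenarios (limited / moderate / ambitious) enroll new
activity each year relative to HV, with ramp fraction r = 0.1, growth share
g, post-decade share p, and a resource cap:

```
Δ(t) = min(t·r, 1) · g · HV          t = 1..10
Δ(t) = p · g · HV                    t = 11..31
E(t) = min( Σ_{s≤t} Δ(s),  cap_fraction · max_resource )
```

Enrollment is additional and cumulative (year 1 = 2020, year 31 = 2050).
Annual flux is `E(t) · ρ` for stock-mode activities, where ρ is the signed
per-unit CO₂e rate (negative = removal/avoided emission); cohort pathways
weight each enrollment-year tranche by an age profile. Uncertainty in ρ is
propagated by Monte Carlo: 1,000 draws per (activity, region) from
N(mean, sd), held fixed over years within an iteration. Summaries report
the median and the 5th/95th percentiles of the per-iteration *aggregated*
totals (never sums of per-pathway medians), in MMT CO₂e yr⁻¹.

## Worked example

```
ncspath synth --seed 5 --outdir demo          # synthetic 39-county bundle
ncspath run --config demo/config.yaml --outdir demo/out --scenario ambitious
```

where `demo/config.yaml` contains

```yaml
n_iter: 1000
seed: 1
goal_baseline_mmt: 99.57
```

`demo/out/table2.csv` then holds the final-year statewide medians. On the
default synthetic bundle generated with seed 1 the run prints a statewide
ambitious total of **−7.49 MMT CO₂e yr⁻¹** (5th/95th interval wider on the
negative side), i.e. 7.5 % of a 99.57 MMT CO₂e annual emissions baseline;
the limited and moderate scenarios land at −5.44 and −3.02 MMT CO₂e yr⁻¹.
Negative values are net reductions. The moderate scenario can fall below
the limited one: its growth coefficients throttle enrollment harder than
the limited rule's post-decade plateau, which is a property of the scenario
definitions, not a bug. `demo/out/shares.csv`, `clusters.csv` and
`intensity.csv` break the total down by pathway share, top-county clusters
covering half of each pathway's reductions, and per-hectare intensity.

Programmatic use mirrors the CLI:

```python
from ncspath import generate_bundle, run_simulation, summarize
from ncspath.synthetic_data import SynthConfig, load_bundle

paths, truth = generate_bundle(SynthConfig(), seed=1, outdir="demo")
bundle = load_bundle(paths)
cube = run_simulation(bundle, "ambitious", n_iter=1000, seed=1)
print(summarize(cube, "total").query("year == 31"))
```

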