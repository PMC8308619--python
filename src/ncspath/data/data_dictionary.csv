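file,column,type,description
counties.csv,county_id,int,Unique integer county identifier
counties.csv,name,str,County name
counties.csv,region,enum(west;east),Side of the Cascade crest
counties.csv,area_ha,float,County land area in hectares (> 0)
counties.csv,timber_excluded,bool,True where >50% of forestland is at high/extreme wildfire risk; extended rotations switched off
baselines.csv,county_id,int,County the record belongs to
baselines.csv,pathway,enum,One of the eight registered pathways
baselines.csv,sub_activity,str,Sub-activity (may be empty)
baselines.csv,ownership,enum(private;state;federal;other;na),Land ownership class
baselines.csv,year,int,Calendar year of a series observation; empty for a single constant annual rate
baselines.csv,amount,float,Annual activity amount (>= 0) in the row's units
baselines.csv,units,enum(ha_per_yr;volume_per_yr;kgN_per_yr),Activity units label
baselines.csv,max_resource,float,Total implementable stock in activity units; empty = unbounded
rates.csv,pathway,enum,Activity key component
rates.csv,sub_activity,str,Activity key component
rates.csv,ownership,enum,Activity key component
rates.csv,region,enum(west;east;statewide),Region the rate applies to; statewide is the fallback
rates.csv,mean_rate,float,Signed MT CO2e per activity unit per yr (negative = removal/avoided emission)
rates.csv,sd_rate,float,Standard deviation of the rate (>= 0); sampled in the Monte Carlo
rates.csv,units,enum,Must match the baseline units it combines with
rates.csv,age_profile,str,Optional profile_id into age_profiles.csv for cohort pathways
age_profiles.csv,profile_id,str,Profile identifier
age_profiles.csv,age,int,Stand age (years; strictly increasing from 1)
age_profiles.csv,multiplier,float,Rate multiplier applied at that age (step function; terminal value held)
scenario_params.csv,scenario,enum(limited;moderate;ambitious),Scenario the override applies to
scenario_params.csv,pathway,enum,Activity key component
scenario_params.csv,sub_activity,str,Activity key component
scenario_params.csv,ownership,enum,Activity key component
scenario_params.csv,ramp_fraction,float,Per-year ramp increment as fraction of allowed growth (default 0.1)
scenario_params.csv,growth_share,float,Fraction of historical variation allowed as growth (0..1)
scenario_params.csv,post_decade_share,float,Multiplier on the post-decade increment (0..1)
scenario_params.csv,cap_fraction,float,Max fraction of max_resource enrollable (0..1)
scenario_params.csv,flux_mode,enum(stock;pulse),Whether flux accrues on enrolled stock or on the year's new enrollment
results_long.csv,geography,str,County id or statewide
results_long.csv,pathway,str,Pathway or total
results_long.csv,sub_activity,str,Sub-activity (empty at pathway level)
results_long.csv,scenario,enum,Scenario
results_long.csv,year,int,Simulation year 1..31
results_long.csv,calendar_year,int,2020 + year - 1
results_long.csv,median,float,Median annual flux over iterations (MMT CO2e per yr; signed)
results_long.csv,p05,float,Numeric 5th percentile over iterations (most negative bound for reductions)
results_long.csv,p95,float,Numeric 95th percentile over iterations
results_long.csv,cumulative_median,float,Median over iterations of the running cumulative flux (MMT CO2e)
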