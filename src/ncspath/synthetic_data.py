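"""Synthetic input bundles with known ground truth.

The generator emulates the structure of the statewide input tables: 39
counties split east/west of the Cascade crest, timber harvest series
2003-2017 per ownership, post-wildfire replanting series, single-rate
baselines with the conservative 10% default variation for the remaining
pathways, finite resource caps, and signed per-unit CO2e rates with
standard deviations.  Magnitudes are scaled so the statewide ambitious
total lands in single-digit MMT CO2e per yr, which makes MT-vs-MMT
mistakes conspicuous.  County *values* are synthetic; only the structure
and rough magnitudes are realistic.

Series construction is noise-free: a standardized template is scaled so
the sample mean and sample CV hit their targets exactly, which makes the
CV round-trip through ``baseline.coefficient_of_variation`` exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import baseline as bl
from .flux import TimberRateComponents, timber_net_rate
from .model_io import InputBundle, ValidationError, read_inputs
from .registry import (
    ACTIVITY_REGISTRY,
    AGRICULTURE,
    FOREST_CONVERSION,
    TIMBER,
    ActivityKey,
)
from .scenario_engine import params_for_county, scenario_defaults

__all__ = [
    "SynthConfig",
    "SyntheticTruth",
    "generate_series",
    "generate_bundle",
    "load_bundle",
    "analytic_oracle",
    "expected_final_flux",
    "cohort_expected_flux",
]

TIMBER_YEARS = tuple(range(2003, 2018))
REPLANT_YEARS = tuple(range(2008, 2018))

# Regional five-component timber rates, MT CO2e per volume unit per yr.
TIMBER_COMPONENT_RATES = {
    "west": TimberRateComponents("west", -0.100, -0.030, -0.020, -0.010, 0.010),
    "east": TimberRateComponents("east", -0.070, -0.020, -0.015, -0.005, 0.010),
}


@dataclass(frozen=True)
class SynthConfig:
    """Generator knobs; the defaults are the study conditions being emulated."""

    n_counties: int = 39
    pathways: tuple[str, ...] = tuple(sorted({k.pathway for k in ACTIVITY_REGISTRY}))
    timber_excluded_fraction: float = 0.25  # of eastern counties
    rate_rel_sd: float = 0.10  # sd as a fraction of |mean rate|
    with_age_profiles: bool = True  # cohort profiles for replanting/added seq.
    n_years_series: int = len(TIMBER_YEARS)

    def __post_init__(self) -> None:
        if self.n_counties < 2:
            raise ValidationError("need at least 2 counties (one per region)")
        unknown = set(self.pathways) - {k.pathway for k in ACTIVITY_REGISTRY}
        if unknown:
            raise ValidationError(f"unknown pathway(s) in config: {sorted(unknown)}")
        if not 0 <= self.timber_excluded_fraction <= 1:
            raise ValidationError("timber_excluded_fraction must be in [0, 1]")
        if self.rate_rel_sd < 0:
            raise ValidationError("rate_rel_sd must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground-truth parameters per (county, activity), plus the generator seed.

    ``table`` columns: county_id, region, pathway, sub_activity, ownership,
    baseline_rate, cv, hv, mean_rate, sd_rate, max_resource, flux_mode,
    flat_profile (False where an age profile makes the closed form invalid).
    """

    table: pd.DataFrame
    seed: int
    config: SynthConfig
    age_profiles: dict[str, tuple[tuple[int, float], ...]] = field(default_factory=dict)


def generate_series(
    mean: float, target_cv: float, n_years: int, seed: int = 0
) -> np.ndarray:
    """Annual series whose sample mean and sample CV are exact.

    A symmetric standardized template (shuffled for realism; order does not
    affect mean or CV) is scaled by ``mean * target_cv``.  Raises when the
    requested CV would force a negative value.
    """
    if mean <= 0:
        raise ValidationError("mean must be > 0")
    if target_cv < 0:
        raise ValidationError("target_cv must be >= 0")
    if n_years < 2:
        raise ValidationError("n_years must be >= 2")
    if target_cv == 0:
        return np.full(n_years, float(mean))
    z = np.linspace(-1.0, 1.0, n_years)
    z = z / z.std(ddof=1)  # sample mean 0, sample sd 1 exactly
    if target_cv * np.abs(z).max() >= 1.0:
        raise ValidationError(
            f"target_cv {target_cv} too large for nonnegative values at n={n_years}"
        )
    rng = np.random.default_rng(seed)
    rng.shuffle(z)
    return mean * (1.0 + target_cv * z)


def _county_table(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_counties
    n_west = (n + 1) // 2
    rows = []
    east_ids = []
    for i in range(n):
        cid = 2 * i + 1  # odd FIPS-style county ids
        region = "west" if i < n_west else "east"
        if region == "east":
            east_ids.append(cid)
        rows.append(
            {
                "county_id": cid,
                "name": f"County{cid:02d}",
                "region": region,
                "area_ha": float(np.round(rng.uniform(80_000, 600_000), 1)),
                "timber_excluded": False,
            }
        )
    df = pd.DataFrame(rows)
    n_excl = int(round(config.timber_excluded_fraction * len(east_ids)))
    for cid in east_ids[:n_excl]:
        df.loc[df["county_id"] == cid, "timber_excluded"] = True
    return df


# Statewide scale targets (activity units per yr) used to apportion
# baselines across counties.
_TIMBER_STATEWIDE = {"private": 5e6, "state": 1.5e6, "federal": 1e6, "other": 0.5e6}
_SCALE = {
    "cover_crops": 1.0e5,
    "no_till": 1.5e5,
    "nutrient_mgmt": 3.0e7,  # kg N per yr
    "forest_to_urban": 3_000.0,
    "forest_to_rural": 5_000.0,
    "sagebrush": 2_000.0,
    "riparian": 1_200.0,
    "replanting": 1_500.0,
    "clearcut_private": 2.0e4,  # ha/yr entering even-aged deferral
}
_LOST_TIDAL_STATEWIDE_HA = 47_000.0

_MEAN_RATES = {  # MT CO2e per activity unit per yr (statewide unless split)
    ("agriculture", "cover_crops"): -1.5,
    ("agriculture", "no_till"): -1.2,
    ("agriculture", "nutrient_mgmt"): -0.003,
    ("avoided_forest_conversion", "forest_to_urban"): {"west": -80.0, "east": -50.0},
    ("avoided_forest_conversion", "forest_to_rural"): {"west": -40.0, "east": -25.0},
    ("avoided_sagebrush_conversion", ""): -5.0,
    ("avoided_grassland_conversion", ""): -1.0,
    ("riparian_restoration", ""): -8.0,
    ("replanting_after_wildfire", ""): {"west": -5.0, "east": -3.0},
    ("tidal_wetland_restoration", ""): -8.0,
    ("extended_rotation", "added_sequestration"): {"west": -2.5, "east": -1.5},
}

_REPLANT_PROFILE = ((1, 0.2), (5, 0.6), (10, 1.0), (20, 1.2))
_ADDED_SEQ_PROFILE = ((1, 1.0), (10, 0.8), (20, 0.6))


def _shares(rng: np.random.Generator, n: int) -> np.ndarray:
    w = rng.uniform(0.2, 1.8, size=n)
    return w / w.sum()


def generate_bundle(
    config: SynthConfig | None = None,
    seed: int = 0,
    outdir: str | Path = ".",
) -> tuple[dict[str, Path], SyntheticTruth]:
    """Write a complete, schema-valid input bundle and return its ground truth.

    Files written: counties.csv, baselines.csv, rates.csv,
    scenario_params.csv (header-only: registry defaults apply), and
    age_profiles.csv.  Identical (config, seed) give identical files.
    """
    config = config or SynthConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(97,)))

    counties = _county_table(config, rng)
    west = counties.loc[counties["region"] == "west", "county_id"].tolist()
    east = counties.loc[counties["region"] == "east", "county_id"].tolist()
    all_ids = counties["county_id"].tolist()

    baseline_rows: list[dict] = []
    truth_rows: list[dict] = []
    region_of = dict(zip(counties["county_id"], counties["region"]))

    def add_activity(
        cid: int,
        key: ActivityKey,
        series: np.ndarray,
        years: tuple[int, ...] | None,
        units: str,
        max_resource: float,
        mean_rate: float,
        sd_rate: float,
        cv_truth: float,
        baseline_rate: float,
        flat_profile: bool,
    ) -> None:
        if years is None:
            baseline_rows.append(
                {
                    "county_id": cid,
                    "pathway": key.pathway,
                    "sub_activity": key.sub_activity,
                    "ownership": key.ownership,
                    "year": "",
                    "amount": float(series[0]),
                    "units": units,
                    "max_resource": max_resource if math.isfinite(max_resource) else "",
                }
            )
        else:
            for y, a in zip(years, series):
                baseline_rows.append(
                    {
                        "county_id": cid,
                        "pathway": key.pathway,
                        "sub_activity": key.sub_activity,
                        "ownership": key.ownership,
                        "year": y,
                        "amount": float(a),
                        "units": units,
                        "max_resource": max_resource if math.isfinite(max_resource) else "",
                    }
                )
        hv = bl.historical_variation(
            key, cid, baseline_rate, cv_truth if years is not None else None
        )
        excluded = (
            key.pathway == TIMBER
            and bool(
                counties.loc[counties["county_id"] == cid, "timber_excluded"].iloc[0]
            )
        )
        truth_rows.append(
            {
                "county_id": cid,
                "region": region_of[cid],
                "pathway": key.pathway,
                "sub_activity": key.sub_activity,
                "ownership": key.ownership,
                "baseline_rate": baseline_rate,
                "cv": hv.cv,
                "hv": 0.0 if excluded else hv.hv,
                "mean_rate": mean_rate,
                "sd_rate": sd_rate,
                "max_resource": max_resource,
                "flux_mode": "stock",
                "flat_profile": flat_profile,
            }
        )

    rate_rows: list[dict] = []
    profile_rows: list[dict] = []
    age_profiles: dict[str, tuple[tuple[int, float], ...]] = {}

    def add_rate(
        key: ActivityKey, region: str, mean: float, units: str, profile_id: str = ""
    ) -> float:
        sd = config.rate_rel_sd * abs(mean)
        rate_rows.append(
            {
                "pathway": key.pathway,
                "sub_activity": key.sub_activity,
                "ownership": key.ownership,
                "region": region,
                "mean_rate": mean,
                "sd_rate": sd,
                "units": units,
                "age_profile": profile_id,
            }
        )
        return sd

    def register_profile(pid: str, profile: tuple[tuple[int, float], ...]) -> str:
        if not config.with_age_profiles:
            return ""
        if pid not in age_profiles:
            age_profiles[pid] = profile
            for a, m in profile:
                profile_rows.append({"profile_id": pid, "age": a, "multiplier": m})
        return pid

    def regional_mean(entry, region: str) -> float:
        return entry[region] if isinstance(entry, dict) else float(entry)

    # --- extended timber harvest rotations -------------------------------
    if TIMBER in config.pathways:
        net_rates = {r: timber_net_rate(c) for r, c in TIMBER_COMPONENT_RATES.items()}
        sds = {}
        for own in ("private", "state", "federal", "other"):
            key = ActivityKey(TIMBER, "harvest", own)
            for region in ("west", "east"):
                sds[(own, region)] = add_rate(
                    key, region, net_rates[region], "volume_per_yr"
                )
        for own, statewide in _TIMBER_STATEWIDE.items():
            key = ActivityKey(TIMBER, "harvest", own)
            shares = _shares(rng, len(all_ids))
            for cid, share in zip(all_ids, shares):
                mean_vol = statewide * share
                cv = float(rng.uniform(0.12, 0.35))
                series = generate_series(
                    mean_vol, cv, config.n_years_series, seed=int(rng.integers(2**31))
                )
                region = region_of[cid]
                add_activity(
                    cid, key, series, TIMBER_YEARS, "volume_per_yr",
                    max_resource=40.0 * mean_vol,
                    mean_rate=net_rates[region],
                    sd_rate=sds[(own, region)],
                    cv_truth=cv, baseline_rate=mean_vol, flat_profile=True,
                )
        # added sequestration on deferred private even-aged stands
        key = ActivityKey(TIMBER, "added_sequestration", "private")
        pid = register_profile("added_seq_delta", _ADDED_SEQ_PROFILE)
        as_sds = {
            region: add_rate(
                key, region,
                regional_mean(_MEAN_RATES[(TIMBER, "added_sequestration")], region),
                "ha_per_yr", pid,
            )
            for region in ("west", "east")
        }
        shares = _shares(rng, len(all_ids))
        for cid, share in zip(all_ids, shares):
            b = _SCALE["clearcut_private"] * share
            region = region_of[cid]
            add_activity(
                cid, key, np.array([b]), None, "ha_per_yr",
                max_resource=40.0 * b,
                mean_rate=regional_mean(_MEAN_RATES[(TIMBER, "added_sequestration")], region),
                sd_rate=as_sds[region],
                cv_truth=bl.DEFAULT_CV, baseline_rate=b,
                flat_profile=not config.with_age_profiles,
            )

    # --- agriculture ------------------------------------------------------
    if AGRICULTURE in config.pathways:
        ag_ids = east + west[-4:]  # cropland concentrated east of the crest
        for sub, scale_name, units in (
            ("cover_crops", "cover_crops", "ha_per_yr"),
            ("no_till", "no_till", "ha_per_yr"),
            ("nutrient_mgmt", "nutrient_mgmt", "kgN_per_yr"),
        ):
            key = ActivityKey(AGRICULTURE, sub)
            mean = _MEAN_RATES[(AGRICULTURE, sub)]
            sd = add_rate(key, "statewide", mean, units)
            statewide = _SCALE[scale_name]
            shares = _shares(rng, len(ag_ids))
            if sub == "cover_crops":
                # emulate a census year with two unreported counties, filled
                # from the statewide total and the other census year
                full = dict(zip(ag_ids, statewide * shares))
                missing = ag_ids[-2:]
                reported = {c: v for c, v in full.items() if c not in missing}
                other_year = {c: v * float(rng.uniform(0.8, 1.2)) for c, v in full.items()}
                filled = bl.disaggregate_missing_counties(
                    statewide, reported, other_year
                )
                alloc = filled
            else:
                alloc = dict(zip(ag_ids, statewide * shares))
            for cid, b in alloc.items():
                if sub == "nutrient_mgmt":
                    cropland_ha = b / 100.0  # ~100 kg N applied per ha
                    max_res = bl.nutrient_max_area(cropland_ha) * 120.0 * 10.0
                else:
                    max_res = b * float(rng.uniform(2.0, 30.0))
                add_activity(
                    cid, key, np.array([b]), None, units,
                    max_resource=max_res, mean_rate=mean, sd_rate=sd,
                    cv_truth=bl.DEFAULT_CV, baseline_rate=b, flat_profile=True,
                )

    # --- avoided forest conversion ---------------------------------------
    if FOREST_CONVERSION in config.pathways:
        conv_ids = west + east[:4]  # development pressure mostly west
        for sub in ("forest_to_urban", "forest_to_rural"):
            key = ActivityKey(FOREST_CONVERSION, sub)
            entry = _MEAN_RATES[(FOREST_CONVERSION, sub)]
            sds = {r: add_rate(key, r, regional_mean(entry, r), "ha_per_yr")
                   for r in ("west", "east")}
            shares = _shares(rng, len(conv_ids))
            for cid, share in zip(conv_ids, shares):
                b = _SCALE[sub] * share
                region = region_of[cid]
                add_activity(
                    cid, key, np.array([b]), None, "ha_per_yr",
                    max_resource=b * 60.0,
                    mean_rate=regional_mean(entry, region), sd_rate=sds[region],
                    cv_truth=bl.DEFAULT_CV, baseline_rate=b, flat_profile=True,
                )

    # --- avoided sagebrush-steppe conversion (east only) ------------------
    if "avoided_sagebrush_conversion" in config.pathways and east:
        key = ActivityKey("avoided_sagebrush_conversion")
        mean = _MEAN_RATES[("avoided_sagebrush_conversion", "")]
        sd = add_rate(key, "east", mean, "ha_per_yr")
        shares = _shares(rng, len(east))
        for cid, share in zip(east, shares):
            b = _SCALE["sagebrush"] * share
            add_activity(
                cid, key, np.array([b]), None, "ha_per_yr",
                max_resource=b * 50.0, mean_rate=mean, sd_rate=sd,
                cv_truth=bl.DEFAULT_CV, baseline_rate=b, flat_profile=True,
            )

    # --- avoided grassland conversion (proportional allocation, east) -----
    if "avoided_grassland_conversion" in config.pathways and east:
        key = ActivityKey("avoided_grassland_conversion")
        mean = _MEAN_RATES[("avoided_grassland_conversion", "")]
        sd = add_rate(key, "statewide", mean, "ha_per_yr")
        # 15,681 acres converted over the 2008-2012 reference window
        statewide_rate = 15_681 / 2.4711 / 5.0  # acres -> ha, per yr
        shares = dict(zip(east, _shares(rng, len(east))))
        for cid, b in bl.grassland_county_baseline(statewide_rate, shares).items():
            add_activity(
                cid, key, np.array([b]), None, "ha_per_yr",
                max_resource=b * 50.0, mean_rate=mean, sd_rate=sd,
                cv_truth=bl.DEFAULT_CV, baseline_rate=b, flat_profile=True,
            )

    # --- riparian reforestation -------------------------------------------
    if "riparian_restoration" in config.pathways:
        key = ActivityKey("riparian_restoration")
        mean = _MEAN_RATES[("riparian_restoration", "")]
        sd = add_rate(key, "statewide", mean, "ha_per_yr")
        shares = _shares(rng, len(all_ids))
        for cid, share in zip(all_ids, shares):
            b = _SCALE["riparian"] * share
            add_activity(
                cid, key, np.array([b]), None, "ha_per_yr",
                max_resource=b * 40.0, mean_rate=mean, sd_rate=sd,
                cv_truth=bl.DEFAULT_CV, baseline_rate=b, flat_profile=True,
            )

    # --- post-wildfire replanting on federal land --------------------------
    if "replanting_after_wildfire" in config.pathways:
        key = ActivityKey("replanting_after_wildfire", "", "federal")
        pid = register_profile("replant_growth", _REPLANT_PROFILE)
        entry = _MEAN_RATES[("replanting_after_wildfire", "")]
        sds = {r: add_rate(key, r, regional_mean(entry, r), "ha_per_yr", pid)
               for r in ("west", "east")}
        replant_ids = east + west[:3]
        shares = _shares(rng, len(replant_ids))
        for cid, share in zip(replant_ids, shares):
            mean_ha = _SCALE["replanting"] * share
            cv = float(rng.uniform(0.2, 0.5))
            series = generate_series(
                mean_ha, cv, len(REPLANT_YEARS), seed=int(rng.integers(2**31))
            )
            region = region_of[cid]
            add_activity(
                cid, key, series, REPLANT_YEARS, "ha_per_yr",
                max_resource=mean_ha * 60.0,
                mean_rate=regional_mean(entry, region), sd_rate=sds[region],
                cv_truth=cv, baseline_rate=mean_ha,
                flat_profile=not config.with_age_profiles,
            )

    # --- tidal wetland restoration (coastal/west) ---------------------------
    if "tidal_wetland_restoration" in config.pathways:
        key = ActivityKey("tidal_wetland_restoration")
        mean = _MEAN_RATES[("tidal_wetland_restoration", "")]
        sd = add_rate(key, "west", mean, "ha_per_yr")
        tidal_ids = west[: max(3, len(west) * 2 // 3)]
        shares = _shares(rng, len(tidal_ids))
        for i, (cid, share) in enumerate(zip(tidal_ids, shares)):
            lost_ha = _LOST_TIDAL_STATEWIDE_HA * share
            mapped = lost_ha * float(rng.uniform(0.001, 0.004)) if i % 3 == 0 else None
            in_ps = i % 3 != 2  # a few coastal counties outside Puget Sound
            rate, max_res = bl.tidal_baseline(lost_ha, mapped, in_ps)
            add_activity(
                cid, key, np.array([rate]), None, "ha_per_yr",
                max_resource=max_res, mean_rate=mean, sd_rate=sd,
                cv_truth=bl.DEFAULT_CV, baseline_rate=rate, flat_profile=True,
            )

    # --- write files --------------------------------------------------------
    paths = {
        "counties": outdir / "counties.csv",
        "baselines": outdir / "baselines.csv",
        "rates": outdir / "rates.csv",
        "scenario_params": outdir / "scenario_params.csv",
        "age_profiles": outdir / "age_profiles.csv",
    }
    counties.to_csv(paths["counties"], index=False)
    pd.DataFrame(baseline_rows).to_csv(paths["baselines"], index=False)
    pd.DataFrame(rate_rows).to_csv(paths["rates"], index=False)
    pd.DataFrame(
        columns=[
            "scenario", "pathway", "sub_activity", "ownership", "ramp_fraction",
            "growth_share", "post_decade_share", "cap_fraction", "flux_mode",
        ]
    ).to_csv(paths["scenario_params"], index=False)
    pd.DataFrame(
        profile_rows, columns=["profile_id", "age", "multiplier"]
    ).to_csv(paths["age_profiles"], index=False)

    truth = SyntheticTruth(
        table=pd.DataFrame(truth_rows),
        seed=seed,
        config=config,
        age_profiles=age_profiles,
    )
    return paths, truth


def load_bundle(paths: dict[str, Path]) -> InputBundle:
    """Convenience: read a generated bundle back through the validating loader."""
    return read_inputs(
        paths["counties"],
        paths["baselines"],
        paths["rates"],
        paths["scenario_params"],
        paths["age_profiles"],
    )


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def _cum_increments(params, hv: float, n_years: int = 31) -> float:
    ramp_years = round(1.0 / params.ramp_fraction)
    ramp_sum = sum(
        min(t * params.ramp_fraction, 1.0) for t in range(1, min(ramp_years, n_years) + 1)
    )
    post_years = max(n_years - ramp_years, 0)
    return params.growth_share * hv * (ramp_sum + params.post_decade_share * post_years)


def analytic_oracle(
    truth: SyntheticTruth, scenario: str, n_years: int = 31
) -> pd.DataFrame:
    """Closed-form deterministic final-year flux per (county, activity).

    Valid for stock-mode activities with flat (or absent) age profiles:
    final flux = min(cumulative increments, cap_fraction x max_resource) x
    mean rate.  Rows carrying a non-flat profile are unsupported here — use
    :func:`cohort_expected_flux` for those.

    Returns columns: county_id, pathway, sub_activity, ownership,
    expected_final_flux_mt, plus a statewide ``total`` row appended.
    """
    if not truth.table["flat_profile"].all():
        raise ValidationError(
            "analytic oracle supports flat profiles only; use cohort_expected_flux"
        )
    return expected_final_flux(truth, scenario, n_years)


def expected_final_flux(
    truth: SyntheticTruth, scenario: str, n_years: int = 31
) -> pd.DataFrame:
    """Independent expected deterministic final-year flux per (county, activity).

    Flat-profile stock activities use the closed form
    ``min(cumulative increments, cap) x mean rate``; cohort activities go
    through the plain-loop :func:`cohort_expected_flux`.  Neither path
    shares code with the flux pipeline.
    """
    registry = scenario_defaults()
    rows = []
    for r in truth.table.itertuples():
        key = ActivityKey(r.pathway, r.sub_activity, r.ownership)
        params = params_for_county(registry[(scenario, key)], r.region)
        cap = params.cap_fraction * r.max_resource
        if r.flat_profile:
            cum = _cum_increments(params, r.hv, n_years)
            flux = min(cum, cap) * r.mean_rate
        else:
            ramp_years = round(1.0 / params.ramp_fraction)
            raw = [
                (
                    min(t * params.ramp_fraction, 1.0)
                    if t <= ramp_years
                    else params.post_decade_share
                )
                * params.growth_share
                * r.hv
                for t in range(1, n_years + 1)
            ]
            increments, total = [], 0.0
            for inc in raw:  # trim at the resource cap
                inc = min(inc, max(cap - total, 0.0))
                increments.append(inc)
                total += inc
            profile_id = (
                "replant_growth"
                if r.pathway == "replanting_after_wildfire"
                else "added_seq_delta"
            )
            profile = list(truth.age_profiles[profile_id])
            flux = cohort_expected_flux(increments, profile, r.mean_rate, n_years)
        rows.append(
            {
                "county_id": r.county_id,
                "pathway": r.pathway,
                "sub_activity": r.sub_activity,
                "ownership": r.ownership,
                "expected_final_flux_mt": flux,
            }
        )
    df = pd.DataFrame(rows)
    total = pd.DataFrame(
        [
            {
                "county_id": -1,
                "pathway": "total",
                "sub_activity": "",
                "ownership": "na",
                "expected_final_flux_mt": df["expected_final_flux_mt"].sum(),
            }
        ]
    )
    return pd.concat([df, total], ignore_index=True)


def cohort_expected_flux(
    increments: list[float],
    profile: list[tuple[int, float]],
    rate: float,
    year: int,
) -> float:
    """Brute-force cohort oracle: plain per-cohort loop, no vectorization.

    ``profile`` entries are (age, multiplier) steps; the multiplier for an
    age is the last entry at or below it, held at the terminal value past
    the table.  Flux in ``year`` (1-based) sums amount x multiplier x rate
    over all cohorts enrolled by then.
    """
    ages = [a for a, _ in profile]
    vals = [v for _, v in profile]

    def mult(age: int) -> float:
        m = vals[0]
        for a, v in zip(ages, vals):
            if a <= age:
                m = v
        return m

    flux = 0.0
    for j, amount in enumerate(increments[:year], start=1):
        age = year - j + 1
        flux += amount * mult(age) * rate
    return flux
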