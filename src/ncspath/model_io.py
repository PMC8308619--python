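"""Domain types and strict CSV I/O for the county-level NCS model.

All tabular inputs and outputs are UTF-8, comma-delimited CSV with ``.``
decimals.  Fluxes are signed throughout: negative values are net removals or
avoided emissions, positive values are net emissions.  The simulation spans
31 years; year 1 maps to calendar 2020 and year 31 to 2050.

Input files
-----------
counties.csv          county_id, name, region, area_ha, timber_excluded
baselines.csv         county_id, pathway, sub_activity, ownership, year,
                      amount, units, max_resource   (long format; one row per
                      series year, or a single row with empty year for a
                      constant annual rate)
rates.csv             pathway, sub_activity, ownership, region, mean_rate,
                      sd_rate, units, age_profile
age_profiles.csv      profile_id, age, multiplier
scenario_params.csv   scenario, pathway, sub_activity, ownership,
                      ramp_fraction, growth_share, post_decade_share,
                      cap_fraction, flux_mode   (overrides; may be empty)

A machine-readable data dictionary for these schemas ships with the package
(``ncspath/data/data_dictionary.csv``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .registry import (
    ACTIVITY_REGISTRY,
    UNITS,
    ActivityKey,
    RegistryError,
    validate_key,
)

logger = logging.getLogger(__name__)

N_YEARS = 31
START_CALENDAR_YEAR = 2020  # simulation year 1

REGIONS = ("west", "east")
RATE_REGIONS = ("west", "east", "statewide")
SCENARIOS = ("limited", "moderate", "ambitious")


class SchemaError(ValueError):
    """An input file does not match its documented schema."""


class ValidationError(ValueError):
    """A value violates a domain invariant."""


class UnresolvedKeyError(ValueError):
    """A baseline activity has no matching rate or scenario parameters."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountyRecord:
    """One county: integer id, name, side of the Cascade crest, land area.

    ``timber_excluded`` marks counties where more than half the forestland
    carries high or extreme wildfire risk; the extended-rotation pathway is
    switched off there.
    """

    county_id: int
    name: str
    region: str
    area_ha: float
    timber_excluded: bool = False

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(
                f"county {self.name!r}: region must be one of {REGIONS}, "
                f"got {self.region!r}"
            )
        if not self.area_ha > 0:
            raise ValidationError(f"county {self.name!r}: area_ha must be > 0")


@dataclass(frozen=True)
class BaselineRecord:
    """Baseline activity in one county: an annual series or a single rate.

    ``series`` is an ordered tuple of (year, amount); a length-1 series with
    year 0 denotes a constant annual rate with no usable interannual record.
    ``max_resource`` is the total implementable stock in activity units
    (e.g. lost tidal wetland hectares); ``inf`` means unbounded.
    """

    county_id: int
    key: ActivityKey
    series: tuple[tuple[int, float], ...]
    units: str
    max_resource: float = math.inf

    def __post_init__(self) -> None:
        validate_key(self.key)
        if self.units not in UNITS:
            raise ValidationError(f"unknown units {self.units!r}")
        years = [y for y, _ in self.series]
        if years != sorted(set(years)):
            raise ValidationError(
                f"{self.key.label()} county {self.county_id}: series years "
                "must be strictly increasing"
            )
        if any(a < 0 for _, a in self.series):
            raise ValidationError(
                f"{self.key.label()} county {self.county_id}: negative activity amount"
            )
        if self.max_resource < 0:
            raise ValidationError("max_resource must be >= 0")

    @property
    def amounts(self) -> list[float]:
        return [a for _, a in self.series]


@dataclass(frozen=True)
class RateSpec:
    """Per-unit CO2e flux rate (MT CO2e per activity-unit per yr) with uncertainty.

    Negative means net removal / avoided emission.  ``age_profile`` is an
    ordered tuple of (stand age, rate multiplier) for cohort pathways; the
    sampled rate scales the whole profile.
    """

    key: ActivityKey
    region: str
    mean_rate: float
    sd_rate: float
    units: str
    age_profile: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        validate_key(self.key)
        if self.region not in RATE_REGIONS:
            raise ValidationError(f"rate region must be one of {RATE_REGIONS}")
        if self.sd_rate < 0:
            raise ValidationError(
                f"{self.key.label()} ({self.region}): sd_rate must be >= 0"
            )
        if self.units not in UNITS:
            raise ValidationError(f"unknown units {self.units!r}")
        if self.age_profile:
            ages = [a for a, _ in self.age_profile]
            if ages[0] != 1 or ages != sorted(set(ages)):
                raise ValidationError(
                    f"{self.key.label()}: age_profile ages must strictly "
                    "increase starting at 1"
                )


@dataclass(frozen=True)
class ScenarioParams:
    """Ramp/plateau/cap rules for one (scenario, activity).

    Implementation enrolls new activity each year in proportion to the
    historical variation (HV):

    * years 1-10: increment = min(t * ramp_fraction, 1) * growth_share * HV
    * years 11-31: increment = post_decade_share * growth_share * HV
    * cumulative enrollment capped at cap_fraction * max_resource
    """

    scenario: str
    key: ActivityKey
    ramp_fraction: float = 0.1
    growth_share: float = 1.0
    post_decade_share: float = 1.0
    cap_fraction: float = 1.0
    flux_mode: str = "stock"

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValidationError(f"unknown scenario {self.scenario!r}")
        validate_key(self.key)
        if not 0 < self.ramp_fraction <= 1:
            raise ValidationError("ramp_fraction must be in (0, 1]")
        for name in ("growth_share", "post_decade_share", "cap_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.flux_mode not in ("stock", "pulse"):
            raise ValidationError("flux_mode must be 'stock' or 'pulse'")


@dataclass(frozen=True)
class ResultRecord:
    """One summarized result row (MMT CO2e per yr, signed)."""

    geography: str  # county_id as string, or "statewide"
    pathway: str  # pathway name or "total"
    sub_activity: str
    scenario: str
    year: int
    median: float
    p05: float
    p95: float
    cumulative_median: float

    def __post_init__(self) -> None:
        if not 1 <= self.year <= N_YEARS:
            raise ValidationError(f"year must be in [1, {N_YEARS}]")


# ---------------------------------------------------------------------------
# Input bundle
# ---------------------------------------------------------------------------


@dataclass
class InputBundle:
    """Validated model inputs with referential closure.

    Every baseline key resolves to a rate (county region, falling back to
    statewide) and to scenario parameters for all three scenarios.
    """

    counties: dict[int, CountyRecord]
    baselines: list[BaselineRecord]
    rates: dict[tuple[ActivityKey, str], RateSpec]
    scenario_params: dict[tuple[str, ActivityKey], ScenarioParams]
    age_profiles: dict[str, tuple[tuple[int, float], ...]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def rate_for(self, county_id: int, key: ActivityKey) -> RateSpec:
        """Resolve the flux rate for an activity in a county.

        Lookup order: county region, then statewide.  No interpolation.
        """
        region = self.counties[county_id].region
        for reg in (region, "statewide"):
            spec = self.rates.get((key, reg))
            if spec is not None:
                return spec
        raise UnresolvedKeyError(
            f"no rate for {key.label()!r} in region {region!r} or statewide"
        )

    def params_for(self, scenario: str, key: ActivityKey) -> ScenarioParams:
        try:
            return self.scenario_params[(scenario, key)]
        except KeyError:
            raise UnresolvedKeyError(
                f"no scenario parameters for ({scenario}, {key.label()})"
            ) from None


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_COUNTY_COLS = ["county_id", "name", "region", "area_ha", "timber_excluded"]
_BASELINE_COLS = [
    "county_id",
    "pathway",
    "sub_activity",
    "ownership",
    "year",
    "amount",
    "units",
    "max_resource",
]
_RATE_COLS = [
    "pathway",
    "sub_activity",
    "ownership",
    "region",
    "mean_rate",
    "sd_rate",
    "units",
    "age_profile",
]
_PROFILE_COLS = ["profile_id", "age", "multiplier"]
_SCENARIO_COLS = [
    "scenario",
    "pathway",
    "sub_activity",
    "ownership",
    "ramp_fraction",
    "growth_share",
    "post_decade_share",
    "cap_fraction",
    "flux_mode",
]
RESULT_COLS = [
    "geography",
    "pathway",
    "sub_activity",
    "scenario",
    "year",
    "calendar_year",
    "median",
    "p05",
    "p95",
    "cumulative_median",
]


def _read_csv(path: str | Path, required: list[str], name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{name} file not found: {path}")
    df = pd.read_csv(path, dtype={"sub_activity": str, "ownership": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} ({path.name}): missing column(s) {missing}")
    return df


def _key_from_row(row: pd.Series) -> ActivityKey:
    sub = row.get("sub_activity", "")
    own = row.get("ownership", "na")
    sub = "" if pd.isna(sub) else str(sub)
    own = "na" if (pd.isna(own) or own == "") else str(own)
    return ActivityKey(str(row["pathway"]), sub, own)


def read_counties(path: str | Path) -> dict[int, CountyRecord]:
    df = _read_csv(path, _COUNTY_COLS, "counties")
    counties: dict[int, CountyRecord] = {}
    for _, row in df.iterrows():
        cid = int(row["county_id"])
        if cid in counties:
            raise ValidationError(f"duplicate county_id {cid}")
        counties[cid] = CountyRecord(
            county_id=cid,
            name=str(row["name"]),
            region=str(row["region"]),
            area_ha=float(row["area_ha"]),
            timber_excluded=bool(row["timber_excluded"]),
        )
    return counties


def read_baselines(path: str | Path) -> list[BaselineRecord]:
    df = _read_csv(path, _BASELINE_COLS, "baselines")
    records: list[BaselineRecord] = []
    group_cols = ["county_id", "pathway", "sub_activity", "ownership"]
    df = df.copy()
    df["sub_activity"] = df["sub_activity"].fillna("")
    df["ownership"] = df["ownership"].fillna("na").replace("", "na")
    for (cid, _pw, _sub, _own), grp in df.groupby(group_cols, sort=True, dropna=False):
        key = _key_from_row(grp.iloc[0])
        grp = grp.sort_values("year", na_position="first")
        years = grp["year"].fillna(0).astype(int).tolist()
        amounts = grp["amount"].astype(float).tolist()
        units = set(grp["units"])
        if len(units) != 1:
            raise ValidationError(f"{key.label()} county {cid}: mixed units {units}")
        max_res = grp["max_resource"].astype(float)
        if max_res.nunique() > 1:
            raise ValidationError(
                f"{key.label()} county {cid}: inconsistent max_resource"
            )
        mr = float(max_res.iloc[0])
        records.append(
            BaselineRecord(
                county_id=int(cid),
                key=key,
                series=tuple(zip(years, amounts)),
                units=units.pop(),
                max_resource=math.inf if pd.isna(mr) else mr,
            )
        )
    return records


def read_rates(
    path: str | Path, age_profiles: dict[str, tuple[tuple[int, float], ...]]
) -> dict[tuple[ActivityKey, str], RateSpec]:
    df = _read_csv(path, _RATE_COLS, "rates")
    rates: dict[tuple[ActivityKey, str], RateSpec] = {}
    for _, row in df.iterrows():
        key = _key_from_row(row)
        prof_id = row["age_profile"]
        profile: tuple[tuple[int, float], ...] = ()
        if not (pd.isna(prof_id) or prof_id == ""):
            if str(prof_id) not in age_profiles:
                raise UnresolvedKeyError(
                    f"rate {key.label()} references unknown age profile {prof_id!r}"
                )
            profile = age_profiles[str(prof_id)]
        spec = RateSpec(
            key=key,
            region=str(row["region"]),
            mean_rate=float(row["mean_rate"]),
            sd_rate=float(row["sd_rate"]),
            units=str(row["units"]),
            age_profile=profile,
        )
        rk = (key, spec.region)
        if rk in rates:
            raise ValidationError(
                f"duplicate rate for {key.label()} in region {spec.region}"
            )
        rates[rk] = spec
    return rates


def read_age_profiles(path: str | Path) -> dict[str, tuple[tuple[int, float], ...]]:
    path = Path(path)
    if not path.exists():
        return {}
    df = _read_csv(path, _PROFILE_COLS, "age_profiles")
    profiles: dict[str, tuple[tuple[int, float], ...]] = {}
    for pid, grp in df.groupby("profile_id", sort=True):
        grp = grp.sort_values("age")
        profiles[str(pid)] = tuple(
            (int(a), float(m)) for a, m in zip(grp["age"], grp["multiplier"])
        )
    return profiles


def read_scenario_overrides(path: str | Path) -> list[dict]:
    """Read scenario-parameter override rows (empty cells keep the default)."""
    path = Path(path)
    if not path.exists():
        return []
    df = _read_csv(path, _SCENARIO_COLS[:4], "scenario_params")
    rows = []
    for _, row in df.iterrows():
        entry: dict = {
            "scenario": str(row["scenario"]),
            "key": _key_from_row(row),
        }
        for fld in (
            "ramp_fraction",
            "growth_share",
            "post_decade_share",
            "cap_fraction",
        ):
            if fld in row and not pd.isna(row[fld]):
                entry[fld] = float(row[fld])
        if "flux_mode" in row and not pd.isna(row["flux_mode"]) and row["flux_mode"]:
            entry["flux_mode"] = str(row["flux_mode"])
        rows.append(entry)
    return rows


def read_inputs(
    counties_path: str | Path,
    baselines_path: str | Path,
    rates_path: str | Path,
    scenarios_path: str | Path,
    age_profiles_path: str | Path | None = None,
) -> InputBundle:
    """Load and cross-validate the full input bundle.

    Raises
    ------
    SchemaError
        A file is missing a documented column.
    RegistryError
        A row names an unregistered pathway/sub-activity/ownership.
    UnresolvedKeyError
        A baseline activity has no resolvable rate or scenario parameters.
    ValidationError
        A value breaks a domain invariant (negative activity, bad region...).
    """
    from .scenario_engine import scenario_defaults  # local import avoids a cycle

    counties = read_counties(counties_path)
    baselines = read_baselines(baselines_path)
    if age_profiles_path is None:
        age_profiles_path = Path(rates_path).with_name("age_profiles.csv")
    age_profiles = read_age_profiles(age_profiles_path)
    rates = read_rates(rates_path, age_profiles)
    overrides = read_scenario_overrides(scenarios_path)
    params = scenario_defaults(overrides)

    bundle = InputBundle(counties, baselines, rates, params, age_profiles)

    unresolved: list[str] = []
    for rec in baselines:
        if rec.county_id not in counties:
            raise ValidationError(
                f"baseline references unknown county_id {rec.county_id}"
            )
        region = counties[rec.county_id].region
        spec = rates.get((rec.key, region)) or rates.get((rec.key, "statewide"))
        if spec is None:
            unresolved.append(f"{rec.key.label()} (county {rec.county_id}, {region})")
            continue
        if (rec.key, region) not in rates:
            other = {"west": "east", "east": "west"}[region]
            # a purely-statewide rate is normal; warn only when the key is
            # regionalized elsewhere but missing for this county's region
            if (rec.key, other) in rates:
                msg = (
                    f"{rec.key.label()} county {rec.county_id}: no {region} rate, "
                    "using statewide"
                )
                bundle.warnings.append(msg)
                logger.info(msg)
        if spec.units != rec.units:
            raise ValidationError(
                f"{rec.key.label()} county {rec.county_id}: baseline units "
                f"{rec.units} do not match rate units {spec.units}"
            )
        for scen in SCENARIOS:
            bundle.params_for(scen, rec.key)  # raises UnresolvedKeyError
    if unresolved:
        raise UnresolvedKeyError(
            "baseline keys with no matching rate: " + "; ".join(sorted(set(unresolved)))
        )
    logger.info(
        "loaded %d counties, %d baseline records, %d rates",
        len(counties),
        len(baselines),
        len(rates),
    )
    return bundle


# ---------------------------------------------------------------------------
# Results I/O
# ---------------------------------------------------------------------------


def write_results(records: list[ResultRecord], path: str | Path) -> None:
    """Write result rows in canonical order (header-only file when empty)."""
    rows = [
        {
            "geography": r.geography,
            "pathway": r.pathway,
            "sub_activity": r.sub_activity,
            "scenario": r.scenario,
            "year": r.year,
            "calendar_year": START_CALENDAR_YEAR + r.year - 1,
            "median": r.median,
            "p05": r.p05,
            "p95": r.p95,
            "cumulative_median": r.cumulative_median,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=RESULT_COLS)
    df = df.sort_values(
        ["geography", "pathway", "sub_activity", "scenario", "year"],
        kind="stable",
    )
    df.to_csv(path, index=False)


def read_results(path: str | Path) -> list[ResultRecord]:
    df = _read_csv(path, RESULT_COLS, "results")
    out = []
    for _, row in df.iterrows():
        out.append(
            ResultRecord(
                geography=str(row["geography"]),
                pathway=str(row["pathway"]),
                sub_activity="" if pd.isna(row["sub_activity"]) else str(row["sub_activity"]),
                scenario=str(row["scenario"]),
                year=int(row["year"]),
                median=float(row["median"]),
                p05=float(row["p05"]),
                p95=float(row["p95"]),
                cumulative_median=float(row["cumulative_median"]),
            )
        )
    return out
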