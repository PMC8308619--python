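"""CO2e flux accounting on enrolled-activity trajectories.

All fluxes are signed MT CO2e per year; negative means net removal or
avoided emission.  Three accrual modes:

* **stock** — flux accrues on all enrolled activity each year
  (management and restoration pathways; default for avoided conversion).
* **pulse** — flux is counted only on the year's new enrollment
  (committed-emissions accounting for avoided conversion, selectable).
* **cohort** — flux depends on the age of each enrollment-year cohort
  through a step-function age profile (replanting, added sequestration on
  deferred stands).

Extended-rotation net rates decompose into five signed components:
harvest volume, below-ground biomass, unused mill residues, wood burned as
commercial fuel, and short-lived (<= 20-year) wood products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_io import ValidationError
from .registry import ActivityKey

__all__ = [
    "TIMBER_COMPONENTS",
    "TimberRateComponents",
    "FluxSeries",
    "timber_net_rate",
    "stock_flux",
    "pulse_flux",
    "cohort_flux",
    "unit_profile_series",
    "delayed_harvest_added_sequestration",
]

TIMBER_COMPONENTS = (
    "harvest_volume",
    "belowground_biomass",
    "unused_mill_residue",
    "commercial_fuel",
    "shortlived_products",
)


@dataclass(frozen=True)
class TimberRateComponents:
    """Signed per-volume-unit rates for the five extended-rotation components."""

    region: str
    harvest_volume: float
    belowground_biomass: float
    unused_mill_residue: float
    commercial_fuel: float
    shortlived_products: float


@dataclass(frozen=True)
class FluxSeries:
    """Annual signed flux (MT CO2e/yr) and its running cumulative sum."""

    county_id: int
    key: ActivityKey
    scenario: str
    annual_flux: np.ndarray
    cumulative: np.ndarray

    @classmethod
    def from_annual(
        cls, county_id: int, key: ActivityKey, scenario: str, annual: np.ndarray
    ) -> "FluxSeries":
        annual = np.asarray(annual, dtype=float)
        return cls(county_id, key, scenario, annual, np.cumsum(annual))


def timber_net_rate(components: TimberRateComponents | dict) -> float:
    """Net per-unit rate: the signed sum of the five timber components."""
    if isinstance(components, TimberRateComponents):
        return float(sum(getattr(components, c) for c in TIMBER_COMPONENTS))
    missing = [c for c in TIMBER_COMPONENTS if c not in components]
    if missing:
        raise ValidationError(f"missing timber rate component(s): {missing}")
    return float(sum(components[c] for c in TIMBER_COMPONENTS))


def stock_flux(trajectory, rate: float, rate_units: str | None = None,
               baseline_units: str | None = None) -> FluxSeries:
    """Flux accrues on cumulative enrolled stock: flux[t] = enrolled[t] * rate."""
    if rate_units is not None and baseline_units is not None and rate_units != baseline_units:
        raise ValidationError(
            f"unit mismatch: rate per {rate_units}, enrollment in {baseline_units}"
        )
    annual = trajectory.enrolled * rate
    return FluxSeries.from_annual(
        trajectory.county_id, trajectory.key, trajectory.scenario, annual
    )


def pulse_flux(trajectory, rate: float) -> FluxSeries:
    """Flux counted in the enrollment year only: flux[t] = increments[t] * rate."""
    annual = trajectory.increments * rate
    return FluxSeries.from_annual(
        trajectory.county_id, trajectory.key, trajectory.scenario, annual
    )


def _profile_lookup(age_profile: tuple[tuple[int, float], ...], max_age: int) -> np.ndarray:
    """Expand a step-function age profile to a dense per-age vector.

    Ages between tabulated entries take the last tabulated value (no
    interpolation); ages past the final entry hold the terminal value.
    """
    if not age_profile:
        raise ValidationError("age profile is empty")
    dense = np.empty(max_age)
    ages = [a for a, _ in age_profile]
    vals = [v for _, v in age_profile]
    idx = 0
    for age in range(1, max_age + 1):
        while idx + 1 < len(ages) and ages[idx + 1] <= age:
            idx += 1
        dense[age - 1] = vals[idx]
    return dense


def unit_profile_series(trajectory, age_profile: tuple[tuple[int, float], ...]) -> np.ndarray:
    """Profile-weighted enrolled activity per year.

    Each enrollment-year cohort (the year's increment) is weighted by the
    profile value at its current age; a flat profile of 1 reduces this to
    the enrolled series.  Multiplying by a per-unit rate yields cohort flux.
    """
    n = trajectory.n_years
    dense = _profile_lookup(age_profile, n)
    inc = trajectory.increments
    out = np.zeros(n)
    for j in range(n):  # cohort enrolled in year j+1
        if inc[j] == 0:
            continue
        ages = np.arange(n - j)  # age-1 at year j+1
        out[j:] += inc[j] * dense[ages]
    return out


def cohort_flux(trajectory, age_profile: tuple[tuple[int, float], ...]) -> FluxSeries:
    """Age-dependent flux: flux[t] = sum over cohorts of amount * rate(age).

    ``age_profile`` entries are absolute per-unit rates here (when the
    profile stores multipliers, scale it by the drawn rate first).
    """
    annual = unit_profile_series(trajectory, age_profile)
    return FluxSeries.from_annual(
        trajectory.county_id, trajectory.key, trajectory.scenario, annual
    )


def delayed_harvest_added_sequestration(
    trajectory, growth_delta_profile: tuple[tuple[int, float], ...]
) -> FluxSeries:
    """Added sequestration on deferred private even-aged stands.

    ``growth_delta_profile`` holds the per-age difference between the
    deferred-stand sequestration rate and business-as-usual regrowth after
    clearcut.  Only valid for private-ownership activities.
    """
    if trajectory.key.ownership != "private":
        raise ValidationError(
            "added sequestration applies to private even-aged stands only, "
            f"got ownership {trajectory.key.ownership!r}"
        )
    return cohort_flux(trajectory, growth_delta_profile)
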