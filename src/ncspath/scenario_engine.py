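"""Implementation scenarios: 31-year enrollment trajectories.

Three effort levels — limited, moderate, ambitious — govern how fast new
activity is enrolled relative to the historical variation (HV) of the
baseline.  Enrollment is additional and cumulative: activity brought under
a practice stays enrolled (deferred stands stay deferred, restored
hectares stay restored).  Each year's enrollment increment is

    years 1-10:   min(t * ramp_fraction, 1) * growth_share * HV
    years 11-31:  post_decade_share * growth_share * HV

and cumulative enrollment is capped at ``cap_fraction * max_resource``.
With the default ramp of 0.1 the increment grows linearly to 100% of the
allowed growth at year 10; ``post_decade_share`` then either holds the
year-10 increment (1.0) or throttles it (e.g. 0.5 for limited-effort
timber deferral).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_io import N_YEARS, SCENARIOS, BaselineRecord, ScenarioParams, ValidationError
from .registry import ACTIVITY_REGISTRY, TIMBER, ActivityKey

__all__ = [
    "Trajectory",
    "annual_increment",
    "build_trajectory",
    "params_for_county",
    "scenario_defaults",
]


@dataclass(frozen=True)
class Trajectory:
    """Enrolled activity per simulation year for one (county, activity, scenario)."""

    county_id: int
    key: ActivityKey
    scenario: str
    increments: np.ndarray  # new activity enrolled each year (activity units)
    enrolled: np.ndarray  # cumulative enrolled activity
    capped_at: int | None = None  # first year the resource cap binds

    def __post_init__(self) -> None:
        if len(self.increments) != len(self.enrolled):
            raise ValidationError("increments and enrolled must be the same length")
        if np.any(self.increments < -1e-12):
            raise ValidationError("increments must be >= 0")
        if np.any(np.diff(self.enrolled) < -1e-12):
            raise ValidationError("enrolled must be non-decreasing")

    @property
    def n_years(self) -> int:
        return len(self.enrolled)


def annual_increment(params: ScenarioParams, t: int, hv: float, n_years: int = N_YEARS) -> float:
    """Pre-cap enrollment increment in simulation year ``t`` (1-based)."""
    if not 1 <= t <= n_years:
        raise ValidationError(f"year {t} outside [1, {n_years}]")
    if hv < 0:
        raise ValidationError("hv must be >= 0")
    ramp_years = round(1.0 / params.ramp_fraction)
    if t <= ramp_years:
        return min(t * params.ramp_fraction, 1.0) * params.growth_share * hv
    return params.post_decade_share * params.growth_share * hv


def build_trajectory(
    record: BaselineRecord,
    hv: float,
    params: ScenarioParams,
    n_years: int = N_YEARS,
) -> Trajectory:
    """Accumulate increments, cap at ``cap_fraction * max_resource``.

    The cap applies to cumulative enrollment; the increment in the capping
    year is trimmed so that ``enrolled[t] = enrolled[t-1] + increments[t]``
    holds exactly throughout.
    """
    cap = params.cap_fraction * record.max_resource
    raw = np.array(
        [annual_increment(params, t, hv, n_years) for t in range(1, n_years + 1)]
    )
    cum = np.cumsum(raw)
    enrolled = np.minimum(cum, cap)
    increments = np.diff(enrolled, prepend=0.0)
    capped_at: int | None = None
    if np.any(cum > cap + 1e-12):
        capped_at = int(np.argmax(cum > cap + 1e-12)) + 1
    return Trajectory(
        county_id=record.county_id,
        key=record.key,
        scenario=params.scenario,
        increments=increments,
        enrolled=enrolled,
        capped_at=capped_at,
    )


# ---------------------------------------------------------------------------
# Default scenario-parameter registry
# ---------------------------------------------------------------------------

# Extended-rotation specifics:
#   moderate growth shares by ownership (private 30%, state 15%, federal/other 75%)
#   ambitious resource caps by ownership (private 40%, state 32%, others 100%)
#   limited post-decade throttle: increments stabilize at half the HV.
_TIMBER_MODERATE_GROWTH = {"private": 0.30, "state": 0.15, "federal": 0.75, "other": 0.75}
_TIMBER_AMBITIOUS_CAP = {"private": 0.40, "state": 0.32, "federal": 1.0, "other": 1.0}

# Without pathway-specific feasibility coefficients the moderate scenario
# defaults to half the historical variation; ambitious allows full variation
# and full resource use.  All values are overridable via scenario_params.csv.
_GENERAL_GROWTH = {"limited": 1.0, "moderate": 0.5, "ambitious": 1.0}


def _default_params(scenario: str, key: ActivityKey) -> ScenarioParams:
    spec = ACTIVITY_REGISTRY[key]
    growth = _GENERAL_GROWTH[scenario]
    post = 1.0
    cap = 1.0
    if key.pathway == TIMBER:
        if scenario == "limited":
            post = 0.5
        elif scenario == "moderate":
            growth = _TIMBER_MODERATE_GROWTH.get(key.ownership, 0.75)
        elif scenario == "ambitious":
            growth = 1.0
            cap = _TIMBER_AMBITIOUS_CAP.get(key.ownership, 1.0)
    return ScenarioParams(
        scenario=scenario,
        key=key,
        ramp_fraction=0.1,
        growth_share=growth,
        post_decade_share=post,
        cap_fraction=cap,
        flux_mode=spec.flux_mode,
    )


def params_for_county(params: ScenarioParams, region: str) -> ScenarioParams:
    """Apply region-specific adjustments to scenario parameters.

    Ambitious ownership caps on extended rotations (40% private, 32% state)
    apply only west of the Cascade crest; in eastern counties implementation
    may reach 100% on all ownerships.
    """
    if (
        params.key.pathway == TIMBER
        and params.scenario == "ambitious"
        and region == "east"
        and params.cap_fraction < 1.0
    ):
        return ScenarioParams(
            scenario=params.scenario,
            key=params.key,
            ramp_fraction=params.ramp_fraction,
            growth_share=params.growth_share,
            post_decade_share=params.post_decade_share,
            cap_fraction=1.0,
            flux_mode=params.flux_mode,
        )
    return params


def scenario_defaults(
    overrides: list[dict] | None = None,
) -> dict[tuple[str, ActivityKey], ScenarioParams]:
    """Complete (scenario, activity) parameter registry with optional overrides.

    ``overrides`` rows (as produced by ``model_io.read_scenario_overrides``)
    replace individual fields; rows keyed outside the registry are rejected.
    """
    registry: dict[tuple[str, ActivityKey], ScenarioParams] = {}
    for scenario in SCENARIOS:
        for key in ACTIVITY_REGISTRY:
            registry[(scenario, key)] = _default_params(scenario, key)
    for row in overrides or []:
        rk = (row["scenario"], row["key"])
        if rk not in registry:
            raise ValidationError(
                f"scenario override for unknown combination {rk[0]}, {rk[1].label()}"
            )
        base = registry[rk]
        registry[rk] = ScenarioParams(
            scenario=base.scenario,
            key=base.key,
            ramp_fraction=row.get("ramp_fraction", base.ramp_fraction),
            growth_share=row.get("growth_share", base.growth_share),
            post_decade_share=row.get("post_decade_share", base.post_decade_share),
            cap_fraction=row.get("cap_fraction", base.cap_fraction),
            flux_mode=row.get("flux_mode", base.flux_mode),
        )
    return registry
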