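"""Monte Carlo propagation of sequestration-rate uncertainty.

Only the per-unit CO2e rates are uncertain; enrollment trajectories are
deterministic and computed once.  Each iteration draws one rate per
(activity, region) from Normal(mean, sd) — untruncated, so occasional
sign-flipped draws are retained rather than biasing the mean — and holds
it fixed across years and counties sharing the rate (rate uncertainty is
epistemic, not interannual weather).  A per-year redraw variant is
available behind ``per_year_draws``.

Summaries aggregate per-iteration totals *first* and take quantiles over
iterations afterwards, so the total's median and interval come from the
joint distribution, not from summing per-pathway summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baseline import hv_from_record
from .flux import unit_profile_series
from .model_io import (
    N_YEARS,
    InputBundle,
    RateSpec,
    ResultRecord,
    ValidationError,
)
from .registry import TIMBER
from .scenario_engine import build_trajectory, params_for_county

logger = logging.getLogger(__name__)

MT_PER_MMT = 1e6

_SCENARIO_STREAM = {"limited": 0, "moderate": 1, "ambitious": 2}

GROUPINGS = ("total", "pathway", "county", "county_pathway")


@dataclass
class IterationCube:
    """Monte Carlo annual fluxes, shape (n_iter, n_series, n_years), MT CO2e/yr.

    ``index`` holds one row per modelled series: county_id, pathway,
    sub_activity, ownership.
    """

    values: np.ndarray
    index: pd.DataFrame
    scenario: str
    n_iter: int
    seed: int
    years: np.ndarray = field(default_factory=lambda: np.arange(1, N_YEARS + 1))

    def __post_init__(self) -> None:
        if self.values.shape != (self.n_iter, len(self.index), len(self.years)):
            raise ValidationError("cube shape does not match its index")

    def select(self, exclude_pathways: tuple[str, ...] = ()) -> "IterationCube":
        """Sub-cube without the listed pathways (e.g. drop extended rotations)."""
        mask = ~self.index["pathway"].isin(exclude_pathways)
        return IterationCube(
            values=self.values[:, mask.to_numpy(), :],
            index=self.index.loc[mask].reset_index(drop=True),
            scenario=self.scenario,
            n_iter=self.n_iter,
            seed=self.seed,
            years=self.years,
        )


def draw_rates(
    rate_specs: dict[tuple, RateSpec], rng: np.random.Generator
) -> dict[tuple, float]:
    """One Normal(mean, sd) draw per (activity, region); sd=0 returns the mean."""
    out = {}
    for rk in sorted(rate_specs, key=lambda k: (k[0], k[1])):
        spec = rate_specs[rk]
        if spec.sd_rate < 0:
            raise ValidationError("sd_rate must be >= 0")
        out[rk] = float(rng.normal(spec.mean_rate, spec.sd_rate))
    return out


def _scenario_rng(seed: int, scenario: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_SCENARIO_STREAM[scenario],))
    return np.random.default_rng(ss)


def deterministic_unit_series(
    bundle: InputBundle, scenario: str, n_years: int = N_YEARS
) -> tuple[pd.DataFrame, np.ndarray, list[tuple]]:
    """Rate-independent activity series per baseline record.

    Returns (index frame, U, rate_keys) where ``U[s, t]`` is the
    profile-weighted enrolled activity (stock mode), the enrollment
    increment (pulse mode), or the cohort-age-weighted activity (cohort
    pathways), such that annual flux = U * drawn rate.  ``rate_keys[s]``
    is the (ActivityKey, region) whose rate multiplies series ``s``.
    """
    rows, series, rate_keys = [], [], []
    for rec in sorted(
        bundle.baselines,
        key=lambda r: (r.county_id, r.key.pathway, r.key.sub_activity, r.key.ownership),
    ):
        county = bundle.counties[rec.county_id]
        hv = hv_from_record(rec)
        hv_value = 0.0 if (rec.key.pathway == TIMBER and county.timber_excluded) else hv.hv
        for_rate = bundle.rate_for(rec.county_id, rec.key)
        params = params_for_county(bundle.params_for(scenario, rec.key), county.region)
        traj = build_trajectory(rec, hv_value, params, n_years)
        if for_rate.age_profile:
            u = unit_profile_series(traj, for_rate.age_profile)
        elif params.flux_mode == "pulse":
            u = traj.increments
        else:
            u = traj.enrolled
        rows.append(
            {
                "county_id": rec.county_id,
                "pathway": rec.key.pathway,
                "sub_activity": rec.key.sub_activity,
                "ownership": rec.key.ownership,
            }
        )
        series.append(u)
        rate_keys.append((rec.key, for_rate.region))
    index = pd.DataFrame(rows)
    U = np.vstack(series) if series else np.zeros((0, n_years))
    return index, U, rate_keys


def run_simulation(
    bundle: InputBundle,
    scenario: str,
    n_iter: int = 1000,
    seed: int = 0,
    per_year_draws: bool = False,
    n_years: int = N_YEARS,
) -> IterationCube:
    """Propagate rate uncertainty through the deterministic pipeline.

    Each iteration applies one fresh set of rate draws to the precomputed
    unit series.  Reproducible: the master seed spawns an independent
    substream per scenario, and identical (seed, scenario, n_iter) give
    bitwise-identical cubes.
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    index, U, rate_keys = deterministic_unit_series(bundle, scenario, n_years)
    uniq = sorted(set(rate_keys), key=lambda rk: (rk[0], rk[1]))
    pos = {rk: i for i, rk in enumerate(uniq)}
    means = np.array([bundle.rates[rk].mean_rate for rk in uniq])
    sds = np.array([bundle.rates[rk].sd_rate for rk in uniq])
    rng = _scenario_rng(seed, scenario)
    col = np.array([pos[rk] for rk in rate_keys], dtype=int)
    if per_year_draws:
        R = rng.normal(means[:, None], sds[:, None], size=(n_iter, len(uniq), n_years))
        values = U[None, :, :] * R[:, col, :]
    else:
        R = rng.normal(means, sds, size=(n_iter, len(uniq)))
        values = R[:, col][:, :, None] * U[None, :, :]
    logger.info(
        "scenario %s: %d series, %d distinct rates, %d iterations",
        scenario,
        len(index),
        len(uniq),
        n_iter,
    )
    return IterationCube(
        values=values,
        index=index,
        scenario=scenario,
        n_iter=n_iter,
        seed=seed,
        years=np.arange(1, n_years + 1),
    )


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def _group_labels(cube: IterationCube, group: str) -> pd.DataFrame:
    idx = cube.index
    if group == "total":
        return pd.DataFrame(
            {"geography": ["statewide"] * len(idx), "pathway": ["total"] * len(idx),
             "sub_activity": [""] * len(idx)}
        )
    if group == "pathway":
        return pd.DataFrame(
            {"geography": ["statewide"] * len(idx), "pathway": idx["pathway"],
             "sub_activity": [""] * len(idx)}
        )
    if group == "county":
        return pd.DataFrame(
            {"geography": idx["county_id"].astype(str), "pathway": ["total"] * len(idx),
             "sub_activity": [""] * len(idx)}
        )
    if group == "county_pathway":
        return pd.DataFrame(
            {"geography": idx["county_id"].astype(str), "pathway": idx["pathway"],
             "sub_activity": [""] * len(idx)}
        )
    raise ValidationError(f"group must be one of {GROUPINGS}")


def summarize(cube: IterationCube, group: str = "total") -> pd.DataFrame:
    """Median / 5th / 95th percentile summaries in MMT CO2e per yr.

    Per-iteration sums over the grouping are formed first; quantiles (linear
    interpolation between order statistics) are then taken over iterations.
    ``p05`` is the numeric 5th percentile — for negative fluxes, the most
    negative bound.  ``cumulative_median`` is the median over iterations of
    the per-iteration running cumulative sum.
    """
    if cube.values.size == 0:
        raise ValidationError("cannot summarize an empty cube")
    labels = _group_labels(cube, group)
    label_tuples = list(
        zip(labels["geography"], labels["pathway"], labels["sub_activity"])
    )
    uniq = sorted(set(label_tuples))
    rows = []
    for geo, pw, sub in uniq:
        mask = np.array([lt == (geo, pw, sub) for lt in label_tuples])
        per_iter = cube.values[:, mask, :].sum(axis=1) / MT_PER_MMT  # (n_iter, years)
        med = np.quantile(per_iter, 0.5, axis=0, method="linear")
        p05 = np.quantile(per_iter, 0.05, axis=0, method="linear")
        p95 = np.quantile(per_iter, 0.95, axis=0, method="linear")
        cum_med = np.quantile(np.cumsum(per_iter, axis=1), 0.5, axis=0, method="linear")
        for j, year in enumerate(cube.years):
            rows.append(
                {
                    "geography": geo,
                    "pathway": pw,
                    "sub_activity": sub,
                    "scenario": cube.scenario,
                    "year": int(year),
                    "median": med[j],
                    "p05": p05[j],
                    "p95": p95[j],
                    "cumulative_median": cum_med[j],
                }
            )
    return pd.DataFrame(rows)


def to_result_records(summary: pd.DataFrame) -> list[ResultRecord]:
    return [
        ResultRecord(
            geography=str(r.geography),
            pathway=str(r.pathway),
            sub_activity=str(r.sub_activity),
            scenario=str(r.scenario),
            year=int(r.year),
            median=float(r.median),
            p05=float(r.p05),
            p95=float(r.p95),
            cumulative_median=float(r.cumulative_median),
        )
        for r in summary.itertuples()
    ]
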