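"""Headline summaries: percent-of-goal, pathway shares, county rollups.

Display conventions follow the statewide assessment style: medians to two
decimals, pathway shares to whole percent, goal percentages to one
decimal.  Machine outputs always retain the unrounded values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .model_io import ValidationError
from .montecarlo import IterationCube, summarize
from .registry import TIMBER

__all__ = [
    "GoalContext",
    "load_reference_statewide",
    "percent_of_goal",
    "pathway_shares",
    "per_area_intensity",
    "cluster_top_counties",
    "render_reports",
]

STATEWIDE_EMISSIONS_2018 = 99.57  # MMT CO2e/yr, statewide inventory baseline


@dataclass(frozen=True)
class GoalContext:
    """Net-zero goal arithmetic: statewide emissions baseline and target year."""

    statewide_emissions_baseline: float = STATEWIDE_EMISSIONS_2018
    target_year: int = 2050

    def __post_init__(self) -> None:
        if not self.statewide_emissions_baseline > 0:
            raise ValidationError("statewide emissions baseline must be > 0")


def load_reference_statewide() -> pd.DataFrame:
    """Published statewide final-year medians and CI bounds (MMT CO2e/yr).

    Reference values from the Washington statewide NCS assessment this model
    re-implements, used for arithmetic-consistency checks (percent of goal,
    pathway shares).  The grassland pathway is absent: its median is printed
    only as a bound (< -0.01), not a number.  Columns: pathway, scenario,
    median, ci_low_mag (bound nearer zero), ci_high_mag.
    """
    from importlib.resources import files

    path = files("ncspath.data").joinpath("reference_statewide_2050.csv")
    with path.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def percent_of_goal(
    total_reduction_mmt: float, context: GoalContext | None = None
) -> tuple[float, float]:
    """Share of the statewide emissions baseline offset by a reduction.

    Returns (unrounded, display) percentages; display is rounded to one
    decimal.  The sign of the reduction is ignored — only magnitude counts
    toward the goal.
    """
    context = context or GoalContext()
    pct = abs(total_reduction_mmt) / context.statewide_emissions_baseline * 100.0
    return pct, round(pct, 1)


def pathway_shares(final_year_rows: pd.DataFrame) -> pd.DataFrame:
    """Pathway share of the total median (percent) for one scenario/year.

    Expects statewide rows with a ``total`` pathway row present.  Because
    the total median comes from the joint simulation, shares computed from
    medians need not sum to exactly 100.
    """
    rows = final_year_rows
    total = rows.loc[rows["pathway"] == "total", "median"]
    if total.empty:
        raise ValidationError("missing 'total' row")
    total_median = float(total.iloc[0])
    if total_median == 0:
        raise ValidationError("total median is zero; shares undefined")
    out = rows.loc[rows["pathway"] != "total", ["pathway", "median"]].copy()
    out["share_pct"] = out["median"] / total_median * 100.0
    out["share_display"] = out["share_pct"].round(0).astype(int)
    return out.sort_values("share_pct", ascending=False).reset_index(drop=True)


def per_area_intensity(
    county_totals: dict[str, float], county_areas: dict[str, float]
) -> pd.DataFrame:
    """Final-year reduction per hectare of county area, ranked by magnitude."""
    rows = []
    for geo, total in county_totals.items():
        area = county_areas[geo]
        if not area > 0:
            raise ValidationError(f"county {geo}: area must be > 0")
        rows.append(
            {"geography": geo, "median": total, "area_ha": area,
             "intensity_mmt_per_ha": total / area}
        )
    df = pd.DataFrame(rows)
    df["rank"] = (
        df["intensity_mmt_per_ha"].abs().rank(ascending=False, method="first").astype(int)
    )
    return df.sort_values("rank").reset_index(drop=True)


def cluster_top_counties(
    county_medians: dict[int, float], coverage: float = 0.5
) -> list[int]:
    """Smallest set of counties carrying ``coverage`` of a pathway's reductions.

    Counties are sorted by reduction magnitude (descending, ties broken by
    county id ascending); the shortest prefix whose summed magnitude reaches
    ``coverage`` times the pathway's statewide magnitude is returned.
    """
    if not 0 < coverage <= 1:
        raise ValidationError("coverage must be in (0, 1]")
    total = sum(abs(v) for v in county_medians.values())
    if total == 0:
        return []
    ordered = sorted(county_medians.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
    target = coverage * total
    picked, acc = [], 0.0
    for cid, val in ordered:
        if abs(val) == 0:
            break
        picked.append(cid)
        acc += abs(val)
        if acc >= target - 1e-12:
            break
    return picked


def render_reports(
    cubes: dict[str, IterationCube],
    context: GoalContext,
    county_areas: dict[str, float],
    outdir: str | Path,
    final_year: int | None = None,
) -> dict[str, Path]:
    """Write the six tabular report files from per-scenario iteration cubes.

    table2.csv              statewide pathway x scenario medians/CIs, final year
    county_totals.csv       per-county totals with and without extended rotations
    pathway_by_county.csv   final-year medians per (county, pathway)
    shares.csv              pathway share of total median per scenario
    clusters.csv            top-county clusters covering half of each pathway
    intensity.csv           per-area reduction intensity per county
    """
    if not cubes:
        raise ValidationError("no iteration cubes supplied")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    table2, shares_rows, county_rows, cp_rows, cluster_rows, intensity_rows = (
        [], [], [], [], [], []
    )
    for scenario in sorted(cubes):
        cube = cubes[scenario]
        fy = final_year or int(cube.years[-1])
        path_sum = summarize(cube, "pathway")
        tot_sum = summarize(cube, "total")
        final_rows = pd.concat(
            [
                path_sum.loc[path_sum["year"] == fy],
                tot_sum.loc[tot_sum["year"] == fy],
            ],
            ignore_index=True,
        )
        for r in final_rows.itertuples():
            table2.append(
                {
                    "pathway": r.pathway,
                    "scenario": scenario,
                    "year": fy,
                    "median": r.median,
                    "p05": r.p05,
                    "p95": r.p95,
                    "median_display": round(r.median, 2),
                }
            )
        sh = pathway_shares(final_rows)
        total_median = float(
            final_rows.loc[final_rows["pathway"] == "total", "median"].iloc[0]
        )
        pct, pct_disp = percent_of_goal(total_median, context)
        for r in sh.itertuples():
            shares_rows.append(
                {
                    "scenario": scenario,
                    "pathway": r.pathway,
                    "share_pct": r.share_pct,
                    "share_display": r.share_display,
                    "percent_of_goal": pct,
                    "percent_of_goal_display": pct_disp,
                }
            )
        county_tot = summarize(cube, "county")
        county_tot_ex = summarize(cube.select(exclude_pathways=(TIMBER,)), "county")
        ct = county_tot.loc[county_tot["year"] == fy].set_index("geography")["median"]
        cte = county_tot_ex.loc[county_tot_ex["year"] == fy].set_index("geography")["median"]
        for geo in ct.index:
            county_rows.append(
                {
                    "scenario": scenario,
                    "geography": geo,
                    "median_all_pathways": ct[geo],
                    "median_without_extended_rotation": cte.get(geo, 0.0),
                }
            )
        cp = summarize(cube, "county_pathway")
        cp_final = cp.loc[cp["year"] == fy]
        for r in cp_final.itertuples():
            cp_rows.append(
                {
                    "scenario": scenario,
                    "geography": r.geography,
                    "pathway": r.pathway,
                    "median": r.median,
                    "p05": r.p05,
                    "p95": r.p95,
                }
            )
        for pw, grp in cp_final.groupby("pathway"):
            medians = {int(g): float(m) for g, m in zip(grp["geography"], grp["median"])}
            for rank, cid in enumerate(cluster_top_counties(medians), start=1):
                cluster_rows.append(
                    {"scenario": scenario, "pathway": pw, "rank": rank,
                     "county_id": cid, "median": medians[cid]}
                )
        totals = {g: float(v) for g, v in ct.items()}
        intensity = per_area_intensity(totals, {g: county_areas[g] for g in totals})
        for r in intensity.itertuples():
            intensity_rows.append(
                {
                    "scenario": scenario,
                    "geography": r.geography,
                    "median": r.median,
                    "area_ha": r.area_ha,
                    "intensity_mmt_per_ha": r.intensity_mmt_per_ha,
                    "rank": r.rank,
                }
            )

    files = {
        "table2": (table2, ["pathway", "scenario"]),
        "shares": (shares_rows, ["scenario", "pathway"]),
        "county_totals": (county_rows, ["scenario", "geography"]),
        "pathway_by_county": (cp_rows, ["scenario", "geography", "pathway"]),
        "clusters": (cluster_rows, ["scenario", "pathway", "rank"]),
        "intensity": (intensity_rows, ["scenario", "rank"]),
    }
    written = {}
    for name, (rows, sort_cols) in files.items():
        df = pd.DataFrame(rows).sort_values(sort_cols, kind="stable")
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        written[name] = path
    return written
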