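"""Baseline activity rates, historical variation, and derived caps.

Each activity's future implementation is scaled by its *historical
variation* (HV): the baseline annual rate times the coefficient of
variation (CV) of the activity's historical record.  Activities with an
annual time series (timber harvest, post-wildfire replanting) get an
empirical CV; everything else falls back to a conservative 10% annual
variation.  HV is capped at the baseline rate itself so implementation can
never be scaled by more variation than there is activity.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass

import pandas as pd

from .model_io import BaselineRecord, InputBundle, ValidationError
from .registry import ActivityKey

logger = logging.getLogger(__name__)

DEFAULT_CV = 0.10
TIDAL_RESTORATION_CONSTANT = 0.00215  # annually restored share of lost wetland area
NUTRIENT_CROPLAND_FRACTION = 0.40  # croplands eligible for reduced N application


class InsufficientSeriesError(ValueError):
    """Fewer than two observations: no empirical CV, caller must use the default."""


class DegenerateSeriesError(ValueError):
    """Series mean is zero; CV is undefined."""


@dataclass(frozen=True)
class HistoricalVariation:
    """Baseline rate and its historical variation for one (county, activity)."""

    key: ActivityKey
    county_id: int
    baseline_rate: float
    cv: float
    hv: float
    provenance: str  # 'series_cv' or 'default_10pct'

    def __post_init__(self) -> None:
        if self.hv < 0 or self.hv > self.baseline_rate + 1e-12:
            raise ValidationError("hv must satisfy 0 <= hv <= baseline_rate")


def coefficient_of_variation(series: list[float]) -> float:
    """Sample CV (n-1 standard deviation over mean) of an annual series."""
    if len(series) < 2:
        raise InsufficientSeriesError(
            f"need >= 2 observations for an empirical CV, got {len(series)}"
        )
    if any(v < 0 for v in series):
        raise ValidationError("activity amounts must be >= 0")
    mean = statistics.fmean(series)
    if mean == 0:
        raise DegenerateSeriesError("series mean is zero; CV undefined")
    return statistics.stdev(series) / mean


def historical_variation(
    key: ActivityKey,
    county_id: int,
    baseline_rate: float,
    cv: float | None,
) -> HistoricalVariation:
    """HV = baseline_rate x CV, capped at the baseline rate (cv > 1).

    ``cv=None`` applies the conservative 10% default used for activities
    without an annual record.
    """
    if baseline_rate < 0:
        raise ValidationError("baseline_rate must be >= 0")
    if cv is None:
        cv, provenance = DEFAULT_CV, "default_10pct"
    else:
        if cv < 0:
            raise ValidationError("cv must be >= 0")
        provenance = "series_cv"
    hv = baseline_rate * min(cv, 1.0)
    return HistoricalVariation(key, county_id, baseline_rate, cv, hv, provenance)


def hv_from_record(record: BaselineRecord) -> HistoricalVariation:
    """Derive baseline rate and HV from a baseline record.

    Series of length >= 2 use the series mean as the baseline rate and the
    empirical CV; single-value records use the value with the 10% default.
    A zero-mean series degrades to the default CV on a zero rate (hv = 0).
    """
    amounts = record.amounts
    if len(amounts) >= 2:
        rate = statistics.fmean(amounts)
        try:
            cv: float | None = coefficient_of_variation(amounts)
        except DegenerateSeriesError:
            cv = None
    else:
        rate = amounts[0]
        cv = None
    return historical_variation(record.key, record.county_id, rate, cv)


def tidal_baseline(
    lost_ha: float,
    mapped_rate: float | None,
    in_puget_sound: bool,
) -> tuple[float, float]:
    """Tidal-wetland restoration baseline rate (ha/yr) and its resource cap.

    A mapped restoration rate takes precedence.  Puget Sound counties with
    no mapped restoration are assumed to restore a fixed share (0.00215/yr)
    of their lost tidal wetland area; elsewhere the rate is 0.  The
    restorable area is capped at the county's lost wetland area.
    """
    if lost_ha < 0:
        raise ValidationError("lost_ha must be >= 0")
    if mapped_rate is not None:
        rate = mapped_rate
    elif in_puget_sound:
        rate = lost_ha * TIDAL_RESTORATION_CONSTANT
    else:
        rate = 0.0
    return rate, lost_ha


def grassland_county_baseline(
    statewide_rate: float, shares: dict[int, float]
) -> dict[int, float]:
    """Allocate the statewide grassland-conversion rate by grassland share.

    Shares must sum to 1; the county rates sum exactly to the statewide
    rate (conservation).
    """
    if statewide_rate < 0:
        raise ValidationError("statewide_rate must be >= 0")
    total = sum(shares.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValidationError(f"grassland shares must sum to 1, got {total}")
    return {cid: statewide_rate * share for cid, share in shares.items()}


def nutrient_max_area(county_cropland_ha: float) -> float:
    """Maximum area eligible for reduced fertilizer application: 40% of cropland."""
    if county_cropland_ha < 0:
        raise ValidationError("cropland area must be >= 0")
    return NUTRIENT_CROPLAND_FRACTION * county_cropland_ha


def disaggregate_missing_counties(
    statewide_total: float,
    reported: dict[int, float],
    other_year: dict[int, float],
) -> dict[int, float]:
    """Fill counties missing from a census year from the statewide total.

    The residual (statewide total minus the sum of reported counties) is
    allocated to the missing counties in proportion to their areas in the
    other census year; if all of those are zero the residual is split
    uniformly (logged).  The filled table sums exactly to the statewide
    total.
    """
    reported_sum = sum(reported.values())
    residual = statewide_total - reported_sum
    if residual < -1e-9 * max(1.0, abs(statewide_total)):
        raise ValidationError(
            f"reported county total {reported_sum} exceeds statewide "
            f"total {statewide_total}"
        )
    residual = max(residual, 0.0)
    missing = sorted(set(other_year) - set(reported))
    filled = dict(reported)
    if not missing:
        return filled
    weights = [other_year[cid] for cid in missing]
    wsum = sum(weights)
    if wsum == 0:
        logger.warning(
            "missing counties %s have zero other-year area; splitting residual "
            "%.4g uniformly",
            missing,
            residual,
        )
        weights = [1.0] * len(missing)
        wsum = float(len(missing))
    for cid, w in zip(missing, weights):
        filled[cid] = residual * w / wsum
    return filled


def derive_baselines(bundle: InputBundle) -> pd.DataFrame:
    """Audit table of baseline rate, CV, HV and cap per (county, activity).

    Counties flagged ``timber_excluded`` contribute no extended-rotation
    activity: their timber HV rows are zeroed.
    """
    rows = []
    for rec in bundle.baselines:
        hv = hv_from_record(rec)
        county = bundle.counties[rec.county_id]
        if rec.key.pathway == "extended_rotation" and county.timber_excluded:
            hv = HistoricalVariation(
                rec.key, rec.county_id, 0.0, hv.cv, 0.0, hv.provenance
            )
        rows.append(
            {
                "county_id": rec.county_id,
                "pathway": rec.key.pathway,
                "sub_activity": rec.key.sub_activity,
                "ownership": rec.key.ownership,
                "baseline_rate": hv.baseline_rate,
                "cv": hv.cv,
                "hv": hv.hv,
                "provenance": hv.provenance,
                "max_resource": rec.max_resource,
                "units": rec.units,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["county_id", "pathway", "sub_activity", "ownership"]
    ).reset_index(drop=True)
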