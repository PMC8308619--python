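"""Monte Carlo propagation: draws, cubes, and aggregate-first summaries."""

import numpy as np
import pandas as pd
import pytest

from ncspath.model_io import RateSpec, ValidationError
from ncspath.montecarlo import (
    IterationCube,
    draw_rates,
    run_simulation,
    summarize,
)
from ncspath.registry import ActivityKey

RIP = ActivityKey("riparian_restoration")
TID = ActivityKey("tidal_wetland_restoration")


def make_cube(values, index_rows, scenario="limited", seed=0):
    values = np.asarray(values, dtype=float)
    return IterationCube(
        values=values,
        index=pd.DataFrame(index_rows),
        scenario=scenario,
        n_iter=values.shape[0],
        seed=seed,
        years=np.arange(1, values.shape[2] + 1),
    )


class TestDrawRates:
    def _specs(self, sd=0.5):
        return {
            (RIP, "statewide"): RateSpec(RIP, "statewide", -2.0, sd, "ha_per_yr"),
            (TID, "west"): RateSpec(TID, "west", -8.0, sd, "ha_per_yr"),
        }

    def test_zero_sd_returns_means_exactly(self):
        draws = draw_rates(self._specs(sd=0.0), np.random.default_rng(1))
        assert draws[(RIP, "statewide")] == -2.0
        assert draws[(TID, "west")] == -8.0

    def test_same_seed_identical_draws(self):
        d1 = draw_rates(self._specs(), np.random.default_rng(42))
        d2 = draw_rates(self._specs(), np.random.default_rng(42))
        assert d1 == d2

    def test_distributional_moments(self):
        # mean -2, sd 0.5: with 1e5 draws the sample mean sits within 3 se
        spec = {(RIP, "statewide"): RateSpec(RIP, "statewide", -2.0, 0.5, "ha_per_yr")}
        rng = np.random.default_rng(7)
        draws = np.array([draw_rates(spec, rng)[(RIP, "statewide")] for _ in range(10_000)])
        se = 0.5 / np.sqrt(draws.size)
        assert abs(draws.mean() - (-2.0)) < 3 * se
        assert abs(draws.std(ddof=1) - 0.5) < 0.02


class TestRunSimulation:
    def test_degenerate_mc_equals_deterministic(self, small_bundle):
        bundle, truth = small_bundle  # rate sd = 0 in this fixture
        c1 = run_simulation(bundle, "limited", n_iter=1, seed=5)
        c2 = run_simulation(bundle, "limited", n_iter=50, seed=9)
        assert np.allclose(c1.values[0], c2.values[17])

    def test_same_seed_bitwise_identical(self, default_bundle):
        bundle, _ = default_bundle
        c1 = run_simulation(bundle, "ambitious", n_iter=20, seed=11)
        c2 = run_simulation(bundle, "ambitious", n_iter=20, seed=11)
        assert np.array_equal(c1.values, c2.values)

    def test_scenarios_use_independent_streams(self, default_bundle):
        bundle, _ = default_bundle
        ca = run_simulation(bundle, "ambitious", n_iter=5, seed=11)
        cl = run_simulation(bundle, "limited", n_iter=5, seed=11)
        assert not np.array_equal(ca.values, cl.values)

    def test_invalid_n_iter(self, small_bundle):
        bundle, _ = small_bundle
        with pytest.raises(ValidationError):
            run_simulation(bundle, "limited", n_iter=0, seed=1)

    def test_per_year_draws_widen_no_change_to_units(self, default_bundle):
        bundle, _ = default_bundle
        cube = run_simulation(bundle, "limited", n_iter=10, seed=2, per_year_draws=True)
        assert cube.values.shape == (10, len(cube.index), 31)


class TestSummarize:
    def test_quantile_definition(self):
        # one series, 100 iterations valued -1..-100 in year 1
        vals = -np.arange(1, 101, dtype=float).reshape(100, 1, 1) * 1e6
        cube = make_cube(vals, [{"county_id": 1, "pathway": "riparian_restoration",
                                 "sub_activity": "", "ownership": "na"}])
        row = summarize(cube, "total").iloc[0]
        assert row["median"] == pytest.approx(-50.5)
        assert row["p05"] == pytest.approx(-95.05)
        assert row["p95"] == pytest.approx(-5.95)

    def test_sd_zero_quantiles_collapse(self, small_bundle):
        bundle, _ = small_bundle
        cube = run_simulation(bundle, "moderate", n_iter=40, seed=3)
        s = summarize(cube, "total")
        assert np.allclose(s["median"], s["p05"]) and np.allclose(s["median"], s["p95"])

    def test_total_is_quantile_of_elementwise_sum(self):
        # anti-correlated pathways: median of sums != sum of medians
        rng = np.random.default_rng(0)
        a = rng.normal(-5, 2, size=101)
        b = np.where(a < -5, -1.0, -4.0)  # skewed, dependent on a
        vals = np.stack([a, b], axis=1)[:, :, None] * 1e6
        cube = make_cube(
            vals,
            [
                {"county_id": 1, "pathway": "riparian_restoration",
                 "sub_activity": "", "ownership": "na"},
                {"county_id": 1, "pathway": "tidal_wetland_restoration",
                 "sub_activity": "", "ownership": "na"},
            ],
        )
        total = summarize(cube, "total").iloc[0]["median"]
        per_path = summarize(cube, "pathway")
        sum_of_medians = per_path["median"].sum()
        brute = np.quantile(a + b, 0.5)
        assert total == pytest.approx(brute)
        assert total != pytest.approx(sum_of_medians)

    def test_total_aggregation_identity(self, default_bundle):
        bundle, _ = default_bundle
        cube = run_simulation(bundle, "limited", n_iter=30, seed=6)
        per_iter_total = cube.values.sum(axis=1)  # sum over series
        manual = np.quantile(per_iter_total / 1e6, 0.5, axis=0)
        s = summarize(cube, "total")
        assert np.allclose(s["median"].to_numpy(), manual)

    def test_county_grouping_partitions_total(self, small_bundle):
        bundle, _ = small_bundle
        cube = run_simulation(bundle, "ambitious", n_iter=1, seed=0)
        by_county = summarize(cube, "county")
        total = summarize(cube, "total")
        yr = by_county["year"] == 31
        # sd = 0, so medians are deterministic sums and must partition exactly
        assert by_county.loc[yr, "median"].sum() == pytest.approx(
            total.loc[total["year"] == 31, "median"].iloc[0]
        )

    def test_empty_cube_rejected(self):
        cube = make_cube(np.zeros((1, 0, 3)), pd.DataFrame(
            columns=["county_id", "pathway", "sub_activity", "ownership"]))
        with pytest.raises(ValidationError):
            summarize(cube, "total")

    def test_unknown_grouping_rejected(self, small_bundle):
        bundle, _ = small_bundle
        cube = run_simulation(bundle, "limited", n_iter=2, seed=1)
        with pytest.raises(ValidationError):
            summarize(cube, "watershed")

    def test_select_excludes_pathway(self, default_bundle):
        bundle, _ = default_bundle
        cube = run_simulation(bundle, "ambitious", n_iter=5, seed=8)
        sub = cube.select(exclude_pathways=("extended_rotation",))
        assert "extended_rotation" not in set(sub.index["pathway"])
        assert len(sub.index) < len(cube.index)
        # remaining series untouched
        keep = cube.index["pathway"] != "extended_rotation"
        assert np.array_equal(sub.values, cube.values[:, keep.to_numpy(), :])
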