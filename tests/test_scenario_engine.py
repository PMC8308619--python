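"""Trajectory construction: ramps, plateaus, caps, and the default registry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import limited_general, make_record
from ncspath.model_io import ValidationError
from ncspath.registry import ActivityKey
from ncspath.scenario_engine import (
    annual_increment,
    build_trajectory,
    params_for_county,
    scenario_defaults,
)


class TestAnnualIncrement:
    def test_ramp_year_three(self):
        assert annual_increment(limited_general(), 3, 50.0) == pytest.approx(15.0)

    def test_plateau_at_and_after_year_ten(self):
        p = limited_general()
        assert annual_increment(p, 10, 50.0) == pytest.approx(50.0)
        assert annual_increment(p, 25, 50.0) == pytest.approx(50.0)

    def test_post_decade_throttle_halves_increment(self):
        p = limited_general(post_decade_share=0.5)
        assert annual_increment(p, 20, 50.0) == pytest.approx(25.0)

    def test_year_out_of_range(self):
        with pytest.raises(ValidationError):
            annual_increment(limited_general(), 0, 1.0)
        with pytest.raises(ValidationError):
            annual_increment(limited_general(), 32, 1.0)


class TestBuildTrajectory:
    def test_zero_hv_gives_zero_trajectory(self):
        traj = build_trajectory(make_record(), 0.0, limited_general())
        assert np.all(traj.enrolled == 0)

    def test_uncapped_limited_closed_form(self):
        # ramp sums to 5.5*hv over the decade, then 21 years at hv
        traj = build_trajectory(make_record(), 10.0, limited_general())
        assert traj.enrolled[-1] == pytest.approx(265.0)
        assert traj.capped_at is None

    def test_cap_plateau_matches_bruteforce_cumsum(self):
        hv = 10.0
        record = make_record(max_resource=100.0)
        traj = build_trajectory(record, hv, limited_general())
        # independent brute force: cumulative of min(t/10,1)*hv clipped at 100
        cum, expect = 0.0, []
        for t in range(1, 32):
            cum += min(t * 0.1, 1.0) * hv if t <= 10 else hv
            expect.append(min(cum, 100.0))
        assert np.allclose(traj.enrolled, expect)
        assert traj.capped_at == next(
            t for t, e in enumerate(np.cumsum(
                [min(t * 0.1, 1.0) * hv if t <= 10 else hv for t in range(1, 32)]
            ), start=1) if e > 100.0
        )
        # additivity identity survives the cap
        assert np.allclose(np.cumsum(traj.increments), traj.enrolled)

    def test_enrollment_monotone_and_capped(self):
        record = make_record(max_resource=50.0)
        p = limited_general(cap_fraction=0.4)
        traj = build_trajectory(record, 5.0, p)
        assert np.all(np.diff(traj.enrolled) >= 0)
        assert traj.enrolled.max() <= 0.4 * 50.0 + 1e-12

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        hv=st.floats(0, 1e4, allow_nan=False),
        k=st.floats(0.1, 10, allow_nan=False),
        post=st.floats(0, 1, allow_nan=False),
    )
    def test_linearity_in_hv_when_uncapped(self, hv, k, post):
        p = limited_general(post_decade_share=post)
        t1 = build_trajectory(make_record(), hv, p)
        t2 = build_trajectory(make_record(), k * hv, p)
        assert np.allclose(t2.enrolled, k * t1.enrolled, rtol=1e-9, atol=1e-6)


class TestScenarioDefaults:
    def test_ambitious_timber_private_cap(self):
        reg = scenario_defaults()
        p = reg[("ambitious", ActivityKey("extended_rotation", "harvest", "private"))]
        assert p.cap_fraction == 0.40

    def test_ambitious_timber_state_cap(self):
        reg = scenario_defaults()
        p = reg[("ambitious", ActivityKey("extended_rotation", "harvest", "state"))]
        assert p.cap_fraction == 0.32

    def test_moderate_timber_growth_shares(self):
        reg = scenario_defaults()
        shares = {
            own: reg[
                ("moderate", ActivityKey("extended_rotation", "harvest", own))
            ].growth_share
            for own in ("private", "state", "federal", "other")
        }
        assert shares == {"private": 0.30, "state": 0.15, "federal": 0.75, "other": 0.75}

    def test_limited_general_rule(self):
        reg = scenario_defaults()
        p = reg[("limited", ActivityKey("riparian_restoration"))]
        assert p.growth_share == 1.0 and p.post_decade_share == 1.0

    def test_limited_timber_post_decade_half(self):
        reg = scenario_defaults()
        p = reg[("limited", ActivityKey("extended_rotation", "harvest", "private"))]
        assert p.post_decade_share == 0.5

    def test_registry_is_complete(self):
        reg = scenario_defaults()
        from ncspath.registry import ACTIVITY_REGISTRY

        assert len(reg) == 3 * len(ACTIVITY_REGISTRY)

    def test_override_replaces_single_field(self):
        key = ActivityKey("riparian_restoration")
        reg = scenario_defaults(
            [{"scenario": "moderate", "key": key, "growth_share": 0.7}]
        )
        assert reg[("moderate", key)].growth_share == 0.7
        assert reg[("moderate", key)].post_decade_share == 1.0

    def test_override_for_unknown_key_rejected(self):
        with pytest.raises(ValidationError):
            scenario_defaults(
                [{"scenario": "limited",
                  "key": ActivityKey("agriculture", "vertical_farming"),
                  "growth_share": 0.5}]
            )
        # valid key but out-of-range value must also fail
        with pytest.raises(ValidationError):
            scenario_defaults(
                [{"scenario": "limited",
                  "key": ActivityKey("agriculture", "no_till"),
                  "growth_share": 1.5}]
            )

    def test_east_counties_lift_ambitious_timber_caps(self):
        reg = scenario_defaults()
        key = ActivityKey("extended_rotation", "harvest", "private")
        west = params_for_county(reg[("ambitious", key)], "west")
        east = params_for_county(reg[("ambitious", key)], "east")
        assert west.cap_fraction == 0.40 and east.cap_fraction == 1.0
        # non-timber parameters pass through unchanged
        rip = reg[("ambitious", ActivityKey("riparian_restoration"))]
        assert params_for_county(rip, "east") is rip
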