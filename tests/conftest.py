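import math

import pytest

from ncspath.model_io import BaselineRecord, ScenarioParams
from ncspath.registry import ActivityKey
from ncspath.synthetic_data import SynthConfig, generate_bundle, load_bundle


def make_record(
    pathway: str = "riparian_restoration",
    sub: str = "",
    own: str = "na",
    county_id: int = 1,
    rate: float = 10.0,
    max_resource: float = math.inf,
    units: str = "ha_per_yr",
) -> BaselineRecord:
    return BaselineRecord(
        county_id=county_id,
        key=ActivityKey(pathway, sub, own),
        series=((0, rate),),
        units=units,
        max_resource=max_resource,
    )


def limited_general(key: ActivityKey | None = None, **kw) -> ScenarioParams:
    return ScenarioParams(
        scenario="limited",
        key=key or ActivityKey("riparian_restoration"),
        ramp_fraction=kw.get("ramp_fraction", 0.1),
        growth_share=kw.get("growth_share", 1.0),
        post_decade_share=kw.get("post_decade_share", 1.0),
        cap_fraction=kw.get("cap_fraction", 1.0),
        flux_mode=kw.get("flux_mode", "stock"),
    )


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A compact deterministic bundle (6 counties, sd=0, flat profiles)."""
    outdir = tmp_path_factory.mktemp("small_bundle")
    config = SynthConfig(n_counties=6, rate_rel_sd=0.0, with_age_profiles=False)
    paths, truth = generate_bundle(config, seed=13, outdir=outdir)
    return load_bundle(paths), truth


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The full default synthetic bundle (39 counties, age profiles, sd>0)."""
    outdir = tmp_path_factory.mktemp("default_bundle")
    paths, truth = generate_bundle(SynthConfig(), seed=7, outdir=outdir)
    return load_bundle(paths), truth
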