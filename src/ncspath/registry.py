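"""Closed registry of NCS pathways, sub-activities and ownerships.

The model tracks eight reporting pathways.  Three of them decompose into
finer activities: extended timber harvest rotations into four ownership
classes plus an added-sequestration activity on private even-aged stands;
cropland agriculture into cover crops, no-till and nutrient management;
avoided forest conversion into forest-to-urban and forest-to-rural.  Every
baseline, rate and scenario-parameter row must key into this registry —
unknown (pathway, sub_activity, ownership) combinations are rejected at
load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ActivityKey",
    "ActivitySpec",
    "PATHWAYS",
    "OWNERSHIPS",
    "UNITS",
    "ACTIVITY_REGISTRY",
    "TIMBER",
    "AGRICULTURE",
    "FOREST_CONVERSION",
    "RegistryError",
    "validate_key",
]


class RegistryError(ValueError):
    """A (pathway, sub_activity, ownership) combination is not registered."""


TIMBER = "extended_rotation"
AGRICULTURE = "agriculture"
FOREST_CONVERSION = "avoided_forest_conversion"

PATHWAYS = (
    TIMBER,
    AGRICULTURE,
    FOREST_CONVERSION,
    "avoided_sagebrush_conversion",
    "avoided_grassland_conversion",
    "riparian_restoration",
    "replanting_after_wildfire",
    "tidal_wetland_restoration",
)

OWNERSHIPS = ("private", "state", "federal", "other", "na")

# Activity units are carried as labels; a rate may only combine with a
# baseline when the labels match (guards against ha x per-volume products).
UNITS = ("ha_per_yr", "volume_per_yr", "kgN_per_yr")


@dataclass(frozen=True, order=True)
class ActivityKey:
    """Identifies one modelled activity: pathway, optional sub-activity, ownership."""

    pathway: str
    sub_activity: str = ""
    ownership: str = "na"

    def __post_init__(self) -> None:
        if self.pathway not in PATHWAYS:
            raise RegistryError(f"unknown pathway {self.pathway!r}")
        if self.ownership not in OWNERSHIPS:
            raise RegistryError(f"unknown ownership {self.ownership!r}")

    def label(self) -> str:
        parts = [self.pathway]
        if self.sub_activity:
            parts.append(self.sub_activity)
        if self.ownership != "na":
            parts.append(self.ownership)
        return "/".join(parts)


@dataclass(frozen=True)
class ActivitySpec:
    """Registry metadata for one activity."""

    units: str
    flux_mode: str = "stock"  # 'stock' or 'pulse'
    cohort: bool = False  # flux may depend on cohort age


def _timber_keys() -> dict[ActivityKey, ActivitySpec]:
    reg: dict[ActivityKey, ActivitySpec] = {}
    for own in ("private", "state", "federal", "other"):
        reg[ActivityKey(TIMBER, "harvest", own)] = ActivitySpec("volume_per_yr")
    # Added sequestration on deferred private even-aged stands: baseline is the
    # clearcut area entering deferral, flux follows stand age.
    reg[ActivityKey(TIMBER, "added_sequestration", "private")] = ActivitySpec(
        "ha_per_yr", cohort=True
    )
    return reg


ACTIVITY_REGISTRY: dict[ActivityKey, ActivitySpec] = {
    **_timber_keys(),
    ActivityKey(AGRICULTURE, "cover_crops"): ActivitySpec("ha_per_yr"),
    ActivityKey(AGRICULTURE, "no_till"): ActivitySpec("ha_per_yr"),
    ActivityKey(AGRICULTURE, "nutrient_mgmt"): ActivitySpec("kgN_per_yr"),
    ActivityKey(FOREST_CONVERSION, "forest_to_urban"): ActivitySpec("ha_per_yr"),
    ActivityKey(FOREST_CONVERSION, "forest_to_rural"): ActivitySpec("ha_per_yr"),
    ActivityKey("avoided_sagebrush_conversion"): ActivitySpec("ha_per_yr"),
    ActivityKey("avoided_grassland_conversion"): ActivitySpec("ha_per_yr"),
    ActivityKey("riparian_restoration"): ActivitySpec("ha_per_yr"),
    ActivityKey("replanting_after_wildfire", "", "federal"): ActivitySpec(
        "ha_per_yr", cohort=True
    ),
    ActivityKey("tidal_wetland_restoration"): ActivitySpec("ha_per_yr"),
}


def validate_key(key: ActivityKey) -> ActivitySpec:
    """Return the registry entry for ``key`` or raise :class:`RegistryError`."""
    try:
        return ACTIVITY_REGISTRY[key]
    except KeyError:
        raise RegistryError(
            f"activity {key.label()!r} is not in the closed registry"
        ) from None
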