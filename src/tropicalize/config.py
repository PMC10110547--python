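"""Scenario configuration for the synthetic metacommunity generator.

A :class:`ScenarioConfig` describes the study design being emulated: two
regions (one per hemisphere) of reef sites spanning a tropical-to-temperate
latitudinal gradient, grouped into contiguous latitude-band zones, with a
species pool organised into trait-defined functional groups whose tropical
members decline poleward (each group at its own configured 20-fold-decline
latitude) and whose temperate members increase.

Configurations are plain dataclasses validated eagerly, and round-trip
through YAML so scenarios can be kept under version control.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

#: Sentinel accepted for a group whose tropical biomass never reaches the
#: 20-fold decline inside the surveyed latitude range.
NEVER = "never"

DIET_LEVELS = ("herbivore", "omnivore", "planktivore", "predator", "corallivore")
HABITAT_LEVELS = ("benthic", "upper-benthic", "demersal")
AGGREGATION_LEVELS = (1, 2, 3, 4, 5)


class ConfigurationError(ValueError):
    """Raised when a scenario field is out of its documented domain."""


@dataclass
class RegionConfig:
    name: str
    hemisphere: int  # +1 northern, -1 southern (sign applied to latitudes)
    n_sites: int

    def validate(self) -> None:
        if self.hemisphere not in (-1, 1):
            raise ConfigurationError(f"region {self.name}: hemisphere must be +1 or -1")
        if self.n_sites < 1:
            raise ConfigurationError(f"region {self.name}: n_sites must be positive")


@dataclass
class GroupArchetype:
    """Modal trait values and gradient parameters for one functional group.

    ``fold_decline_latitude`` is the absolute latitude at which the group's
    expected tropical biomass equals 1/20 of its expectation at the
    reference-zone centre; ``"never"`` means the decline stays above 1/20
    across the whole gradient.  Tropical-temperate niche sharing is
    controlled by three knobs applied to the temperate guild:
    ``guild_trait_offset`` (log-scale shift of depth range),
    ``guild_aggregation_offset`` (shift of the ordinal aggregation level —
    the effective separator in PCoA space) and ``temperate_sigma_scale``
    (breadth of the continuous traits); all zero/one means the guilds are
    drawn from the same trait distribution.
    """

    name: str
    diet: str
    habitat: str
    body_size_cm: float
    aggregation: int
    depth_range_m: float
    n_species: int
    frac_tropical: float
    fold_decline_latitude: float | str
    reference_biomass: float  # expected group tropical biomass (g/m²) at reference-zone centre
    guild_trait_offset: float = 0.0
    guild_aggregation_offset: int = 0  # added to temperate members' aggregation level
    temperate_sigma_scale: float = 1.0  # breadth of the temperate guild's continuous traits
    temperate_reference_biomass: Optional[float] = None  # defaults to reference_biomass/4

    def validate(self, latitude_range: tuple[float, float]) -> None:
        if self.diet not in DIET_LEVELS:
            raise ConfigurationError(f"group {self.name}: diet {self.diet!r} not in {DIET_LEVELS}")
        if self.habitat not in HABITAT_LEVELS:
            raise ConfigurationError(
                f"group {self.name}: habitat {self.habitat!r} not in {HABITAT_LEVELS}"
            )
        if self.aggregation not in AGGREGATION_LEVELS:
            raise ConfigurationError(f"group {self.name}: aggregation must be in 1..5")
        if self.body_size_cm <= 0:
            raise ConfigurationError(f"group {self.name}: body_size_cm must be > 0")
        if self.depth_range_m <= 0:
            raise ConfigurationError(f"group {self.name}: depth_range_m must be > 0")
        if self.n_species < 1:
            raise ConfigurationError(f"group {self.name}: n_species must be positive")
        if not 0.0 <= self.frac_tropical <= 1.0:
            raise ConfigurationError(f"group {self.name}: frac_tropical must lie in [0, 1]")
        if self.reference_biomass <= 0:
            raise ConfigurationError(f"group {self.name}: reference_biomass must be > 0")
        if self.temperate_sigma_scale <= 0:
            raise ConfigurationError(f"group {self.name}: temperate_sigma_scale must be > 0")
        lo, hi = latitude_range
        if self.fold_decline_latitude != NEVER:
            lat = float(self.fold_decline_latitude)  # type: ignore[arg-type]
            if not lo < lat:
                raise ConfigurationError(
                    f"group {self.name}: fold_decline_latitude {lat} must exceed the "
                    f"equatorward edge {lo} (or be 'never')"
                )


@dataclass
class ScenarioConfig:
    regions: list[RegionConfig]
    groups: list[GroupArchetype]
    latitude_range: tuple[float, float] = (23.0, 35.0)
    n_zones: int = 6
    transects_per_site: int = 4
    temperate_trend_slope: float = 1.2  # per-degree multiplier for temperate biomass
    noise_sigma: float = 0.5  # lognormal sigma for per-species transect biomass
    detection_exponent: float = 0.15  # presence prob ∝ decline-factor^exponent
    trait_flip_prob: float = 0.005  # nominal trait deviation from archetype
    trait_log_sigma: float = 0.35  # log-scale sd of body size / depth range
    aggregation_jitter_prob: float = 0.10
    missingness: dict = field(
        default_factory=lambda: {"depth_range": 0.033, "diet": 0.002}
    )
    thermal_limit_means: dict = field(
        default_factory=lambda: {"tropical": 31.0, "temperate": 26.0}
    )
    thermal_limit_sd: float = 1.0
    seed: int = 0

    # ------------------------------------------------------------------
    @property
    def n_species(self) -> int:
        return sum(g.n_species for g in self.groups)

    @property
    def zone_edges(self):
        import numpy as np

        lo, hi = self.latitude_range
        return np.linspace(lo, hi, self.n_zones + 1)

    @property
    def zone_centres(self):
        e = self.zone_edges
        return (e[:-1] + e[1:]) / 2.0

    def validate(self) -> None:
        if not self.regions:
            raise ConfigurationError("regions: at least one region required")
        for r in self.regions:
            r.validate()
        if not self.groups:
            raise ConfigurationError("groups: at least one group required")
        lo, hi = self.latitude_range
        if not lo < hi:
            raise ConfigurationError("latitude_range: must be (low, high) with low < high")
        if lo < 0 or hi > 90:
            raise ConfigurationError("latitude_range: absolute degrees in [0, 90]")
        if self.n_zones < 2:
            raise ConfigurationError("n_zones: must be >= 2")
        if not 3 <= self.transects_per_site <= 5:
            raise ConfigurationError("transects_per_site: must be in 3..5")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma: must be >= 0")
        if self.temperate_trend_slope <= 0:
            raise ConfigurationError("temperate_trend_slope: must be > 0")
        for trait, rate in self.missingness.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"missingness[{trait}]: rate must lie in [0, 1]")
        for g in self.groups:
            g.validate(self.latitude_range)
        if len(self.groups) > self.n_species:
            raise ConfigurationError("groups: n_groups cannot exceed n_species")

    # ------------------------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["latitude_range"] = list(self.latitude_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["regions"] = [RegionConfig(**r) for r in d["regions"]]
        d["groups"] = [GroupArchetype(**g) for g in d["groups"]]
        d["latitude_range"] = tuple(d["latitude_range"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def default_scenario(seed: int = 0, n_sites: int = 30,
                     scale: float = 1.0) -> ScenarioConfig:
    """The default two-region, nine-group study scenario.

    Emulates the design of a tropical-to-temperate reef survey: two regions
    (one per hemisphere), ``n_sites`` sites each spanning 23-35° absolute
    latitude in six 2°-wide zones, four transects per site, 300 species in
    nine trait-defined functional groups.  Four species-rich "generalist"
    groups carry most of the biomass, share trait space across thermal
    guilds (zero guild offset) and decline 20-fold only in the most
    poleward zone; the remaining groups have progressively lower guild
    overlap and more equatorward decline points; corallivores have no
    temperate members at all.  ``scale`` multiplies per-group species
    counts (rounded, min 6) for reduced-size runs.
    """

    def n(k: int) -> int:
        return max(6, round(k * scale))

    groups = [
        GroupArchetype("Benthic Predators", "predator", "benthic", 45.0, 1, 35.0,
                       n(60), 0.65, 33.3, 50.0, 0.0, 0, 2.0),
        GroupArchetype("Upper-benthic Predators", "predator", "upper-benthic", 60.0, 2, 40.0,
                       n(45), 0.65, 33.3, 50.0, 0.0, 0, 2.0),
        GroupArchetype("Benthic Herbivore/Omnivores", "herbivore", "benthic", 25.0, 2, 20.0,
                       n(40), 0.70, 33.3, 50.0, 0.0, 0, 2.0),
        GroupArchetype("Upper-benthic Planktivores", "planktivore", "upper-benthic", 12.0, 4, 30.0,
                       n(35), 0.70, 33.3, 50.0, 0.0, 0, 2.0),
        GroupArchetype("Upper-benthic Omnivores", "omnivore", "upper-benthic", 18.0, 3, 22.0,
                       n(30), 0.65, 31.0, 5.0, 0.9, 1, 1.0),
        GroupArchetype("Upper-benthic Herbivores", "herbivore", "upper-benthic", 30.0, 3, 15.0,
                       n(28), 0.75, 25.5, 5.0, 1.5, 2, 0.8),
        GroupArchetype("Demersal Predators", "predator", "demersal", 80.0, 1, 60.0,
                       n(22), 0.60, 29.3, 5.0, 1.5, 2, 0.8),
        GroupArchetype("Benthic Planktivores", "planktivore", "benthic", 8.0, 3, 25.0,
                       n(22), 0.70, 29.3, 5.0, 1.5, 2, 0.8),
        GroupArchetype("Corallivores", "corallivore", "benthic", 14.0, 2, 18.0,
                       n(18), 1.00, 29.3, 5.0, 0.0),
    ]
    cfg = ScenarioConfig(
        regions=[
            RegionConfig("Australia", -1, n_sites),
            RegionConfig("Japan", +1, n_sites),
        ],
        groups=groups,
        seed=seed,
    )
    cfg.validate()
    return cfg
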