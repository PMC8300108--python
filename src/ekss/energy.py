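"""Digestible-energy and crude-protein requirements and ration intake.

Maintenance requirements follow the National Research Council (NRC)
nutrient-requirement convention: an adult horse at maintenance needs
``coefficient x body weight`` Mcal of digestible energy (DE) per day, with
a minimum / average / elevated tier for temperament and metabolic
differences, and working horses scaled by a workload multiplier on the
average tier. Crude protein (CP) requirements are likewise linear in body
weight with a per-workload coefficient. The coefficients ship as an
editable configuration — they come from the standard NRC tables, and users
with different editions or special cases can override every number.

Ration intake sums as-fed kilograms and nutrient densities over feed items.
Ad-libitum forage (pasture or free hay) is estimated from access time at a
configurable ingestion rate and capped by the rule that a horse can ingest
up to 2% of its body weight per day: with 16+ hours of access the ad-lib
pool is filled up to that 2% threshold minus all other offered feed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

from ekss.errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)

MAINTENANCE_TIERS: tuple[str, ...] = ("minimum", "average", "elevated")
WORKLOADS: tuple[str, ...] = ("no_work", "light", "moderate", "heavy", "very_heavy")

_DEFAULT_DE = {"minimum": 0.0303, "average": 0.0333, "elevated": 0.0363}
_DEFAULT_WORK_MULT = {
    "no_work": 1.0,
    "light": 1.20,
    "moderate": 1.40,
    "heavy": 1.60,
    "very_heavy": 1.90,
}
# g CP per kg BW per day; adult maintenance 1.26, working tiers per NRC-style
# tables (overridable).
_DEFAULT_CP = {
    "no_work": 1.26,
    "light": 1.40,
    "moderate": 1.54,
    "heavy": 1.72,
    "very_heavy": 2.01,
}


@dataclass(frozen=True)
class RequirementConfig:
    """Coefficient tables for DE and CP maintenance requirements.

    ``special_type_overrides`` maps a horse type (growing, pregnant,
    lactating, ...) to absolute daily requirements
    ``{"de_mcal_per_day": x, "cp_g_per_day": y}``; there are no built-in
    guesses for these physiological states.
    """

    de_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DE)
    )
    workload_multipliers: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_WORK_MULT)
    )
    cp_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CP)
    )
    adlib_rate: float = 0.8  # kg as fed per hour of access
    special_type_overrides: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for tier in MAINTENANCE_TIERS:
            if tier not in self.de_coefficients:
                raise ConfigError(f"de_coefficients missing tier '{tier}'")
        for table_name, table in (
            ("de_coefficients", self.de_coefficients),
            ("workload_multipliers", self.workload_multipliers),
            ("cp_coefficients", self.cp_coefficients),
        ):
            for key, value in table.items():
                if not value > 0:
                    raise ConfigError(
                        f"{table_name}['{key}'] must be > 0, got {value!r}"
                    )
        if self.workload_multipliers.get("no_work") != 1.0:
            raise ConfigError("workload_multipliers['no_work'] must equal 1.0")
        if not self.adlib_rate > 0:
            raise ConfigError(f"adlib_rate must be > 0, got {self.adlib_rate!r}")

    def with_overrides(self, **kwargs) -> "RequirementConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class FeedItem:
    """One daily feed source, as fed.

    For weighed (offered) feeds, ``kg_per_day`` is the daily amount. For
    ad-libitum items (pasture, free-choice hay) the ingested amount is
    estimated from ``access_hours`` and the ingestion rate, so
    ``kg_per_day`` is ignored and may be 0.
    """

    name: str
    kg_per_day: float = 0.0
    de_density: float = 0.0  # Mcal per kg as fed
    cp_density: float = 0.0  # g per kg as fed
    ad_libitum: bool = False
    access_hours: float = 0.0
    adlib_rate: Optional[float] = None  # kg/h; falls back to config rate

    def __post_init__(self) -> None:
        if self.kg_per_day < 0:
            raise ValidationError(
                f"feed '{self.name}': kg_per_day must be >= 0, got {self.kg_per_day!r}"
            )
        if self.de_density < 0 or self.cp_density < 0:
            raise ValidationError(
                f"feed '{self.name}': nutrient densities must be >= 0"
            )
        if not 0.0 <= self.access_hours <= 24.0:
            raise ValidationError(
                f"feed '{self.name}': access_hours must be in [0, 24], "
                f"got {self.access_hours!r}"
            )
        if self.adlib_rate is not None and self.adlib_rate <= 0:
            raise ValidationError(
                f"feed '{self.name}': adlib_rate must be > 0 when given"
            )


@dataclass(frozen=True)
class RationIntake:
    """Resolved daily intake of a ration."""

    total_kg: float
    dei_mcal: float
    cpi_g: float
    resolved_kg: Mapping[str, float]  # per feed item, ad-lib amounts filled in


@dataclass(frozen=True)
class EnergyProfile:
    """Requirements and intakes for one horse, with the derived percentages."""

    de_m: float  # Mcal/day maintenance DE requirement
    cp_m: float  # g/day maintenance CP requirement
    dei: float  # Mcal/day DE intake (symbol D)
    cpi: float  # g/day CP intake
    total_kg: float  # kg/day as fed
    dei_percent: float  # 100 * dei / de_m
    cpi_percent: float  # 100 * cpi / cp_m
    total_intake_percent: float  # 100 * total_kg / bw


def _check_bw(bw: float) -> float:
    bw = float(bw)
    if not bw > 0:
        raise ValidationError(f"body weight must be > 0 kg, got {bw!r}")
    return bw


def de_maintenance(
    bw: float,
    tier: str = "average",
    workload: str = "no_work",
    config: Optional[RequirementConfig] = None,
    horse_type: Optional[str] = None,
) -> float:
    """Daily digestible-energy maintenance requirement, Mcal/day.

    Idle horses use the tier coefficient; working horses use the average
    tier scaled by the workload multiplier. Special physiological types
    (growing, pregnant, lactating) resolve only through explicit absolute
    overrides in the config.
    """
    config = config or RequirementConfig()
    bw = _check_bw(bw)
    if horse_type is not None:
        try:
            return float(config.special_type_overrides[horse_type]["de_mcal_per_day"])
        except KeyError:
            raise ConfigError(
                f"horse type '{horse_type}' has no de_mcal_per_day override; "
                f"configured types: {sorted(config.special_type_overrides)}"
            ) from None
    if tier not in config.de_coefficients:
        raise ValidationError(
            f"unknown maintenance tier '{tier}'; "
            f"valid: {sorted(config.de_coefficients)}"
        )
    if workload not in config.workload_multipliers:
        raise ValidationError(
            f"unknown workload '{workload}'; "
            f"valid: {sorted(config.workload_multipliers)}"
        )
    if workload == "no_work":
        return config.de_coefficients[tier] * bw
    return (
        config.de_coefficients["average"]
        * config.workload_multipliers[workload]
        * bw
    )


def cp_maintenance(
    bw: float,
    workload: str = "no_work",
    config: Optional[RequirementConfig] = None,
    horse_type: Optional[str] = None,
) -> float:
    """Daily crude-protein requirement, g/day (linear in body weight)."""
    config = config or RequirementConfig()
    bw = _check_bw(bw)
    if horse_type is not None:
        try:
            return float(config.special_type_overrides[horse_type]["cp_g_per_day"])
        except KeyError:
            raise ConfigError(
                f"horse type '{horse_type}' has no cp_g_per_day override"
            ) from None
    if workload not in config.cp_coefficients:
        raise ValidationError(
            f"unknown workload '{workload}'; valid: {sorted(config.cp_coefficients)}"
        )
    return config.cp_coefficients[workload] * bw


def ration_intake(
    ration: Sequence[FeedItem],
    bw: float,
    config: Optional[RequirementConfig] = None,
) -> RationIntake:
    """Resolve a ration into total kg, DE intake (Mcal) and CP intake (g).

    Offered (weighed) items contribute their stated kg. Ad-libitum items
    share a single allocation pool of ``max(0, 0.02 x bw - offered_kg)``
    kilograms: each item's potential intake is ``rate x access_hours`` and
    potentials are scaled down proportionally when they exceed the pool,
    so ad-lib feed never pushes total intake past 2% of body weight.
    """
    config = config or RequirementConfig()
    bw = _check_bw(bw)
    offered = [f for f in ration if not f.ad_libitum]
    adlib = [f for f in ration if f.ad_libitum]
    offered_kg = sum(f.kg_per_day for f in offered)
    resolved: dict[str, float] = {f.name: f.kg_per_day for f in offered}

    if adlib:
        pool = max(0.0, 0.02 * bw - offered_kg)
        potentials = {
            f.name: (f.adlib_rate if f.adlib_rate is not None else config.adlib_rate)
            * f.access_hours
            for f in adlib
        }
        total_potential = sum(potentials.values())
        scale = 1.0 if total_potential <= pool else (
            pool / total_potential if total_potential > 0 else 0.0
        )
        for f in adlib:
            resolved[f.name] = potentials[f.name] * scale

    by_name = {f.name: f for f in ration}
    if len(by_name) != len(ration):
        raise ValidationError("feed item names within a ration must be unique")
    total_kg = sum(resolved.values())
    dei = sum(kg * by_name[name].de_density for name, kg in resolved.items())
    cpi = sum(kg * by_name[name].cp_density for name, kg in resolved.items())
    return RationIntake(total_kg=total_kg, dei_mcal=dei, cpi_g=cpi, resolved_kg=resolved)


def energy_profile(
    bw: float,
    ration: Sequence[FeedItem],
    tier: str = "average",
    workload: str = "no_work",
    config: Optional[RequirementConfig] = None,
    horse_type: Optional[str] = None,
) -> EnergyProfile:
    """Requirements, intakes and the derived percentages for one horse.

    ``dei_percent`` is DE intake relative to the DE maintenance requirement,
    ``cpi_percent`` likewise for crude protein, and ``total_intake_percent``
    is total as-fed kilograms relative to body weight.
    """
    config = config or RequirementConfig()
    bw = _check_bw(bw)
    de_m = de_maintenance(bw, tier=tier, workload=workload, config=config,
                          horse_type=horse_type)
    cp_m = cp_maintenance(bw, workload=workload, config=config,
                          horse_type=horse_type)
    intake = ration_intake(ration, bw, config=config)
    return EnergyProfile(
        de_m=de_m,
        cp_m=cp_m,
        dei=intake.dei_mcal,
        cpi=intake.cpi_g,
        total_kg=intake.total_kg,
        dei_percent=100.0 * intake.dei_mcal / de_m,
        cpi_percent=100.0 * intake.cpi_g / cp_m,
        total_intake_percent=100.0 * intake.total_kg / bw,
    )
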