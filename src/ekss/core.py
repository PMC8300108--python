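"""The Equine Keeper Status Scale: equations and classification.

The scale combines three quantities per horse — the overall body condition
score (BCS), the digestible-energy maintenance requirement DE_M (Mcal/day)
and the digestible-energy intake DEI (Mcal/day) — through three equations:

    B = ideal_BCS - A                    (BCS deficit; A is the overall BCS)
    C = B x DE_M x dDE                   (Mcal adjustment to reach ideal BCS)
    RDI5% = (D + C) / DE_M x 100         (D = DEI; recommended dietary intake
                                          as a percent of maintenance)

dDE is the per-BCS-unit energy adjustment fraction; the NRC band is 10-15%
per BCS unit and the default here is 12.5%. RDI5% — the intake needed to
drive the horse to the ideal BCS of 5 — is the classification variable: a
horse that would reach ideal condition on much less than maintenance is an
easy keeper (EK), one needing much more is a hard keeper (HK), and one near
maintenance is a medium keeper (MK). Seven finer levels (E+, E, M+, M, M-,
H, H-) subdivide the three groups.

The three equations collapse algebraically to the closed form

    RDI5% = DEI% + (ideal_BCS - BCS) x dDE x 100

which is scale-invariant in body weight: doubling BW doubles both DE_M and
(for the same relative ration) DEI, leaving RDI5% and the classification
unchanged.

The group/level RDI5% cutoffs are configuration. The defaults shipped here
are provisional fallbacks built from the NRC 10-15%-per-BCS-unit rule (the
published figure with the exact ranges is not machine-readable); they place
one level per ~15% band around maintenance and are flagged as provisional
in the config.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from ekss.bcs import BCSAssessment
from ekss.energy import EnergyProfile
from ekss.errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)

GROUPS: tuple[str, ...] = ("EK", "MK", "HK")
LEVELS: tuple[str, ...] = ("E+", "E", "M+", "M", "M-", "H", "H-")

LEVEL_TO_GROUP = {
    "E+": "EK",
    "E": "EK",
    "M+": "MK",
    "M": "MK",
    "M-": "MK",
    "H": "HK",
    "H-": "HK",
}


@dataclass(frozen=True)
class LevelBand:
    """One level's RDI5% interval; ``lower``/``upper`` may be +-inf."""

    level: str
    lower: float
    upper: float
    lower_inclusive: bool
    upper_inclusive: bool

    def contains(self, x: float) -> bool:
        lo = x >= self.lower if self.lower_inclusive else x > self.lower
        hi = x <= self.upper if self.upper_inclusive else x < self.upper
        return lo and hi


# Provisional fallback cutoffs (see module docstring). Intervals are
# half-open toward the hard-keeper direction below the central M band and
# toward the easy-keeper direction above it, so the bands tile the line.
_FALLBACK_BANDS: tuple[LevelBand, ...] = (
    LevelBand("E+", -math.inf, 75.0, False, False),
    LevelBand("E", 75.0, 90.0, True, False),
    LevelBand("M+", 90.0, 95.0, True, False),
    LevelBand("M", 95.0, 105.0, True, True),
    LevelBand("M-", 105.0, 110.0, False, True),
    LevelBand("H", 110.0, 125.0, False, True),
    LevelBand("H-", 125.0, math.inf, False, False),
)


@dataclass(frozen=True)
class EKSSConfig:
    """Scale configuration: ideal BCS, adjustment rate and classification bands.

    ``delta_de`` outside the NRC 10-15% band is allowed (the scale is
    explicitly tunable to managers' preferences) but logs a warning.
    """

    ideal_bcs: float = 5.0
    delta_de: float = 0.125
    level_bands: tuple[LevelBand, ...] = field(default=_FALLBACK_BANDS)

    def __post_init__(self) -> None:
        if not 1.0 <= self.ideal_bcs <= 9.0:
            raise ConfigError(
                f"ideal_bcs must lie on the 1-9 scale, got {self.ideal_bcs!r}"
            )
        if not self.delta_de > 0:
            raise ConfigError(f"delta_de must be > 0, got {self.delta_de!r}")
        if not 0.10 <= self.delta_de <= 0.15:
            logger.warning(
                "delta_de=%.4g is outside the NRC-recommended 10-15%% per BCS "
                "unit band", self.delta_de,
            )
        self._validate_bands()

    def _validate_bands(self) -> None:
        bands = self.level_bands
        if tuple(b.level for b in bands) != LEVELS:
            raise ConfigError(
                f"level bands must cover exactly {LEVELS} in order, got "
                f"{tuple(b.level for b in bands)}"
            )
        if not (math.isinf(bands[0].lower) and math.isinf(bands[-1].upper)):
            raise ConfigError("outermost bands must be unbounded (+-inf)")
        for left, right in zip(bands, bands[1:]):
            if left.upper != right.lower:
                raise ConfigError(
                    f"bands '{left.level}' and '{right.level}' do not share a "
                    f"boundary ({left.upper} vs {right.lower})"
                )
            if left.upper_inclusive == right.lower_inclusive:
                raise ConfigError(
                    f"boundary {left.upper} between '{left.level}' and "
                    f"'{right.level}' must belong to exactly one band"
                )
            if not left.upper < right.upper:
                raise ConfigError("band boundaries must be strictly increasing")

    def group_bands(self) -> dict[str, tuple[float, float]]:
        """Group RDI5% ranges derived from the level bands (levels nest exactly)."""
        out: dict[str, tuple[float, float]] = {}
        for group in GROUPS:
            members = [b for b in self.level_bands if LEVEL_TO_GROUP[b.level] == group]
            out[group] = (members[0].lower, members[-1].upper)
        return out


@dataclass(frozen=True)
class EKSSResult:
    """Derived quantities and assignment for one horse."""

    a: float  # overall BCS
    b: float  # BCS deficit, ideal - a
    c: float  # Mcal/day adjustment
    d: float  # DEI, Mcal/day
    de_m: float  # maintenance requirement, Mcal/day
    rdi5_percent: float
    group: str
    level: str


def bcs_deficit(a: float, ideal: float = 5.0) -> float:
    """BCS deficit B = ideal - A; positive for under-conditioned horses."""
    a = float(a)
    if not 1.0 <= a <= 9.0:
        raise ValidationError(f"BCS must lie on the 1-9 scale, got {a!r}")
    return ideal - a


def energy_adjustment(b: float, de_m: float, delta_de: float = 0.125) -> float:
    """Mcal/day adjustment C = B x DE_M x dDE; sign follows the deficit."""
    if not de_m > 0:
        raise ValidationError(f"DE_M must be > 0 Mcal/day, got {de_m!r}")
    if not delta_de > 0:
        raise ValidationError(f"delta_de must be > 0, got {delta_de!r}")
    return b * de_m * delta_de


def rdi5(d: float, c: float, de_m: float) -> float:
    """Recommended dietary intake percent, RDI5% = (D + C) / DE_M x 100."""
    if not de_m > 0:
        raise ValidationError(f"DE_M must be > 0 Mcal/day, got {de_m!r}")
    if d < 0:
        raise ValidationError(f"DEI must be >= 0 Mcal/day, got {d!r}")
    return (d + c) / de_m * 100.0


def classify(
    rdi5_percent: float,
    config: Optional[EKSSConfig] = None,
) -> tuple[str, str]:
    """Map an RDI5% value to its (group, level) under the configured bands.

    The bands tile the real line, so every finite value maps to exactly one
    level; values landing exactly on a boundary log a warning because a
    measurement that precise is suspicious in field data.
    """
    config = config or EKSSConfig()
    x = float(rdi5_percent)
    if not math.isfinite(x):
        raise ValidationError(f"RDI5% must be finite, got {rdi5_percent!r}")
    for band in config.level_bands:
        if band.contains(x):
            if x in (band.lower, band.upper):
                logger.warning(
                    "RDI5%%=%.6g falls exactly on a band boundary; assigned "
                    "level '%s'", x, band.level,
                )
            return LEVEL_TO_GROUP[band.level], band.level
    raise ConfigError(  # pragma: no cover - bands are validated to tile
        f"no level band contains RDI5%={x!r}"
    )


def assign(
    bcs_assessment: BCSAssessment,
    profile: EnergyProfile,
    config: Optional[EKSSConfig] = None,
) -> EKSSResult:
    """Run the full scale for one horse: equations plus classification."""
    config = config or EKSSConfig()
    a = bcs_assessment.overall_bcs
    b = bcs_deficit(a, ideal=config.ideal_bcs)
    c = energy_adjustment(b, profile.de_m, delta_de=config.delta_de)
    r = rdi5(profile.dei, c, profile.de_m)
    group, level = classify(r, config)
    return EKSSResult(
        a=a, b=b, c=c, d=profile.dei, de_m=profile.de_m,
        rdi5_percent=r, group=group, level=level,
    )


def bands_from_spec(spec: Sequence[dict]) -> tuple[LevelBand, ...]:
    """Build level bands from a config-file list of dicts.

    Each entry: ``{level, lower, upper, lower_inclusive, upper_inclusive}``
    with ``lower``/``upper`` omitted (or null) for unbounded outer bands.
    """
    bands = []
    for entry in spec:
        try:
            lower = (
                float(entry["lower"])
                if entry.get("lower") is not None else -math.inf
            )
            upper = (
                float(entry["upper"])
                if entry.get("upper") is not None else math.inf
            )
            bands.append(
                LevelBand(
                    level=entry["level"],
                    lower=lower,
                    upper=upper,
                    # inclusivity at an infinite edge is vacuous; pin it
                    # False so equal configs compare equal
                    lower_inclusive=bool(entry.get("lower_inclusive", True))
                    and math.isfinite(lower),
                    upper_inclusive=bool(entry.get("upper_inclusive", False))
                    and math.isfinite(upper),
                )
            )
        except KeyError as exc:
            raise ConfigError(f"level band entry missing key {exc}") from None
    return tuple(bands)
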