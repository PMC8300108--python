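"""Body condition scoring.

Implements the Kohnke modification of the Henneke nine-point body condition
score (BCS): six body regions — tailhead, crease down the back, crest of the
neck, withers, ribs, and behind the shoulder — are each scored on a 1–9
scale and averaged into a cumulative BCS per scorer; cumulative scores from
independent (typically blinded) scorers are averaged into the overall BCS.

Also provides the BCS rank partition (lean < 5, normal 5–6, obese > 6) and
the estimated total body fat equation of Dugdale et al.,

    eTBF% = 0.006 + 1.56 x BCS,

a linear map from condition score to percent body fat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ekss.errors import ValidationError

#: The six regions of the Kohnke modification, scored independently.
REGIONS: tuple[str, ...] = (
    "tailhead",
    "crease_down_back",
    "crest_of_neck",
    "withers",
    "ribs",
    "behind_shoulder",
)

#: BCS rank labels and their boundaries (closed "normal" interval).
RANKS: tuple[str, ...] = ("lean", "normal", "obese")

_ETBF_INTERCEPT = 0.006
_ETBF_SLOPE = 1.56


def _check_score(value: float, *, what: str) -> float:
    value = float(value)
    if not 1.0 <= value <= 9.0:
        raise ValidationError(
            f"{what} is {value!r}; scores must lie on the 1-9 scale"
        )
    return value


@dataclass(frozen=True)
class RegionalScores:
    """One scorer's regional scores for one horse.

    Fractional scores (half points or finer) are accepted; no rounding is
    applied anywhere in the scoring chain.
    """

    scores_by_region: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [r for r in REGIONS if r not in self.scores_by_region]
        if missing:
            raise ValidationError(
                f"missing regional score(s): {', '.join(missing)}"
            )
        unknown = [r for r in self.scores_by_region if r not in REGIONS]
        if unknown:
            raise ValidationError(
                f"unknown region(s): {', '.join(unknown)}; "
                f"expected {', '.join(REGIONS)}"
            )
        for region in REGIONS:
            _check_score(self.scores_by_region[region], what=f"region '{region}'")

    def cumulative(self) -> float:
        return sum(self.scores_by_region[r] for r in REGIONS) / len(REGIONS)


@dataclass(frozen=True)
class BCSAssessment:
    """Overall body condition derived from one or more scorers."""

    per_scorer_cumulative: tuple[float, ...]
    overall_bcs: float
    rank: str = field(init=False)
    etbf_percent: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rank", bcs_rank(self.overall_bcs))
        object.__setattr__(self, "etbf_percent", etbf(self.overall_bcs))


def cumulative_bcs(regional: RegionalScores | Mapping[str, float]) -> float:
    """Average the six regional scores into a cumulative BCS.

    Parameters
    ----------
    regional
        A :class:`RegionalScores` or a plain mapping of region name to score.

    Returns
    -------
    float
        Arithmetic mean of the six regional scores, in [1, 9].
    """
    if not isinstance(regional, RegionalScores):
        regional = RegionalScores(dict(regional))
    return regional.cumulative()


def overall_bcs(
    assessments: Sequence[RegionalScores | Mapping[str, float]],
) -> BCSAssessment:
    """Average per-scorer cumulative scores into the overall BCS.

    Any positive number of scorers is accepted; the field protocol used two
    blinded scorers but the average is defined for one or many.
    """
    if len(assessments) == 0:
        raise ValidationError("at least one scorer's assessment is required")
    cumulative = tuple(cumulative_bcs(a) for a in assessments)
    overall = sum(cumulative) / len(cumulative)
    return BCSAssessment(per_scorer_cumulative=cumulative, overall_bcs=overall)


def bcs_rank(bcs: float) -> str:
    """Rank a BCS as ``lean`` (< 5), ``normal`` (5–6, closed) or ``obese`` (> 6)."""
    bcs = _check_score(bcs, what="BCS")
    if bcs < 5.0:
        return "lean"
    if bcs <= 6.0:
        return "normal"
    return "obese"


def etbf(bcs: float) -> float:
    """Estimated total body fat, percent, from BCS.

    eTBF% = 0.006 + 1.56 x BCS (Dugdale et al. equation). Strictly
    increasing: 1.56 percentage points of body fat per BCS unit.
    """
    bcs = _check_score(bcs, what="BCS")
    return _ETBF_INTERCEPT + _ETBF_SLOPE * bcs
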