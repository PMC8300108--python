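"""Cohort-level summaries and agreement statistics.

Covers the descriptive statistics used to evaluate the scale on a cohort:
distributions of keeper statuses / levels / BCS ranks, agreement between
owner-reported keeper status (ORKS) and the scale's assignments,
nonparametric between-group comparisons (Kruskal-Wallis omnibus plus
pairwise Wilcoxon rank-sum with Benjamini-Hochberg correction and a compact
letter display), and Spearman correlations between class-membership
indicator vectors.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ekss.bcs import RANKS
from ekss.core import GROUPS, LEVELS
from ekss.errors import ValidationError

logger = logging.getLogger(__name__)

#: Correlation magnitude bands; |r| below 0.3 is not considered significant.
CORRELATION_BANDS: tuple[tuple[float, str], ...] = (
    (0.9, "substantial"),
    (0.7, "strong"),
    (0.5, "moderate"),
    (0.3, "fairly_significant"),
)

_STATUS_ALIASES = {
    "ek": "EK", "easy": "EK", "easy keeper": "EK", "easy_keeper": "EK",
    "mk": "MK", "medium": "MK", "medium keeper": "MK", "medium_keeper": "MK",
    "hk": "HK", "hard": "HK", "hard keeper": "HK", "hard_keeper": "HK",
}


def normalize_status(label: str) -> str:
    """Normalize a keeper-status label to EK/MK/HK (case-insensitive aliases)."""
    key = str(label).strip().lower()
    if key not in _STATUS_ALIASES:
        raise ValidationError(
            f"unrecognized keeper status {label!r}; expected one of "
            "EK/MK/HK or easy/medium/hard keeper"
        )
    return _STATUS_ALIASES[key]


def correlation_band(r: float) -> str:
    """Label a Spearman r by the magnitude bands used for screening."""
    if not math.isfinite(r):
        return "not_applicable"
    mag = abs(r)
    for cutoff, name in CORRELATION_BANDS:
        if mag >= cutoff:
            return name
    return "none"


def _partition_table(labels: Sequence[str], categories: Sequence[str]) -> pd.DataFrame:
    counts = pd.Series(labels).value_counts()
    n = len(labels)
    rows = []
    for cat in categories:
        c = int(counts.get(cat, 0))
        rows.append(
            {"category": cat, "count": c,
             "percent": 100.0 * c / n,
             "percent_rounded": int(round(100.0 * c / n))}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DistributionSummary:
    """Counts and percentages by group, level, BCS rank and (optionally) ORKS."""

    n_total: int
    by_group: pd.DataFrame
    by_level: pd.DataFrame
    by_rank: pd.DataFrame
    by_orks: Optional[pd.DataFrame] = None


def distribution(results: pd.DataFrame) -> DistributionSummary:
    """Summarize a results table into per-partition counts and percentages.

    ``results`` needs columns ``ekss_group``, ``ekss_level`` and
    ``bcs_rank``; an ``orks`` column is summarized when present. Percentages
    carry both machine precision and the nearest-integer display value.
    """
    if len(results) == 0:
        raise ValidationError("cannot summarize an empty results table")
    for col in ("ekss_group", "ekss_level", "bcs_rank"):
        if col not in results.columns:
            raise ValidationError(f"results table missing column '{col}'")
    by_orks = None
    if "orks" in results.columns and results["orks"].notna().any():
        orks = results["orks"].dropna().map(normalize_status)
        by_orks = _partition_table(list(orks), GROUPS)
    return DistributionSummary(
        n_total=len(results),
        by_group=_partition_table(list(results["ekss_group"]), GROUPS),
        by_level=_partition_table(list(results["ekss_level"]), LEVELS),
        by_rank=_partition_table(list(results["bcs_rank"]), RANKS),
        by_orks=by_orks,
    )


@dataclass(frozen=True)
class AgreementSummary:
    """ORKS x EKSS agreement: contingency, overall/per-class percent, correlations."""

    contingency: pd.DataFrame  # ORKS rows x EKSS columns, counts
    n: int
    overall_percent: float
    per_orks_percent: Mapping[str, float]
    mosaic_fractions: pd.DataFrame  # cell fractions of n
    membership_correlations: pd.DataFrame  # orks_class, ekss_class, r, band


def membership_correlation(
    indicator_a: Sequence[int], indicator_b: Sequence[int]
) -> tuple[float, str]:
    """Spearman correlation between two binary membership indicators.

    On binary data Spearman's rank correlation with midranks reduces to the
    phi coefficient of the 2x2 table. A constant indicator has no rank
    variation, so the correlation is undefined and reported as NaN with the
    band ``not_applicable`` (not as zero).
    """
    a = np.asarray(indicator_a, dtype=float)
    b = np.asarray(indicator_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValidationError("indicators must be equal-length 1-d, length >= 3")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValidationError("indicators must be binary 0/1 vectors")
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        logger.warning("constant membership indicator: correlation undefined")
        return float("nan"), "not_applicable"
    r = float(stats.spearmanr(a, b).statistic)
    return r, correlation_band(r)


def agreement(
    orks: Sequence[str], ekss: Sequence[str]
) -> AgreementSummary:
    """Compare owner-reported and scale-assigned statuses.

    Overall agreement is the contingency-table trace over n; per-class
    agreement conditions on the ORKS class (the share of owners' EK calls
    the scale also rated EK, and so on). Membership correlations are
    Spearman r between the binary indicator of each ORKS class and each
    EKSS class.
    """
    orks_n = [normalize_status(x) for x in orks]
    ekss_n = [normalize_status(x) for x in ekss]
    if len(orks_n) != len(ekss_n) or len(orks_n) == 0:
        raise ValidationError("ORKS and EKSS label vectors must be equal length >= 1")
    n = len(orks_n)
    table = pd.DataFrame(0, index=list(GROUPS), columns=list(GROUPS), dtype=int)
    for o, e in zip(orks_n, ekss_n):
        table.loc[o, e] += 1
    trace = sum(table.loc[g, g] for g in GROUPS)
    per_class = {}
    for g in GROUPS:
        row_total = int(table.loc[g].sum())
        per_class[g] = 100.0 * table.loc[g, g] / row_total if row_total else float("nan")
    corrs = []
    orks_arr = np.array(orks_n)
    ekss_arr = np.array(ekss_n)
    for go, ge in itertools.product(GROUPS, GROUPS):
        if n < 3:
            r, band = float("nan"), "not_applicable"
        else:
            r, band = membership_correlation(
                (orks_arr == go).astype(int), (ekss_arr == ge).astype(int)
            )
        corrs.append(
            {"orks_class": go, "ekss_class": ge, "r": r, "band": band,
             "flagged": bool(abs(r) >= 0.3) if math.isfinite(r) else False}
        )
    return AgreementSummary(
        contingency=table,
        n=n,
        overall_percent=100.0 * trace / n,
        per_orks_percent=per_class,
        mosaic_fractions=table / n,
        membership_correlations=pd.DataFrame(corrs),
    )


@dataclass(frozen=True)
class GroupComparison:
    """Kruskal-Wallis omnibus with BH-adjusted pairwise Wilcoxon tests."""

    omnibus_p: float
    pairwise: pd.DataFrame  # group_a, group_b, p_raw, p_adjusted
    letters: Mapping[str, str] = field(default_factory=dict)
    alpha: float = 0.05


def _compact_letters(
    groups: Sequence[str],
    medians: Mapping[str, float],
    significant: set[frozenset],
) -> dict[str, str]:
    """Compact letter display: groups share a letter iff not significantly
    different. Letters come from maximal cliques of the non-significance
    graph, ordered so 'a' attaches to the largest-median groups (the table
    convention of superscripting the top group 'a')."""
    order = sorted(groups, key=lambda g: -medians[g])
    k = len(order)
    cliques: list[tuple[str, ...]] = []
    for size in range(k, 0, -1):
        for combo in itertools.combinations(order, size):
            if any(set(combo) <= set(c) for c in cliques):
                continue
            if all(
                frozenset((x, y)) not in significant
                for x, y in itertools.combinations(combo, 2)
            ):
                cliques.append(combo)
    cliques.sort(key=lambda c: min(order.index(g) for g in c))
    letters = {g: "" for g in groups}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i)
        for g in clique:
            letters[g] += letter
    return letters


def group_compare(
    values: Sequence[float],
    groups: Sequence[str],
    alpha: float = 0.05,
) -> GroupComparison:
    """Nonparametric comparison of a numeric trait across keeper groups.

    Kruskal-Wallis omnibus p-value, pairwise two-sided Wilcoxon rank-sum
    tests with Benjamini-Hochberg adjustment, and a compact letter display
    at the given alpha (shared letter = not significantly different).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray([str(g) for g in groups])
    if values.shape != labels.shape or values.ndim != 1:
        raise ValidationError("values and groups must be equal-length 1-d")
    names = sorted(set(labels), key=list(labels).index)
    samples = {g: values[labels == g] for g in names}
    if len(names) < 2 or any(len(s) < 2 for s in samples.values()):
        raise ValidationError("need >= 2 groups with >= 2 observations each")
    omnibus_p = float(stats.kruskal(*samples.values()).pvalue)
    pairs = list(itertools.combinations(names, 2))
    raw = [
        float(stats.mannwhitneyu(samples[a], samples[b],
                                 alternative="two-sided").pvalue)
        for a, b in pairs
    ]
    adjusted = multipletests(raw, method="fdr_bh")[1] if pairs else []
    pairwise = pd.DataFrame(
        {"group_a": [a for a, _ in pairs], "group_b": [b for _, b in pairs],
         "p_raw": raw, "p_adjusted": adjusted}
    )
    significant = {
        frozenset((a, b))
        for (a, b), p in zip(pairs, adjusted)
        if p < alpha
    }
    medians = {g: float(np.median(samples[g])) for g in names}
    letters = _compact_letters(names, medians, significant)
    return GroupComparison(
        omnibus_p=omnibus_p, pairwise=pairwise, letters=letters, alpha=alpha
    )
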