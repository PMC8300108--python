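"""Synthetic cohorts and count tables with known ground truth.

The cohort generator draws a true keeper level per horse, places the
horse's true RDI5% inside that level's band, and works backwards through
the scale's closed-form identity

    RDI5% = DEI% + (ideal_BCS - BCS) x dDE x 100

to a consistent body condition score and energy intake. The intake is then
decomposed into realistic forage + grain feed items (forage-first, hay DE
1.8-2.2 and grain 2.8-3.6 Mcal/kg as fed), regional condition scores for
two blinded scorers are drawn around the true BCS with configurable noise,
and the owner-reported status is drawn from a row-stochastic confusion
matrix applied to the true group. With zero scorer noise and an identity
confusion matrix the full assignment pipeline recovers every planted level
exactly.

The taxa generator draws Dirichlet-multinomial count tables with planted
fold-change effects in chosen groups, returning the ground-truth effect
list for recovery scoring.

All draws flow from a single seed; generation is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ekss.bcs import REGIONS
from ekss.core import GROUPS, LEVEL_TO_GROUP, LEVELS, EKSSConfig
from ekss.energy import RequirementConfig
from ekss.errors import ValidationError
from ekss.microbiome import AbundanceTable

# Level mix observed in a 240-horse field cohort (counts 57/27/22/21/17/14/82),
# used as the default conditional level distribution within each group.
_DEFAULT_LEVEL_COUNTS = {
    "E+": 57, "E": 27, "M+": 22, "M": 21, "M-": 17, "H": 14, "H-": 82,
}

# Default owner confusion: diagonals match observed per-class owner agreement
# (41.6/19.7/64.3%); off-diagonal mass leans toward owners over-calling EK.
_DEFAULT_CONFUSION = np.array(
    [
        [0.416, 0.384, 0.200],
        [0.450, 0.197, 0.353],
        [0.157, 0.200, 0.643],
    ]
)

# Practical outer sampling edges for the unbounded E+ and H- bands.
_OUTER_EDGE_LOW = 55.0
_OUTER_EDGE_HIGH = 160.0


@dataclass(frozen=True)
class CohortSimParams:
    """Study-condition parameters for the cohort generator.

    Defaults emulate the 240-horse field cohort: mixed body weights around
    500 kg, the observed group mix (35% EK / 25% MK / 40% HK), two scorers
    with quarter-point scoring noise, and owner confusion calibrated to the
    observed per-class agreement rates.
    """

    n_horses: int = 240
    bw_mean: float = 500.0
    bw_sd: float = 75.0
    true_group_probabilities: tuple[float, float, float] = (0.35, 0.25, 0.40)
    scorer_noise_sd: float = 0.25
    n_scorers: int = 2
    orks_confusion: np.ndarray = field(
        default_factory=lambda: _DEFAULT_CONFUSION.copy()
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_horses < 1:
            raise ValidationError("n_horses must be >= 1")
        probs = np.asarray(self.true_group_probabilities, dtype=float)
        if probs.shape != (3,) or (probs < 0).any() or not math.isclose(
            probs.sum(), 1.0, abs_tol=1e-9
        ):
            raise ValidationError("true_group_probabilities must be 3 probabilities summing to 1")
        conf = np.asarray(self.orks_confusion, dtype=float)
        if conf.shape != (3, 3) or (conf < 0).any() or not np.allclose(
            conf.sum(axis=1), 1.0, atol=1e-9
        ):
            raise ValidationError("orks_confusion must be 3x3 row-stochastic")
        if self.scorer_noise_sd < 0:
            raise ValidationError("scorer_noise_sd must be >= 0")
        if self.n_scorers < 1:
            raise ValidationError("n_scorers must be >= 1")


@dataclass(frozen=True)
class SimulatedCohort:
    """Generated tables plus the ground truth behind them."""

    horses: pd.DataFrame  # horse_id, bw_kg, workload, tier, orks
    scores: pd.DataFrame  # horse_id, scorer_id, six regional columns
    rations: pd.DataFrame  # horse_id, feed_name, kg_per_day, densities, ...
    truth: pd.DataFrame  # horse_id, true_group, true_level, true_bcs, ...


def _level_probabilities(group_probs: Sequence[float]) -> np.ndarray:
    """Spread group probabilities over levels using the field-cohort mix."""
    group_probs = dict(zip(GROUPS, group_probs))
    group_totals = {
        g: sum(c for lv, c in _DEFAULT_LEVEL_COUNTS.items()
               if LEVEL_TO_GROUP[lv] == g)
        for g in GROUPS
    }
    return np.array(
        [
            group_probs[LEVEL_TO_GROUP[lv]]
            * _DEFAULT_LEVEL_COUNTS[lv] / group_totals[LEVEL_TO_GROUP[lv]]
            for lv in LEVELS
        ]
    )


def _band_sampling_range(band) -> tuple[float, float]:
    """Central 80% of a level band, with practical edges for unbounded bands."""
    lo = band.lower if math.isfinite(band.lower) else _OUTER_EDGE_LOW
    hi = band.upper if math.isfinite(band.upper) else _OUTER_EDGE_HIGH
    margin = 0.1 * (hi - lo)
    return lo + margin, hi - margin


# Group-typical BCS centers for drawing condition scores (over-conditioned
# easy keepers, lean-ish hard keepers), matching field means.
_BCS_CENTERS = {"EK": 6.3, "MK": 5.95, "HK": 5.5}


def simulate_cohort(
    params: Optional[CohortSimParams] = None,
    ekss_config: Optional[EKSSConfig] = None,
    req_config: Optional[RequirementConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedCohort:
    """Generate a cohort of horses with known keeper levels.

    Horses are idle or lightly/moderately worked adults; each carries a
    weighed hay + grain ration engineered so the assignment pipeline's
    energy profile reproduces the planted DEI% exactly (no ad-libitum
    items, whose intake is only estimated, are used by the generator).
    """
    params = params or CohortSimParams()
    ekss_config = ekss_config or EKSSConfig()
    req_config = req_config or RequirementConfig()
    rng = rng or np.random.default_rng(params.seed)

    level_probs = _level_probabilities(params.true_group_probabilities)
    bands = {b.level: b for b in ekss_config.level_bands}
    ideal = ekss_config.ideal_bcs
    ddepct = ekss_config.delta_de * 100.0

    workloads = rng.choice(
        ["no_work", "light", "moderate"], size=params.n_horses, p=[0.5, 0.35, 0.15]
    )
    bw = np.clip(
        rng.normal(params.bw_mean, params.bw_sd, size=params.n_horses), 200.0, 900.0
    )
    levels = rng.choice(LEVELS, size=params.n_horses, p=level_probs)

    horses_rows, scores_rows, ration_rows, truth_rows = [], [], [], []
    for i in range(params.n_horses):
        horse_id = f"H{i + 1:04d}"
        level = str(levels[i])
        group = LEVEL_TO_GROUP[level]
        lo, hi = _band_sampling_range(bands[level])
        true_rdi5 = float(rng.uniform(lo, hi))

        # BCS around the group-typical center, kept where DEI% stays positive.
        true_bcs = float(
            np.clip(rng.normal(_BCS_CENTERS[group], 0.5), 2.0, 8.5)
        )
        dei_percent = true_rdi5 - (ideal - true_bcs) * ddepct
        if dei_percent <= 5.0:  # keep intakes physically plausible
            true_bcs = float(np.clip(ideal + (true_rdi5 - 20.0) / ddepct, 2.0, 8.5))
            dei_percent = true_rdi5 - (ideal - true_bcs) * ddepct
        if dei_percent <= 0:
            raise ValidationError(
                f"infeasible band placement for level {level}: DEI% <= 0"
            )

        workload = str(workloads[i])
        if workload == "no_work":
            de_m = req_config.de_coefficients["average"] * bw[i]
        else:
            de_m = (
                req_config.de_coefficients["average"]
                * req_config.workload_multipliers[workload]
                * bw[i]
            )
        dei = dei_percent / 100.0 * de_m

        # Forage-first decomposition into weighed hay + grain.
        forage_share = float(rng.uniform(0.70, 0.90))
        hay_de = float(rng.uniform(1.8, 2.2))
        grain_de = float(rng.uniform(2.8, 3.6))
        hay_cp = float(rng.uniform(70.0, 100.0))
        grain_cp = float(rng.uniform(100.0, 140.0))
        hay_kg = forage_share * dei / hay_de
        grain_kg = (1.0 - forage_share) * dei / grain_de
        ration_rows.extend(
            [
                {"horse_id": horse_id, "feed_name": "hay", "kg_per_day": hay_kg,
                 "de_mcal_per_kg": hay_de, "cp_g_per_kg": hay_cp,
                 "ad_libitum": False, "access_hours": 0.0},
                {"horse_id": horse_id, "feed_name": "grain", "kg_per_day": grain_kg,
                 "de_mcal_per_kg": grain_de, "cp_g_per_kg": grain_cp,
                 "ad_libitum": False, "access_hours": 0.0},
            ]
        )

        for scorer in range(params.n_scorers):
            noise = rng.normal(0.0, params.scorer_noise_sd, size=len(REGIONS)) \
                if params.scorer_noise_sd > 0 else np.zeros(len(REGIONS))
            regional = np.clip(true_bcs + noise, 1.0, 9.0)
            row = {"horse_id": horse_id, "scorer_id": f"S{scorer + 1}"}
            row.update({region: float(v) for region, v in zip(REGIONS, regional)})
            scores_rows.append(row)

        orks = str(
            rng.choice(GROUPS, p=params.orks_confusion[GROUPS.index(group)])
        )
        horses_rows.append(
            {"horse_id": horse_id, "bw_kg": float(bw[i]), "workload": workload,
             "tier": "average", "orks": orks}
        )
        truth_rows.append(
            {"horse_id": horse_id, "true_group": group, "true_level": level,
             "true_bcs": true_bcs, "true_rdi5_percent": true_rdi5,
             "true_dei_percent": dei_percent}
        )

    return SimulatedCohort(
        horses=pd.DataFrame(horses_rows),
        scores=pd.DataFrame(scores_rows),
        rations=pd.DataFrame(ration_rows),
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# Taxon-by-sample count tables

_PHYLA_CYCLE = (
    "Firmicutes", "Bacteroidetes", "Proteobacteria", "Spirochaetes",
    "Planctomycetes", "Euryarchaeota", "Verrucomicrobia", "Fibrobacteres",
)


@dataclass(frozen=True)
class PlantedEffect:
    """A taxon whose abundance is shifted in one group."""

    taxon_index: int
    group: str
    fold_change: float  # multiplicative shift of the Dirichlet concentration

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group '{self.group}'")
        if not self.fold_change > 0:
            raise ValidationError("fold_change must be > 0")


@dataclass(frozen=True)
class TaxaSimParams:
    """Study-condition parameters for the count-table generator.

    Defaults emulate a 16S survey across the three keeper groups: tens of
    genera with a long-tailed baseline, per-sample read depths in the
    2240-15841 range observed for field fecal samples, and moderate
    Dirichlet overdispersion.
    """

    n_taxa: int = 50
    n_samples_per_group: int = 20
    concentration_scale: float = 200.0  # total Dirichlet concentration
    planted_effects: tuple[PlantedEffect, ...] = ()
    depth_range: tuple[int, int] = (2240, 15841)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2 or self.n_samples_per_group < 1:
            raise ValidationError("need >= 2 taxa and >= 1 sample per group")
        if not self.concentration_scale > 0:
            raise ValidationError("concentration_scale must be > 0")
        lo, hi = self.depth_range
        if not 0 < lo <= hi:
            raise ValidationError("depth_range must be 0 < low <= high")
        for eff in self.planted_effects:
            if not 0 <= eff.taxon_index < self.n_taxa:
                raise ValidationError(
                    f"planted taxon index {eff.taxon_index} out of range"
                )


def _synthetic_lineages(n_taxa: int) -> list[str]:
    lineages = []
    for i in range(n_taxa):
        phylum = _PHYLA_CYCLE[i % len(_PHYLA_CYCLE)]
        lineages.append(
            ";".join(
                [
                    "d__Bacteria" if phylum != "Euryarchaeota" else "d__Archaea",
                    f"p__{phylum}",
                    f"c__Class{i % 12:02d}",
                    f"o__Order{i % 18:02d}",
                    f"f__Family{i % 25:02d}",
                    f"g__Genus{i:03d}",
                ]
            )
        )
    return lineages


def simulate_taxa(
    params: Optional[TaxaSimParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Generate a Dirichlet-multinomial count table with planted group effects.

    Returns the table (with EK/MK/HK sample labels) and a ground-truth
    frame (taxon, group, fold_change) for recovery scoring. Baseline
    proportions follow a long-tailed 1/(i+1) profile; a planted effect
    multiplies the taxon's concentration in its target group's samples.
    """
    params = params or TaxaSimParams()
    rng = rng or np.random.default_rng(params.seed)

    base = 1.0 / np.arange(1, params.n_taxa + 1)
    base = base / base.sum() * params.concentration_scale
    lineages = _synthetic_lineages(params.n_taxa)

    columns, labels = {}, {}
    for group in GROUPS:
        conc_g = base.copy()
        for eff in params.planted_effects:
            if eff.group == group:
                conc_g[eff.taxon_index] *= eff.fold_change
        for j in range(params.n_samples_per_group):
            sample_id = f"{group}{j + 1:03d}"
            depth = int(rng.integers(params.depth_range[0], params.depth_range[1] + 1))
            p = rng.dirichlet(conc_g)
            columns[sample_id] = rng.multinomial(depth, p)
            labels[sample_id] = group

    counts = pd.DataFrame(columns, index=pd.Index(lineages, name="lineage"))
    table = AbundanceTable(
        counts=counts, sample_labels=pd.Series(labels, name="group")
    )
    truth = pd.DataFrame(
        [
            {"taxon": lineages[e.taxon_index], "taxon_index": e.taxon_index,
             "group": e.group, "fold_change": e.fold_change}
            for e in params.planted_effects
        ],
        columns=["taxon", "taxon_index", "group", "fold_change"],
    )
    return table, truth
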