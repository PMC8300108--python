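"""Downstream abundance statistics for taxon-by-sample count tables.

Operates on generic 16S-style count tables (rows: taxa with
semicolon-delimited lineages, columns: samples) with per-sample keeper-group
labels. Provides rank aggregation, relative abundance with a <1% "Others"
collapse, the Firmicutes/Bacteroidetes ratio, Shannon and observed alpha
diversity, total-sum normalization and seeded rarefaction, and the
taxon-status Spearman screen with the |r| >= 0.3 significance bands.

The upstream amplicon pipeline (denoising, chimera checking, taxonomy
assignment) is out of scope: tables arrive already tabulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from ekss.cohort import correlation_band, normalize_status
from ekss.errors import ValidationError

logger = logging.getLogger(__name__)

RANK_NAMES: tuple[str, ...] = (
    "domain", "phylum", "class", "order", "family", "genus",
)

_RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "k__", "s__")

#: Phylum spellings accepted for the F/B ratio (SILVA/GTDB synonyms).
_FIRMICUTES = {"firmicutes", "bacillota"}
_BACTEROIDETES = {"bacteroidetes", "bacteroidota"}


def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Split a semicolon-delimited lineage, stripping ``d__``-style prefixes."""
    parts = []
    for token in str(lineage).split(";"):
        token = token.strip()
        for prefix in _RANK_PREFIXES:
            if token.lower().startswith(prefix):
                token = token[len(prefix):]
                break
        parts.append(token)
    return tuple(parts)


@dataclass(frozen=True)
class AbundanceTable:
    """Taxon-by-sample counts with lineages and optional group labels.

    ``counts`` is a DataFrame indexed by the full lineage string with one
    column per sample. ``sample_labels`` maps sample id to EK/MK/HK.
    """

    counts: pd.DataFrame
    sample_labels: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValidationError("count table contains negative values")
        if self.sample_labels is not None:
            missing = set(self.counts.columns) - set(self.sample_labels.index)
            if missing:
                raise ValidationError(
                    f"samples missing a group label: {sorted(missing)}"
                )

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def labels_for(self, samples: Sequence[str]) -> np.ndarray:
        if self.sample_labels is None:
            raise ValidationError("abundance table has no sample labels")
        return np.array(
            [normalize_status(self.sample_labels[s]) for s in samples]
        )


def aggregate_rank(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum counts within the requested taxonomic rank.

    Lineages too shallow to resolve the rank, or with an empty name at the
    rank, pool under ``unclassified`` so total mass is conserved.
    """
    if rank not in RANK_NAMES:
        raise ValidationError(
            f"unknown rank '{rank}'; valid: {', '.join(RANK_NAMES)}"
        )
    depth = RANK_NAMES.index(rank)
    names = []
    for lineage in table.counts.index:
        parts = parse_lineage(lineage)
        name = parts[depth] if depth < len(parts) else ""
        names.append(name if name else "unclassified")
    aggregated = table.counts.groupby(pd.Index(names, name=rank)).sum()
    return AbundanceTable(counts=aggregated, sample_labels=table.sample_labels)


def relative_abundance(
    table: AbundanceTable,
    collapse_threshold: float = 0.01,
    per_group: bool = False,
) -> pd.DataFrame:
    """Per-sample (or group-mean) proportions with rare taxa pooled as "Others".

    A taxon whose proportion never exceeds ``collapse_threshold`` in any
    column of the output is collapsed into the ``Others`` row; columns sum
    to 1 either way. With ``per_group=True`` the columns are group means of
    the per-sample proportions (equal weight per sample, so deep samples do
    not dominate).
    """
    sums = table.sample_sums()
    empty = sums[sums <= 0]
    if len(empty):
        raise ValidationError(
            f"sample(s) with zero total counts: {list(empty.index)}"
        )
    props = table.counts.div(sums, axis=1)
    if per_group:
        labels = table.labels_for(props.columns)
        props = props.T.groupby(labels).mean().T
    keep = (props > collapse_threshold).any(axis=1)
    out = props.loc[keep]
    others = props.loc[~keep].sum(axis=0)
    if (others > 0).any() or (~keep).any():
        out = pd.concat([out, others.to_frame("Others").T])
    return out


def fb_ratio(table: AbundanceTable, per_group: bool = True) -> pd.Series:
    """Firmicutes / Bacteroidetes relative-abundance ratio.

    Computed on phylum-level group-mean (or per-sample) proportions;
    invariant to per-sample total-sum scaling. Zero Bacteroidetes mass
    yields NaN rather than an error.
    """
    phyla = aggregate_rank(table, "phylum")
    props = relative_abundance(phyla, collapse_threshold=0.0, per_group=per_group)
    index_lower = pd.Index([str(i).lower() for i in props.index])
    f_mass = props.loc[index_lower.isin(_FIRMICUTES).tolist()].sum(axis=0)
    b_mass = props.loc[index_lower.isin(_BACTEROIDETES).tolist()].sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = f_mass / b_mass
    ratio = ratio.where(b_mass > 0, np.nan)
    if ratio.isna().any():
        logger.warning("zero Bacteroidetes mass in %s: F/B ratio undefined",
                       list(ratio.index[ratio.isna()]))
    ratio.name = "fb_ratio"
    return ratio


def alpha_diversity(table: AbundanceTable, base: Optional[float] = None) -> pd.DataFrame:
    """Per-sample observed richness and Shannon index.

    Observed is the number of taxa with nonzero counts; Shannon is
    ``-sum(p_i * log(p_i))`` in the requested log base (natural by
    default). With k equally abundant taxa Shannon equals ``log(k)``.
    """
    sums = table.sample_sums()
    if (sums <= 0).any():
        raise ValidationError("samples with zero total counts have no diversity")
    observed = (table.counts > 0).sum(axis=0)
    shannon = {
        s: float(stats.entropy(table.counts[s].to_numpy(dtype=float), base=base))
        for s in table.samples
    }
    return pd.DataFrame(
        {"observed": observed.astype(int), "shannon": pd.Series(shannon)}
    )


def normalize_to_depth(
    table: AbundanceTable, depth: Optional[float] = None
) -> AbundanceTable:
    """Total-sum scale every sample to a common depth (median depth by default).

    Produces fractional "counts"; relative quantities are unchanged.
    """
    sums = table.sample_sums()
    if (sums <= 0).any():
        raise ValidationError("cannot normalize samples with zero total counts")
    if depth is None:
        depth = float(sums.median())
    if not depth > 0:
        raise ValidationError(f"target depth must be > 0, got {depth!r}")
    scaled = table.counts.div(sums, axis=1) * depth
    return AbundanceTable(counts=scaled, sample_labels=table.sample_labels)


def rarefy(
    table: AbundanceTable,
    depth: int,
    seed: Union[int, np.random.Generator, None] = None,
) -> AbundanceTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples shallower than ``depth`` are dropped with a warning. Drawing
    uses the multivariate hypergeometric distribution, so each rarefied
    column sums exactly to ``depth`` and no taxon exceeds its original
    count; results are bit-reproducible for a fixed seed.
    """
    if not depth > 0:
        raise ValidationError(f"rarefaction depth must be > 0, got {depth!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = table.counts.round().astype(np.int64)
    sums = counts.sum(axis=0)
    keep = [s for s in counts.columns if sums[s] >= depth]
    dropped = [s for s in counts.columns if sums[s] < depth]
    if dropped:
        logger.warning(
            "dropping %d sample(s) shallower than depth %d: %s",
            len(dropped), depth, dropped,
        )
    out = {}
    for s in keep:
        out[s] = rng.multivariate_hypergeometric(counts[s].to_numpy(), depth)
    rarefied = pd.DataFrame(out, index=counts.index)
    labels = table.sample_labels
    if labels is not None:
        labels = labels.loc[[s for s in labels.index if s in keep]]
    return AbundanceTable(counts=rarefied, sample_labels=labels)


def normalize_and_rarefy(
    table: AbundanceTable,
    depth: int,
    normalize_depth: Optional[float] = None,
    seed: Union[int, np.random.Generator, None] = None,
) -> AbundanceTable:
    """Total-sum normalize to the median depth, then rarefy to ``depth``."""
    return rarefy(normalize_to_depth(table, normalize_depth), depth, seed)


def taxa_status_correlations(
    table: AbundanceTable,
    labels: Optional[Sequence[str]] = None,
    threshold: float = 0.3,
    report_all: bool = False,
    use_proportions: bool = True,
) -> pd.DataFrame:
    """Screen taxa for association with keeper groups by Spearman correlation.

    For every taxon and every group, correlates the taxon's abundance
    vector with the group's binary membership indicator across samples.
    Returns a long table (taxon, group, r, band, sign); by default only
    |r| >= ``threshold`` rows are reported. Constant taxa are undefined and
    appear (with NaN) only when ``report_all``.
    """
    samples = table.samples
    if labels is None:
        groups = table.labels_for(samples)
    else:
        groups = np.array([normalize_status(x) for x in labels])
        if len(groups) != len(samples):
            raise ValidationError("labels length must match number of samples")
    if len(samples) < 3:
        raise ValidationError("need at least 3 samples for correlation screening")
    data = table.counts
    if use_proportions:
        sums = data.sum(axis=0)
        if (sums <= 0).any():
            raise ValidationError("zero-sum samples cannot be screened")
        data = data.div(sums, axis=1)
    rows = []
    values = data.to_numpy(dtype=float)
    for i, taxon in enumerate(data.index):
        vec = values[i]
        constant_taxon = np.all(vec == vec[0])
        for group in sorted(set(groups)):
            indicator = (groups == group).astype(float)
            if constant_taxon or indicator.min() == indicator.max():
                r = float("nan")
            else:
                r = float(stats.spearmanr(vec, indicator).statistic)
            band = correlation_band(r)
            flagged = bool(abs(r) >= threshold) if np.isfinite(r) else False
            if flagged or report_all:
                rows.append(
                    {"taxon": taxon, "group": group, "r": r, "band": band,
                     "sign": "+" if (np.isfinite(r) and r > 0)
                     else ("-" if np.isfinite(r) and r < 0 else "NA"),
                     "flagged": flagged}
                )
    return pd.DataFrame(
        rows, columns=["taxon", "group", "r", "band", "sign", "flagged"]
    )
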