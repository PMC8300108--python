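# Methods

## The scale

The Equine Keeper Status Scale classifies metabolic tendency through the
energy a horse would need to reach and hold the ideal body condition score
(BCS) of 5. Three equations chain per horse:

1. `B = ideal_BCS − A`, the condition deficit, where `A` is the overall
   BCS: six regional scores (tailhead, crease down the back, crest of the
   neck, withers, ribs, behind the shoulder; Kohnke modification of the
   Henneke 1–9 system) averaged within scorer, then across scorers. Any
   positive number of scorers is accepted; field protocols typically use
   two blinded scorers. Fractional scores pass through unrounded.
2. `C = B × DE_M × ΔDE`, the Mcal/day adjustment, where `DE_M` is the
   digestible-energy maintenance requirement and `ΔDE` the per-BCS-unit
   adjustment fraction. The NRC's guidance is that a 10–15% change in
   digestible-energy intake moves BCS by about one unit; the default
   `ΔDE = 0.125` sits mid-band. Values outside [0.10, 0.15] are accepted
   (the scale is explicitly tunable, e.g. leanness preferences in
   endurance horses) but log a warning.
3. `RDI5% = (D + C) / DE_M × 100`, the recommended dietary intake as a
   percent of maintenance, with `D` the current digestible-energy intake.
   We read the quotient as `(D + C)/DE_M`; the alternative grouping
   `D + (C/DE_M)×100` adds megacalories to a percentage and cannot
   produce values on the scale's axis.

Algebraically `RDI5% = DEI% + (ideal_BCS − BCS) × ΔDE × 100`, so the
classification is invariant under body-weight scaling and can be computed
from percentages alone. The test suite asserts this identity at 1e−9
relative tolerance over randomized inputs.

### Classification bands

Groups: easy keeper (EK) `RDI5% < 90`, medium keeper (MK) `90–110`, hard
keeper (HK) `> 110`. Levels: `E+ < 75`, `E [75, 90)`, `M+ [90, 95)`,
`M [95, 105]`, `M− (105, 110]`, `H (110, 125]`, `H− > 125`. Intervals are
half-open toward the hard-keeper side below the central `M` band and
toward the easy-keeper side above it, so the seven bands tile the real
line and nest exactly into the three groups; the config validator enforces
tiling, and classification of a value landing exactly on a boundary logs a
warning. **These cutoffs are provisional defaults**: the original
publication presents the ranges only in a figure whose numbers are not
machine-readable, so the defaults were reconstructed from the
10–15%-per-BCS-unit rule (≈15%-wide outer level bands, a ±10% maintenance
window for MK split 5/10/5) under the constraints that the published
group-mean inputs classify into their own groups and the outermost levels
(E+, H−) are the modal levels, as reported. All bands are overridable in
the YAML config.

## Energy requirements and rations

Adult maintenance DE is linear in body weight with minimum / average /
elevated tier coefficients (0.0303 / 0.0333 / 0.0363 Mcal·kg⁻¹·day⁻¹);
working horses use the average tier times a workload multiplier (light
1.20, moderate 1.40, heavy 1.60, very heavy 1.90). Crude-protein
requirements are likewise linear (1.26 g·kg⁻¹·day⁻¹ at maintenance,
1.40/1.54/1.72/2.01 by workload). These numbers are the NRC-style defaults
shipped in `RequirementConfig`; they are configuration, not assertions —
users with a different NRC edition or special cases override them.
Growing, pregnant and lactating animals resolve only through explicit
absolute overrides; the package deliberately ships no guesses for those
states. Requirements never depend on keeper status.

Ration intake is as-fed: `DEI = Σ kg × DE density` over resolved items.
Ad-libitum items (pasture, free hay) are estimated at `rate ×
access_hours` (default 0.8 kg/h, configurable per item or globally) and
share a single allocation pool of `max(0, 0.02 × BW − offered_kg)`: the
rule that a horse can ingest up to 2% of its body weight per day, with
the pool reduced by all weighed feed. Multiple ad-lib items split the pool
proportionally to their rate×hours potentials. The ≥16 h access case from
the field protocol makes the 2% cap bind; the rate-based proration below
16 h is this package's design choice (the original workflow delegated
short-access estimation to a commercial calculator whose model is not
public) and is clearly configurable. Dry-matter accounting is out of
scope. Note one consequence of the pool rule: removing a weighed feed can
*increase* ad-lib intake, so intake additivity holds only among weighed
items.

Estimated total body fat uses the Dugdale et al. linear form
`eTBF% = 0.006 + 1.56 × BCS`. (The published rendering of this equation is
typographically garbled; the linear form reproduces the published group
means from the published BCS means to within rounding, and regressing
those printed pairs recovers slope ≈ 1.56, intercept ≈ 0.006 — both checks
are in the test suite.) Because the form is linear, applying it per horse
and averaging equals applying it to the group-mean BCS.

## Cohort statistics

Distributions report counts with full-precision and nearest-integer
percentages per partition (group, level, BCS rank, owner label). Agreement
between owner-reported keeper status (ORKS) and scale assignments is the
3×3 contingency trace over n, with per-class agreement conditioned on the
ORKS class; per-class rates weighted by ORKS class sizes reconstruct the
overall rate exactly. Owner labels are normalized case-insensitively
("easy keeper" → EK); unmapped labels are errors, never dropped.

Group comparisons use the Kruskal–Wallis omnibus plus pairwise two-sided
Wilcoxon rank-sum tests with Benjamini–Hochberg adjustment (scipy /
statsmodels). The compact letter display assigns letters from maximal
cliques of the non-significance graph at α = 0.05, with 'a' attached to
the largest-median group, matching the superscript convention of nutrition
tables.

Membership correlations are Spearman r between binary class indicators;
with midranks this equals the phi coefficient of the 2×2 table, which the
tests verify against the closed form. Magnitude bands follow the screening
convention: |r| < 0.3 not significant, fairly significant [0.3, 0.5),
moderate [0.5, 0.7), strong [0.7, 0.9), substantial [0.9, 1.0]. A constant
indicator (an empty class) yields NaN labelled `not_applicable`, never a
silent zero.

## Microbiome statistics

Count tables are taxon × sample with semicolon-delimited lineages
(`d__;p__;…;g__` prefixes stripped on parse). Rank aggregation pools
unresolvable lineages under `unclassified`, conserving mass. Relative
abundance divides by sample sums; taxa never exceeding the collapse
threshold (default 1%) pool into `Others`, and group-level abundances are
means of per-sample proportions (equal weight per sample) rather than
pooled counts, to avoid depth weighting. The Firmicutes/Bacteroidetes
ratio is computed on phylum proportions (Bacillota/Bacteroidota synonyms
accepted) and is NaN when Bacteroidetes mass is zero.

Shannon diversity is `−Σ p log p` via `scipy.stats.entropy`, natural log
by default and configurable (upstream ecology toolchains differ in base;
only orderings and closed forms are treated as comparable across
pipelines). Observed richness counts nonzero taxa. Normalization is
total-sum scaling to the median depth; rarefaction draws from the
multivariate hypergeometric distribution (numpy Generator), i.e. exact
subsampling without replacement: every rarefied column sums exactly to the
target depth, no taxon exceeds its original count, fixed seeds are
bit-reproducible, and samples shallower than the depth are dropped with a
warning. The taxon–status screen correlates each taxon's per-sample
proportion (configurable to raw counts) with each group's binary
indicator and reports |r| ≥ 0.3 by default in long format. Whether to
screen normalized, rarefied or raw abundances is exposed because upstream
conventions vary; proportions are the default.

## Synthetic data

The cohort generator defines the study conditions the tests run under. It
emulates a 240-horse field cohort: body weights N(500, 75²) kg clipped to
[200, 900]; true group mix 35% EK / 25% MK / 40% HK spread over levels
with the field cohort's conditional mix (E+ and H− modal); workloads 50%
idle / 35% light / 15% moderate; two scorers with 0.25-BCS-point regional
noise; owner labels drawn from a row-stochastic confusion matrix whose
diagonal matches the observed per-class owner agreement (41.6 / 19.7 /
64.3%) and whose off-diagonal mass leans toward owners over-calling EK.
Each horse's true RDI5% is drawn uniformly within the central 80% of its
level's band (practical edges 55 and 160 for the unbounded outer levels)
to keep recovery properties stable; BCS is drawn around group-typical
centers (6.3 / 5.95 / 5.5) and DEI% follows from the closed-form identity.
Intakes decompose forage-first into weighed hay (DE 1.8–2.2 Mcal/kg) and
grain (2.8–3.6 Mcal/kg); the generator uses only weighed feeds so the
assignment pipeline reproduces the planted DEI% exactly — the ad-libitum
estimation path is exercised by its own unit tests instead.

The taxa generator draws Dirichlet-multinomial counts: long-tailed
baseline proportions (∝ 1/rank over 50 taxa), total concentration 200
(moderate overdispersion), read depths uniform on the observed field range
[2240, 15841], 20 samples per group by default, and planted effects that
multiply a taxon's concentration in its target group.

What the generators do *not* emulate: real scorer bias (noise is
unbiased), diet–condition feedback over time, farm/breed structure,
compositional correlations between taxa beyond the Dirichlet, and
sequencing artifacts. Passing recovery tests therefore demonstrate the
pipeline's correctness and statistical behavior under the stated
conditions, not field performance.

## Problem sizes and numerical choices

Simulation-based tests use 150–3000 horses (3000 for Monte-Carlo
convergence of agreement rates, tolerance ±2 percentage points) and 50
seeds × 60 samples for the association-screen sensitivity check; these
sizes give comfortable margins for the asserted properties while keeping
the suite fast. Identity checks run at 1e−9 relative tolerance; published
values are asserted at their printed precision, with ±0.01 slack where the
published *inputs* are themselves rounded. Degenerate inputs (empty scorer
lists, zero body weight, zero-sum samples, constant indicators) raise
typed errors or NaN-with-reason rather than propagating silently.

## Known limitations

- The level/group cutoffs are reconstructed defaults, not transcribed from
  the original figure; users reproducing that work should transcribe the
  figure's ranges into the YAML config.
- Ad-libitum intake below 16 h access uses a simple rate model.
- The scale is undefined for donkeys and mules.
- Absolute Shannon values depend on log base and upstream processing; only
  within-pipeline comparisons are meaningful.
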