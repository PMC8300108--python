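# ekss — Equine Keeper Status Scale

Horse owners describe animals that hold weight on little feed as "easy
keepers" (EK) and animals that need extra feed to hold condition as "hard
keepers" (HK), with "medium keepers" (MK) in between. These labels drive
real feeding decisions, but they are usually assigned by eye and owners'
calls are unreliable. `ekss` implements a standardized, equation-based
alternative: the **Equine Keeper Status Scale**, which classifies a horse's
metabolic tendency from three measurable quantities — its body condition
score, its digestible-energy maintenance requirement, and its actual
digestible-energy intake — plus the cohort statistics used to evaluate the
scale against owner-reported keeper status (ORKS) and a taxon–status
association screen for gut-microbiome count tables.

It is intended for equine nutritionists, veterinarians and researchers who
need repeatable keeper-status assignment for study enrollment or feeding
management, and for anyone analysing keeper-status cohorts.

## The scale

For each horse, with `A` the overall body condition score (BCS, Henneke
1–9 scale with the six-region Kohnke averaging), `DE_M` the digestible-
energy maintenance requirement (Mcal/day, NRC-style coefficients), `D` the
digestible-energy intake (Mcal/day) and `ΔDE` the per-BCS-unit energy
adjustment fraction (NRC band 10–15%, default 12.5%):

```
B     = 5 − A                    BCS deficit from the ideal score of 5
C     = B × DE_M × ΔDE           Mcal/day adjustment to reach ideal BCS
RDI5% = (D + C) / DE_M × 100     recommended dietary intake, % of maintenance
```

which collapses to the closed form `RDI5% = DEI% + (5 − BCS) × ΔDE × 100`,
independent of body weight. RDI5% is the classification variable: horses
that would reach ideal condition on well under maintenance are easy
keepers, well over are hard keepers. Three groups (EK / MK / HK) and seven
finer levels (E+, E, M+, M, M−, H, H−) partition the RDI5% axis; the
shipped cutoffs (EK < 90, MK 90–110, HK > 110) are configurable.

The package also provides:

- **bcs** — regional score averaging, lean/normal/obese ranks, and the
  estimated total body fat equation `eTBF% = 0.006 + 1.56 × BCS`;
- **energy** — DE/CP maintenance requirements from editable coefficient
  tables, ration aggregation, and the ad-libitum rule (access-time intake
  estimate capped at 2% of body weight);
- **cohort** — status distributions, ORKS×EKSS agreement (overall,
  per-class, mosaic fractions, membership Spearman correlations),
  Kruskal–Wallis + pairwise Wilcoxon/Benjamini–Hochberg comparisons with
  compact letter displays;
- **microbiome** — rank aggregation, relative abundance with a <1%
  "Others" collapse, Firmicutes/Bacteroidetes ratio, Shannon/observed
  alpha diversity, seeded rarefaction, and the |r| ≥ 0.3 Spearman screen;
- **simulate** — synthetic cohorts and Dirichlet-multinomial count tables
  with known ground truth.

## Worked example

Simulate a 60-horse cohort, assign keeper statuses, and compare with the
simulated owners' labels:

```sh
ekss simulate --out-dir demo --seed 42 --n-horses 60
ekss assign --horses demo/horses.csv --scores demo/scores.csv \
            --rations demo/rations.csv --out demo/results.csv
ekss agree --results demo/results.csv --out demo/agreement.json
```

The first rows of `demo/results.csv`:

```
horse_id  overall_bcs  dei_percent  rdi5_percent ekss_group ekss_level
   H0001     5.928737   120.196680    108.587473         MK         M-
   H0002     5.381561   129.379905    124.610394         HK          H
   H0003     6.257257    87.574312     71.858595         EK         E+
```

H0001 eats 120% of maintenance but is nearly a BCS point over-conditioned;
correcting for that, 108.6% of maintenance would hold it at ideal
condition — a medium keeper at the scale's upper edge (M−). H0003 is
over-conditioned *and* eating under maintenance: it would hold condition
on 71.9% of maintenance, a pronounced easy keeper (E+).

The cohort splits 22 EK / 19 MK / 19 HK, and `demo/agreement.json` reports
41.7% overall owner agreement (EK 36.4%, MK 26.7%, HK 56.5% per owner
class) — the simulator's default owner-confusion matrix mirrors the field
observation that owners recognize hard keepers best and medium keepers
worst.

A `microbiome` subcommand screens taxon-by-sample TSV count tables for
keeper-group associations; see `ekss microbiome --help`.

## Scope notes

The scale is defined for horses only (donkeys and mules have different
feed-conversion and fat-distribution profiles). Upstream amplicon
processing (denoising, taxonomy assignment), compositional
differential-abundance tests and phylogenetic beta diversity are out of
scope; count tables arrive already tabulated. See `docs/methods.md` for
the model, parameter and design details.
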