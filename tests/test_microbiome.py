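"""Abundance-table statistics: aggregation, diversity, rarefaction, screening."""

import numpy as np
import pandas as pd
import pytest

from ekss.errors import ValidationError
from ekss.microbiome import (
    AbundanceTable,
    aggregate_rank,
    alpha_diversity,
    fb_ratio,
    normalize_and_rarefy,
    normalize_to_depth,
    parse_lineage,
    rarefy,
    relative_abundance,
    taxa_status_correlations,
)
from ekss.simulate import PlantedEffect, TaxaSimParams, simulate_taxa


class TestAggregateRank:
    def test_prefixed_lineage_parsing(self):
        assert parse_lineage("d__Bacteria;p__Firmicutes;c__X")[1] == "Firmicutes"
        assert parse_lineage("Bacteria;Firmicutes")[0] == "Bacteria"

    def test_phylum_additivity(self, tiny_table):
        phyla = aggregate_rank(tiny_table, "phylum")
        # two Firmicutes genera with counts 30 and 40 in s1
        assert phyla.counts.loc["Firmicutes", "s1"] == 70

    def test_identity_when_one_taxon_per_rank(self, tiny_table):
        genera = aggregate_rank(tiny_table, "genus")
        assert genera.counts.shape == tiny_table.counts.shape
        assert genera.counts.to_numpy().sum() == tiny_table.counts.to_numpy().sum()

    def test_unresolved_mass_conserved_under_unclassified(self):
        counts = pd.DataFrame(
            {"s1": [10, 5, 3]},
            index=["d__Bacteria;p__Firmicutes;c__C;o__O;f__F;g__G",
                   "d__Bacteria;p__;c__;o__;f__;g__",
                   "d__Bacteria"],
        )
        table = AbundanceTable(counts=counts)
        genera = aggregate_rank(table, "genus")
        assert genera.counts.loc["unclassified", "s1"] == 8
        assert genera.counts["s1"].sum() == 18

    def test_unknown_rank(self, tiny_table):
        with pytest.raises(ValidationError):
            aggregate_rank(tiny_table, "kingdom")


class TestRelativeAbundance:
    def test_single_taxon_is_one(self):
        table = AbundanceTable(counts=pd.DataFrame({"s1": [42]}, index=["t"]))
        props = relative_abundance(table)
        assert props.loc["t", "s1"] == pytest.approx(1.0)

    def test_subthreshold_taxa_pool_into_others(self):
        counts = pd.DataFrame(
            {"s1": [500, 490, 6, 4]}, index=["a", "b", "c", "d"]
        )
        props = relative_abundance(AbundanceTable(counts=counts),
                                   collapse_threshold=0.01)
        assert set(props.index) == {"a", "b", "Others"}
        assert props.loc["Others", "s1"] == pytest.approx(0.010)
        assert props["s1"].sum() == pytest.approx(1.0)

    def test_columns_sum_to_one(self, tiny_table):
        props = relative_abundance(tiny_table, collapse_threshold=0.05)
        assert np.allclose(props.sum(axis=0), 1.0)

    def test_group_means_weight_samples_equally(self, tiny_table):
        props = relative_abundance(tiny_table, collapse_threshold=0.0,
                                   per_group=True)
        per_sample = tiny_table.counts.div(tiny_table.counts.sum(axis=0), axis=1)
        expected_ek = per_sample[["s1", "s2"]].mean(axis=1)
        first = tiny_table.counts.index[0]
        assert props.loc[first, "EK"] == pytest.approx(expected_ek[first])

    def test_zero_sum_sample_rejected(self):
        counts = pd.DataFrame({"s1": [1], "s2": [0]}, index=["t"])
        with pytest.raises(ValidationError, match="s2"):
            relative_abundance(AbundanceTable(counts=counts))


class TestFBRatio:
    def test_equal_masses_give_one(self):
        counts = pd.DataFrame(
            {"s1": [50, 50]},
            index=["d__B;p__Firmicutes;c__;o__;f__;g__a",
                   "d__B;p__Bacteroidetes;c__;o__;f__;g__b"],
        )
        table = AbundanceTable(counts=counts,
                               sample_labels=pd.Series({"s1": "EK"}))
        assert fb_ratio(table)["EK"] == pytest.approx(1.0)

    def test_synthetic_112_ratio(self):
        counts = pd.DataFrame(
            {"s1": [528, 472]},
            index=["d__B;p__Firmicutes;c__;o__;f__;g__a",
                   "d__B;p__Bacteroidetes;c__;o__;f__;g__b"],
        )
        table = AbundanceTable(counts=counts,
                               sample_labels=pd.Series({"s1": "HK"}))
        assert fb_ratio(table)["HK"] == pytest.approx(1.12, abs=0.005)

    def test_invariant_under_total_sum_scaling(self, tiny_table):
        base = fb_ratio(tiny_table)
        scaled = fb_ratio(normalize_to_depth(tiny_table, depth=10_000))
        for group in base.index:
            assert scaled[group] == pytest.approx(base[group])

    def test_zero_bacteroidetes_is_na(self):
        counts = pd.DataFrame(
            {"s1": [10, 5]},
            index=["d__B;p__Firmicutes;c__;o__;f__;g__a",
                   "d__B;p__Proteobacteria;c__;o__;f__;g__b"],
        )
        table = AbundanceTable(counts=counts,
                               sample_labels=pd.Series({"s1": "MK"}))
        assert np.isnan(fb_ratio(table)["MK"])


class TestAlphaDiversity:
    def test_single_taxon(self):
        table = AbundanceTable(counts=pd.DataFrame({"s1": [9]}, index=["t"]))
        alpha = alpha_diversity(table)
        assert alpha.loc["s1", "observed"] == 1
        assert alpha.loc["s1", "shannon"] == pytest.approx(0.0)

    @pytest.mark.parametrize("k", [2, 5, 16])
    def test_equal_abundances_hit_log_k(self, k):
        table = AbundanceTable(
            counts=pd.DataFrame({"s1": [10] * k}, index=[f"t{i}" for i in range(k)])
        )
        assert alpha_diversity(table).loc["s1", "shannon"] == pytest.approx(np.log(k))
        assert alpha_diversity(table, base=2).loc["s1", "shannon"] == pytest.approx(
            np.log2(k)
        )

    def test_matches_brute_force_and_skbio(self, tiny_table):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        alpha = alpha_diversity(tiny_table)
        for sample in tiny_table.samples:
            counts = tiny_table.counts[sample].to_numpy(dtype=float)
            p = counts / counts.sum()
            brute = -np.sum(p[p > 0] * np.log(p[p > 0]))
            assert alpha.loc[sample, "shannon"] == pytest.approx(brute)
            assert alpha.loc[sample, "shannon"] == pytest.approx(
                float(skbio_alpha.shannon(counts.astype(int), base=np.e))
            )
            assert alpha.loc[sample, "observed"] == int((counts > 0).sum())


class TestNormalizeAndRarefy:
    def test_normalization_equalizes_depths(self, tiny_table):
        normalized = normalize_to_depth(tiny_table, depth=1000)
        assert np.allclose(normalized.sample_sums(), 1000.0)

    def test_default_depth_is_median(self, tiny_table):
        normalized = normalize_to_depth(tiny_table)
        assert np.allclose(
            normalized.sample_sums(), float(tiny_table.sample_sums().median())
        )

    def test_rarefied_columns_sum_exactly_to_depth(self, tiny_table):
        rarefied = rarefy(tiny_table, depth=80, seed=1)
        assert (rarefied.sample_sums() == 80).all()

    def test_rarefied_counts_bounded_by_originals(self, tiny_table):
        rarefied = rarefy(tiny_table, depth=50, seed=2)
        assert (rarefied.counts.to_numpy()
                <= tiny_table.counts.to_numpy()).all()

    def test_rarefy_to_own_depth_is_identity(self, tiny_table):
        depth = int(tiny_table.sample_sums().min())
        shallow = tiny_table.counts.columns[
            tiny_table.sample_sums() == depth
        ][0]
        rarefied = rarefy(tiny_table, depth=depth, seed=3)
        pd.testing.assert_series_equal(
            rarefied.counts[shallow], tiny_table.counts[shallow],
            check_dtype=False,
        )

    def test_fixed_seed_is_bit_reproducible(self, tiny_table):
        a = rarefy(tiny_table, depth=60, seed=7)
        b = rarefy(tiny_table, depth=60, seed=7)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_shallow_samples_dropped_with_warning(self, tiny_table, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="ekss.microbiome"):
            rarefied = rarefy(tiny_table, depth=95, seed=0)
        assert "s4" not in rarefied.counts.columns  # sum 90 < 95
        assert rarefied.sample_labels is not None
        assert "s4" not in rarefied.sample_labels.index
        assert any("dropping" in rec.message for rec in caplog.records)

    def test_rarefied_means_converge_to_expected_proportions(self, tiny_table):
        # Monte-Carlo: across seeds, per-taxon rarefied means approach
        # depth x original proportion.
        depth = 60
        sample = "s1"
        draws = np.stack(
            [
                rarefy(tiny_table, depth=depth, seed=s).counts[sample].to_numpy()
                for s in range(300)
            ]
        )
        p = tiny_table.counts[sample] / tiny_table.counts[sample].sum()
        assert np.allclose(draws.mean(axis=0), depth * p, atol=0.6)

    def test_normalize_then_rarefy_pipeline(self, tiny_table):
        out = normalize_and_rarefy(tiny_table, depth=50, seed=4)
        assert (out.sample_sums() == 50).all()


class TestStatusCorrelations:
    def test_planted_taxon_has_strong_positive_r(self):
        counts = pd.DataFrame(
            {
                "e1": [100, 50], "e2": [120, 60], "e3": [110, 55],
                "h1": [10, 50], "h2": [12, 60], "h3": [8, 55],
            },
            index=["d__B;p__F;c__;o__;f__;g__planted",
                   "d__B;p__F;c__;o__;f__;g__flat"],
        )
        labels = pd.Series(
            {s: ("EK" if s.startswith("e") else "HK") for s in counts.columns}
        )
        table = AbundanceTable(counts=counts, sample_labels=labels)
        screen = taxa_status_correlations(table, report_all=True)
        planted_ek = screen[
            (screen.taxon.str.contains("planted")) & (screen.group == "EK")
        ].iloc[0]
        assert planted_ek.r > 0.7
        assert planted_ek.sign == "+"
        assert planted_ek.flagged

    def test_constant_taxon_reported_na_only_with_report_all(self):
        counts = pd.DataFrame(
            {"a": [5, 1], "b": [5, 9], "c": [5, 4]},
            index=["t_const", "t_var"],
        )
        labels = pd.Series({"a": "EK", "b": "HK", "c": "HK"})
        table = AbundanceTable(counts=counts, sample_labels=labels)
        screen = taxa_status_correlations(table, report_all=True,
                                          use_proportions=False)
        const_rows = screen[screen.taxon == "t_const"]
        assert const_rows.r.isna().all()
        assert not const_rows.flagged.any()
        default = taxa_status_correlations(table, use_proportions=False)
        assert not (default.taxon == "t_const").any()

    def test_permuted_labels_flag_near_chance(self, rng):
        table, _ = simulate_taxa(TaxaSimParams(seed=42))
        labels = table.labels_for(table.samples)
        rates = []
        for _ in range(10):
            screen = taxa_status_correlations(
                table, labels=rng.permutation(labels)
            )
            rates.append(len(screen) / (table.n_taxa * 3))
        assert np.mean(rates) < 0.10  # no systematic signal

    def test_planted_fourfold_effects_recovered(self):
        effects = (PlantedEffect(3, "EK", 4.0), PlantedEffect(11, "HK", 4.0))
        table, truth = simulate_taxa(
            TaxaSimParams(planted_effects=effects, seed=5)
        )
        screen = taxa_status_correlations(table)
        flagged = set(zip(screen.taxon, screen.group))
        for _, row in truth.iterrows():
            assert (row.taxon, row.group) in flagged
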