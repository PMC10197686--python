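import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcdecay.features import (codon_frequencies, codon_position_gc,
                              gc_content, partition_by_gc, region_features)


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [
        ("ATGC", 0.5),
        ("GGCC", 1.0),
        ("ATGGCGTAA", 4 / 9),
        ("AANNT", 0.0),        # N excluded from the denominator
        ("GNC", 1.0),
    ])
    def test_known_values(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_empty_and_all_n_are_missing(self):
        assert math.isnan(gc_content(""))
        assert math.isnan(gc_content("NNN"))

    @settings(max_examples=200, deadline=None)
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=200))
    def test_matches_character_count_oracle(self, seq):
        gc = seq.count("G") + seq.count("C")
        at = seq.count("A") + seq.count("T")
        if gc + at == 0:
            assert math.isnan(gc_content(seq))
        else:
            assert gc_content(seq) == pytest.approx(gc / (gc + at))


class TestCodonPositionGc:
    def test_gca_repeat(self):
        assert codon_position_gc("GCAGCAGCA") == (1.0, 1.0, 0.0)

    def test_all_a(self):
        assert codon_position_gc("AAA") == (0.0, 0.0, 0.0)

    @settings(max_examples=100, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=3, max_size=150).filter(
        lambda s: len(s) % 3 == 0))
    def test_mean_of_positions_equals_total_gc(self, cds):
        gc1, gc2, gc3 = codon_position_gc(cds)
        assert (gc1 + gc2 + gc3) / 3 == pytest.approx(gc_content(cds))

    def test_bad_length_names_gene(self):
        with pytest.raises(ValueError, match="myGene"):
            codon_position_gc("ATGA", gene_id="myGene")


class TestCodonFrequencies:
    def test_single_codon(self):
        f = codon_frequencies("ATGTAA")
        assert f["ATG"] == 1.0
        assert f.drop("ATG").eq(0).all()

    def test_stop_codons_excluded_entirely(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f = codon_frequencies("ATGATGTGA")
        assert f["ATG"] == 1.0
        assert f.sum() == pytest.approx(1.0)

    def test_poly_gct(self):
        cds = "ATG" + "GCT" * 9 + "TAA"
        f = codon_frequencies(cds)
        assert f["GCT"] == pytest.approx(9 / 10)
        assert f["ATG"] == pytest.approx(1 / 10)

    def test_internal_stop_warns_but_counts(self):
        with pytest.warns(UserWarning, match="internal stop"):
            f = codon_frequencies("ATGTAAGCT", gene_id="g1")
        assert f.sum() == pytest.approx(1.0)

    def test_frequencies_sum_to_one_on_simulated_genes(self, annotation_small):
        for rec in annotation_small.records[:20]:
            f = codon_frequencies(rec.cds_seq)
            assert abs(f.sum() - 1.0) < 1e-9


@pytest.fixture(scope="module")
def table(sim_small):
    return region_features(sim_small.annotation, sim_small.counts,
                           sim_small.design, sim_small.region_counts)


class TestRegionFeatures:
    def test_one_row_per_gene_with_cds(self, table, sim_small):
        assert len(table) == len(sim_small.annotation)
        assert not table["GCcds"].isna().any()

    def test_gc_columns_in_unit_interval(self, table):
        gc_cols = [c for c in table.columns
                   if c.startswith(("GCpct_", "GCpos", "GCcds"))]
        vals = table[gc_cols].values
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_gccds_matches_direct_computation(self, table, annotation_small):
        for rec in annotation_small.records[:10]:
            assert table.loc[rec.gene_id, "GCcds"] == \
                pytest.approx(gc_content(rec.cds_seq))

    def test_intronless_gene_gets_sentinels(self, table, annotation_small):
        intronless = [r.gene_id for r in annotation_small
                      if not r.introns]
        assert intronless, "fixture should contain intronless genes"
        sub = table.loc[intronless]
        assert (sub["loglen_intron"] == 0.0).all()
        assert (sub["posdens_rna_intron"] == 0.0).all()

    def test_gene_order_insensitivity(self, sim_small):
        from gcdecay.annotation import TranscriptAnnotation

        fwd = region_features(sim_small.annotation, sim_small.counts,
                              sim_small.design, sim_small.region_counts)
        rev_ann = TranscriptAnnotation(sim_small.annotation.records[::-1])
        rev = region_features(rev_ann, sim_small.counts,
                              sim_small.design, sim_small.region_counts)
        pd.testing.assert_frame_equal(fwd, rev)

    def test_equal_baseline_counts_give_zero_log_te(self, sim_small):
        counts = sim_small.counts.copy()
        ctrl = sim_small.design[sim_small.design.condition == "control"]
        rna = ctrl[ctrl.assay == "RNA"]["sample"]
        ribo = ctrl[ctrl.assay == "Ribo"]["sample"]
        counts[ribo.tolist()] = counts[rna.tolist()].values
        t = region_features(sim_small.annotation, counts,
                            sim_small.design, sim_small.region_counts)
        assert np.allclose(t["base_TE"], 0.0)


class TestPartitionByGc:
    def test_constant_gc_single_group(self):
        gc = pd.Series(0.5, index=[f"g{i}" for i in range(20)])
        vals = pd.Series(np.arange(20.0), index=gc.index)
        groups, summary, tests = partition_by_gc(vals, gc, n_groups=3)
        assert summary["count"].gt(0).sum() == 1
        assert (tests["status"] == "skipped").all() or tests.empty

    def test_planted_monotone_signal(self):
        rng = np.random.default_rng(0)
        gc = pd.Series(np.repeat([0.3, 0.5, 0.7], 40),
                       index=[f"g{i}" for i in range(120)])
        vals = gc + pd.Series(rng.normal(0, 0.02, 120), index=gc.index)
        groups, summary, tests = partition_by_gc(vals, gc, n_groups=3)
        medians = summary.sort_values("gc_group")["median"].values
        assert (np.diff(medians) > 0).all()
        extreme = tests[(tests.group_a == 0) & (tests.group_b == 2)]
        assert float(extreme["pvalue"].iloc[0]) < 0.05

    def test_half_life_partition_pattern(self):
        # 220 genes whose decay half-life is negatively coupled to GCcds:
        # the high-GC tertile should show the lowest median half-life
        rng = np.random.default_rng(1)
        gc = pd.Series(rng.uniform(0.35, 0.75, 220),
                       index=[f"g{i}" for i in range(220)])
        hl = np.exp(np.log(8.0) - 1.5 * (gc - 0.55) + rng.normal(0, 0.1, 220))
        groups, summary, tests = partition_by_gc(pd.Series(hl, index=gc.index),
                                                 gc, n_groups=3)
        s = summary.sort_values("gc_group")
        assert s["median"].iloc[-1] == s["median"].min()

    def test_quantile_scheme_balances_groups(self):
        rng = np.random.default_rng(2)
        gc = pd.Series(rng.uniform(0, 1, 90), index=range(90))
        vals = pd.Series(rng.normal(size=90), index=range(90))
        groups, summary, _ = partition_by_gc(vals, gc, 3, scheme="quantile")
        assert summary["count"].between(29, 31).all()

    def test_too_few_groups_rejected(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            partition_by_gc(s, s, n_groups=1)
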