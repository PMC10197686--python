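import numpy as np
import pandas as pd
import pytest

from gcdecay.annotation import TranscriptAnnotation, TranscriptRecord
from gcdecay.simulate import SimConfig, simulate_all, simulate_slam
from gcdecay.slam import (ConversionTable, class_retention_test, count_tc_reads,
                          pairs_converted, stability_test)


class TestPairsConverted:
    def test_no_mismatch_not_converted(self):
        pairs = [("A", "A"), ("T", "T"), ("G", "G")]
        assert not pairs_converted(pairs, "+")

    def test_plus_strand_t_to_c(self):
        pairs = [("A", "A")] * 10 + [("T", "C")]
        assert pairs_converted(pairs, "+")
        assert not pairs_converted(pairs, "-")

    def test_minus_strand_reads_genomic_a_to_g(self):
        assert pairs_converted([("a", "G")], "-")
        assert not pairs_converted([("t", "C")], "-")

    def test_min_conversions_threshold(self):
        pairs = [("T", "C"), ("T", "T")]
        assert pairs_converted(pairs, "+", min_conversions=1)
        assert not pairs_converted(pairs, "+", min_conversions=2)

    def test_bad_strand_rejected(self):
        with pytest.raises(ValueError):
            pairs_converted([], ".")


def _write_sam(path, ref_name, ref_len, reads):
    """reads: list of (name, pos0, seq, md, mapq)."""
    import pysam

    header = {"HD": {"VN": "1.6"},
              "SQ": [{"SN": ref_name, "LN": ref_len}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for name, pos0, seq, md, mapq in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.query_sequence = seq
            a.reference_id = 0
            a.reference_start = pos0
            a.mapping_quality = mapq
            a.cigarstring = f"{len(seq)}M"
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            a.set_tag("MD", md)
            out.write(a)


def _mismatch_read(ref, pos0, length, subs):
    """Build (seq, MD) for a read with reference substitutions ``subs``
    mapping read offset -> new base."""
    ref_piece = ref[pos0 : pos0 + length]
    seq = list(ref_piece)
    md, run = [], 0
    for i in range(length):
        if i in subs:
            md.append(str(run))
            md.append(ref_piece[i])
            seq[i] = subs[i]
            run = 0
        else:
            run += 1
    md.append(str(run))
    return "".join(seq), "".join(md)


@pytest.fixture()
def tiny_gene_pair():
    ref_plus = ("ATG" + "ACGT" * 24 + "TAA")  # 102 nt
    plus = TranscriptRecord(
        gene_id="gplus", transcript_id="tplus", chrom="chrP", strand="+",
        genome_start=1, seq=ref_plus, cds_start=1, cds_end=102)
    ref_minus = ("ATG" + "TCGA" * 24 + "TGA")
    minus = TranscriptRecord(
        gene_id="gminus", transcript_id="tminus", chrom="chrM", strand="-",
        genome_start=1, seq=ref_minus, cds_start=1, cds_end=102)
    return plus, minus


class TestCountTcReads(object):
    def test_sam_counting_by_strand(self, tmp_path, tiny_gene_pair):
        plus, minus = tiny_gene_pair
        ann = TranscriptAnnotation([plus, minus])
        # genomic reference of the minus-strand gene is the revcomp of its
        # transcript; build reads against the genomic sequence directly
        genome_p = plus.seq
        comp = str.maketrans("ACGT", "TGCA")
        genome_m = minus.seq.translate(comp)[::-1]

        sam_p = tmp_path / "p.sam"
        t_off = genome_p.index("T", 5)
        a_off = genome_p.index("A", 5)
        _write_sam(sam_p, "chrP", len(genome_p), [
            ("clean", 0, *_mismatch_read(genome_p, 0, 30, {}), 60),
            ("conv", 0, *_mismatch_read(genome_p, 0, 30, {t_off: "C"}), 60),
            ("wrong_sub", 0, *_mismatch_read(genome_p, 0, 30, {a_off: "G"}), 60),
            ("low_mapq", 0, *_mismatch_read(genome_p, 0, 30, {t_off: "C"}), 5),
        ])
        sam_m = tmp_path / "m.sam"
        ag_off = genome_m.index("A", 5)
        tc_off = genome_m.index("T", 5)
        _write_sam(sam_m, "chrM", len(genome_m), [
            ("conv_m", 0, *_mismatch_read(genome_m, 0, 30, {ag_off: "G"}), 60),
            ("not_conv_m", 0, *_mismatch_read(genome_m, 0, 30, {tc_off: "C"}), 60),
        ])

        out_p = count_tc_reads(sam_p, TranscriptAnnotation([plus]))
        row = out_p.set_index("gene_id").loc["gplus"]
        assert row["total_reads"] == 3      # low-mapq read excluded
        assert row["tc_reads"] == 1

        out_m = count_tc_reads(sam_m, TranscriptAnnotation([minus]))
        row = out_m.set_index("gene_id").loc["gminus"]
        assert row["total_reads"] == 2
        assert row["tc_reads"] == 1         # genomic A>G counts on minus strand

    def test_blacklist_masks_position(self, tmp_path, tiny_gene_pair):
        plus, _ = tiny_gene_pair
        genome_p = plus.seq
        t_off = genome_p.index("T", 5)
        sam = tmp_path / "bl.sam"
        _write_sam(sam, "chrP", len(genome_p), [
            ("conv", 0, *_mismatch_read(genome_p, 0, 30, {t_off: "C"}), 60)])
        ann = TranscriptAnnotation([plus])
        assert count_tc_reads(sam, ann)["tc_reads"].iloc[0] == 1
        masked = count_tc_reads(sam, ann,
                                blacklist={("chrP", t_off + 1)})
        assert masked["tc_reads"].iloc[0] == 0


class TestConversionTable:
    def test_tc_cannot_exceed_total(self):
        counts = pd.DataFrame({"gene_id": ["g"], "sample": ["s"],
                               "total_reads": [10], "tc_reads": [11]})
        samples = pd.DataFrame({"sample": ["s"], "labeling": ["4sU"],
                                "degron": ["control"], "chase_h": [0.0],
                                "replicate": [1]})
        with pytest.raises(ValueError, match="exceed"):
            ConversionTable(counts, samples)

    def test_simulated_tables_conserve_reads(self, sim_small):
        c = sim_small.conversion.counts
        assert (c["tc_reads"] <= c["total_reads"]).all()

    def test_unlabeled_fraction_at_background(self, sim_small):
        frac = sim_small.conversion.tc_fraction()
        s = sim_small.conversion.samples
        unlabeled = s[s.labeling == "DMSO"]["sample"]
        assert frac[unlabeled].values.mean() == pytest.approx(0.01, abs=0.005)

    def test_half_life_decay_identity(self, truth_small):
        # chase of one half-life at zero background halves the fraction
        cfg = SimConfig(n_genes=150, seed=13)
        truth = truth_small
        conv = simulate_slam(cfg, truth, background=0.0)
        frac = conv.tc_fraction()
        s = conv.samples.set_index("sample")
        chase0 = s.index[(s.labeling == "4sU") & (s.chase_h == 0)]
        chase8 = s.index[(s.labeling == "4sU") & (s.chase_h == 8)
                         & (s.degron == "control")]
        hl = truth.genes.set_index("gene_id")["half_life_control"]
        near8 = hl[(hl - 8).abs() < 0.5].index
        if len(near8) >= 5:
            ratio = (frac.loc[near8, chase8].mean(axis=1)
                     / frac.loc[near8, chase0].mean(axis=1))
            assert ratio.mean() == pytest.approx(0.5, abs=0.1)


@pytest.fixture(scope="module")
def stab(sim_small):
    return stability_test(sim_small.conversion)


class TestStabilityTest:
    def test_stabilized_genes_positive_coefficient(self, stab, truth_small):
        truth = truth_small.genes.set_index("gene_id")
        powered = truth.index[(truth.class_label == "TE_down")
                              & (truth.baseline_rna > 100)]
        sub = stab.loc[stab.index.intersection(powered)]
        assert (sub["degron_l2fc"] > 0).mean() >= 0.9

    def test_class_field_consistent_with_p(self, stab):
        ns = stab["stability_class"] == "NS"
        assert (ns == (stab["pvalue"] >= 0.05)).all()

    def test_zero_tc_genes_excluded(self, sim_small):
        conv = sim_small.conversion
        gene0 = conv.counts["gene_id"].iloc[0]
        counts = conv.counts.copy()
        counts.loc[counts.gene_id == gene0, "tc_reads"] = 0
        res = stability_test(ConversionTable(counts, conv.samples))
        assert gene0 in res.attrs["excluded"]

    def test_retention_test_detects_planted_stabilization(self, sim_small,
                                                          truth_small):
        classes = truth_small.genes.set_index("gene_id")["class_label"]
        out = class_retention_test(sim_small.conversion, classes)
        assert out["median_a"] > out["median_b"]
        assert out["pvalue"] < 0.05
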