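"""SLAM-seq T>C conversion counting and differential stability testing.

4-thiouridine incorporated during labeling is read out as T>C mismatches
(on the transcribed strand) after chemical conversion, so the fraction of
reads that carry at least one T>C mismatch tracks how much labeled RNA
survives a uridine chase.  Stability regulation is tested per gene with
an NB GLM on T>C-containing read counts, offset by total reads, with
labeling and degron status as covariates; the degron term is dropped in
the reduced model for a likelihood-ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gcdecay.nbglm import (bh_adjust, fit_nb_glm_single, lr_test,
                           moderated_dispersions)

LN2 = np.log(2.0)


@dataclass
class ConversionTable:
    """Per gene x sample read totals and T>C-containing read counts."""

    counts: pd.DataFrame   # gene_id, sample, total_reads, tc_reads
    samples: pd.DataFrame  # sample, labeling, degron, chase_h, replicate

    def __post_init__(self) -> None:
        c = self.counts
        if (c["tc_reads"] > c["total_reads"]).any():
            raise ValueError("T>C reads exceed total reads")
        if (c["tc_reads"] < 0).any() or (c["total_reads"] < 0).any():
            raise ValueError("negative read counts")
        need = {"labeling", "degron"}
        if self.samples[list(need)].isna().any().any():
            raise ValueError("every sample needs labeling and degron status")

    def tc_fraction(self) -> pd.DataFrame:
        """Gene x sample matrix of converted-read fractions."""
        c = self.counts.copy()
        c["frac"] = c["tc_reads"] / c["total_reads"].clip(lower=1)
        return c.pivot(index="gene_id", columns="sample", values="frac")

    @classmethod
    def from_tsv(cls, counts_path, samples_path):
        return cls(pd.read_csv(counts_path, sep="\t"),
                   pd.read_csv(samples_path, sep="\t"))


# ---------------------------------------------------------------------------
# T>C read calling
# ---------------------------------------------------------------------------

def pairs_converted(pairs, strand: str, min_conversions: int = 1) -> bool:
    """Decide conversion status from (reference base, read base) pairs.

    A conversion is T(reference)->C(read) on the transcribed strand: for
    a minus-strand gene the aligner reports genomic bases, so the
    signature is A->G.  Case-insensitive; ``None`` bases are skipped.
    """
    if strand == "+":
        ref_want, read_want = "T", "C"
    elif strand == "-":
        ref_want, read_want = "A", "G"
    else:
        raise ValueError(f"bad strand {strand!r}")
    n = 0
    for ref_base, read_base in pairs:
        if ref_base is None or read_base is None:
            continue
        if ref_base.upper() == ref_want and read_base.upper() == read_want:
            n += 1
            if n >= min_conversions:
                return True
    return False


def read_conversion_pairs(read, min_baseq: int = 20):
    """Extract mismatch (ref, read) base pairs from an aligned read.

    Requires the MD tag (``get_aligned_pairs(with_seq=True)``); returns
    ``None`` when mismatch information is unavailable.  Bases below
    ``min_baseq`` are dropped when base qualities are present.
    """
    try:
        aligned = read.get_aligned_pairs(with_seq=True)
    except ValueError:
        return None
    quals = read.query_qualities
    seq = read.query_sequence
    pairs = []
    for qpos, rpos, ref_base in aligned:
        if qpos is None or rpos is None or ref_base is None:
            continue
        if quals is not None and quals[qpos] < min_baseq:
            continue
        pairs.append((ref_base, seq[qpos]))
    return pairs


def count_tc_reads(bam_path, annotation, min_mapq: int = 10,
                   min_baseq: int = 20, min_conversions: int = 1,
                   blacklist=None) -> pd.DataFrame:
    """Count total and T>C-containing reads per gene from a BAM/SAM file.

    Reads overlapping a gene's exons count toward its total; a read is
    converted when it carries >= ``min_conversions`` T>C mismatches on
    the gene's strand.  Reads below ``min_mapq`` or without mismatch
    information are excluded (the latter tallied in ``no_md_reads``).
    ``blacklist`` is an optional set of (chrom, pos) reference positions
    whose mismatches are ignored (SNP masking).
    """
    import pysam

    mode = "r" if str(bam_path).endswith(".sam") else "rb"
    rows = []
    with pysam.AlignmentFile(str(bam_path), mode) as bam:
        has_index = bam.has_index()
        reads_by_ref = None
        if not has_index:  # small SAM inputs: bucket reads by contig
            reads_by_ref = {}
            for read in bam.fetch(until_eof=True):
                reads_by_ref.setdefault(read.reference_name, []).append(read)
        for rec in annotation:
            intervals = rec.genomic_intervals(1, rec.length)
            total = converted = no_md = 0
            seen = set()
            if has_index:
                reads = []
                for lo, hi in intervals:
                    reads.extend(bam.fetch(rec.chrom, lo - 1, hi))
            else:
                reads = reads_by_ref.get(rec.chrom, [])
            for read in reads:
                if read.is_unmapped or read.mapping_quality < min_mapq:
                    continue
                if read.query_name in seen:
                    continue
                if not has_index and not _overlaps(read, intervals):
                    continue
                seen.add(read.query_name)
                pairs = read_conversion_pairs(read, min_baseq)
                if pairs is None:
                    no_md += 1
                    continue
                if blacklist:
                    pairs = _apply_blacklist(read, pairs, rec.chrom,
                                             blacklist, min_baseq)
                total += 1
                if pairs_converted(pairs, rec.strand, min_conversions):
                    converted += 1
            rows.append((rec.gene_id, total, converted, no_md))
    return pd.DataFrame(rows, columns=["gene_id", "total_reads", "tc_reads",
                                       "no_md_reads"])


def _overlaps(read, intervals) -> bool:
    s, e = read.reference_start + 1, read.reference_end
    return any(s <= hi and e >= lo for lo, hi in intervals)


def _apply_blacklist(read, pairs, chrom, blacklist, min_baseq):
    aligned = read.get_aligned_pairs(with_seq=True)
    quals = read.query_qualities
    seq = read.query_sequence
    out = []
    for qpos, rpos, ref_base in aligned:
        if qpos is None or rpos is None or ref_base is None:
            continue
        if quals is not None and quals[qpos] < min_baseq:
            continue
        if (chrom, rpos + 1) in blacklist:
            continue
        out.append((ref_base, seq[qpos]))
    return out


# ---------------------------------------------------------------------------
# stability test
# ---------------------------------------------------------------------------

def stability_test(table: ConversionTable, p_cutoff: float = 0.05,
                   refine_dispersion: bool = True) -> pd.DataFrame:
    """Differential stability from T>C counts (labeling + degron design).

    Per gene, fits ``tc_reads ~ labeling + degron`` with ``log(total
    reads)`` as offset and LRT-drops the degron term.  A positive degron
    coefficient means more converted reads retained under depletion,
    i.e. stabilization.  Genes with no T>C reads in any labeled sample
    are excluded and reported in ``.attrs['excluded']``.
    """
    samples = table.samples
    # the 2x2 labeling x degron design lives at the chase endpoint;
    # chase-0 samples are collected before degron induction
    chase = samples["chase_h"].max()
    samples = samples[samples["chase_h"] == chase].set_index("sample")
    keep_cols = table.counts["sample"].isin(samples.index)
    table = ConversionTable(table.counts[keep_cols].copy(),
                            samples.reset_index())
    wide_tc = table.counts.pivot(index="gene_id", columns="sample",
                                 values="tc_reads")
    wide_tot = table.counts.pivot(index="gene_id", columns="sample",
                                  values="total_reads")
    order = samples.index.tolist()
    wide_tc, wide_tot = wide_tc[order], wide_tot[order]

    labeled_cols = samples.index[samples["labeling"] == "4sU"]
    keep = wide_tc[labeled_cols].sum(axis=1) > 0
    excluded = list(wide_tc.index[~keep])
    wide_tc, wide_tot = wide_tc[keep], wide_tot[keep]

    lab = (samples["labeling"].values == "4sU").astype(float)
    deg = (samples["degron"].values == "treated").astype(float)
    ones = np.ones_like(lab)
    X_full = np.column_stack([ones, lab, deg])
    X_red = np.column_stack([ones, lab])

    mat = wide_tc.values
    offs = np.log(wide_tot.values.clip(min=1))

    alphas, _ = moderated_dispersions(mat, X_full, offs,
                                      refine=refine_dispersion)

    rows = []
    for y, off, a in zip(mat, offs, alphas):
        full = fit_nb_glm_single(y, X_full, off, alpha=a)
        red = fit_nb_glm_single(y, X_red, off, alpha=a)
        p = lr_test(full["llf"], red["llf"], df=1)
        rows.append((full["beta"][2] / LN2, p))
    res = pd.DataFrame(rows, index=wide_tc.index,
                       columns=["degron_l2fc", "pvalue"])
    res["padj"] = bh_adjust(res["pvalue"])
    res["stability_class"] = np.where(
        res["pvalue"] < p_cutoff,
        np.where(res["degron_l2fc"] > 0, "stabilized", "destabilized"), "NS")
    res.attrs["excluded"] = excluded
    return res


def class_retention_test(table: ConversionTable, classes: pd.Series,
                         group_a: str = "TE_down", group_b: str = "NS",
                         chase_h: float = 8.0):
    """One-sided Wilcoxon: does ``group_a`` retain more label than ``group_b``?

    The per-gene statistic is the difference in converted-read fraction
    (treated minus control) across labeled chase samples.
    """
    s = table.samples
    frac = table.tc_fraction()
    sel = s[(s.labeling == "4sU") & (s.chase_h == chase_h)]
    treated = sel[sel.degron == "treated"]["sample"]
    control = sel[sel.degron == "control"]["sample"]
    delta = frac[treated].mean(axis=1) - frac[control].mean(axis=1)
    a = delta[classes.reindex(delta.index) == group_a].dropna()
    b = delta[classes.reindex(delta.index) == group_b].dropna()
    stat = stats.mannwhitneyu(a, b, alternative="greater")
    return {"n_a": len(a), "n_b": len(b), "median_a": float(a.median()),
            "median_b": float(b.median()), "pvalue": float(stat.pvalue)}
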