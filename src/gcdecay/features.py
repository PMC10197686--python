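"""Per-gene sequence and expression features for the importance models.

Centered on coding-sequence GC content (GCcds) plus the standard
transcript anatomy: GC, log-length and positional read density per region
(5'UTR, +/-25nt windows around start and stop codons, CDS, non-coding
internal exons, introns, 3'UTR), 61 sense-codon frequencies, GC at each
codon position, baseline expression (log TPM), baseline translation
efficiency and a mature-RNA level proxy (length-normalized exon:intron
read ratio).
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
    if c not in STOP_CODONS
)

LOG_LEN_FLOOR = 0.0  # log2 length reported for absent regions (length "1")


def gc_content(sequence: str):
    """GC fraction of a nucleotide sequence; N bases are excluded.

    Returns ``nan`` for empty or all-N input (reported as missing).
    """
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    denom = gc + s.count("A") + s.count("T")
    if denom == 0:
        return float("nan")
    return gc / denom


def codon_position_gc(cds: str, gene_id: str = "<cds>"):
    """GC fraction at codon positions 1, 2 and 3 of a CDS."""
    if len(cds) % 3 != 0:
        raise ValueError(
            f"CDS length {len(cds)} of {gene_id} not divisible by 3")
    return tuple(gc_content(cds[k::3]) for k in range(3))


def codon_frequencies(cds: str, gene_id: str = "<cds>") -> pd.Series:
    """Relative frequencies of the 61 sense codons in a CDS.

    Stop codons are excluded from numerator and denominator.  A CDS with
    internal stop codons triggers a warning (annotation noise tolerated);
    an unexpected first codon likewise warns.
    """
    if len(cds) % 3 != 0:
        raise ValueError(
            f"CDS length {len(cds)} of {gene_id} not divisible by 3")
    cds = cds.upper()
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[0] != "ATG":
        warnings.warn(f"{gene_id}: CDS does not start with ATG")
    if any(c in STOP_CODONS for c in codons[:-1]):
        warnings.warn(f"{gene_id}: internal stop codon")
    sense = [c for c in codons if c in SENSE_CODONS]
    out = pd.Series(0.0, index=list(SENSE_CODONS))
    if sense:
        vc = pd.Series(sense).value_counts()
        out.loc[vc.index] = vc.values / len(sense)
    return out


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------

_REGION_SPECS = (
    # (feature suffix, region_counts key)
    ("5utr", "five_utr"),
    ("startwin", None),
    ("stopwin", None),
    ("cds", "cds"),
    ("ncexon", "ncexon"),
    ("intron", "introns"),
    ("3utr", "three_utr"),
)


def _region_seqs(rec):
    return {
        "5utr": [rec.utr5_seq],
        "startwin": [rec.start_window],
        "stopwin": [rec.stop_window],
        "cds": [rec.cds_seq],
        "ncexon": rec.noncoding_internal_exons(),
        "intron": rec.intron_seqs,
        "3utr": [rec.utr3_seq],
    }


def region_features(annotation, counts, design, region_counts=None,
                    codon_optimality=None) -> pd.DataFrame:
    """Assemble the full per-gene predictor table.

    Densities, TPM, baseline TE and the mature-level proxy use only
    control-condition samples, so the predictors cannot contain the
    response they are meant to predict.  Genes lacking a region get
    defined sentinels (GC ``nan`` -> imputed 0 density / floored
    log-length), never silently propagated NA.
    """
    ctrl = design[design["condition"] == "control"]
    rna_samples = ctrl[ctrl.assay == "RNA"]["sample"]
    ribo_samples = ctrl[ctrl.assay == "Ribo"]["sample"]
    rna_base = counts[rna_samples].mean(axis=1)
    ribo_base = counts[ribo_samples].mean(axis=1)

    if region_counts is not None:
        region_counts = region_counts.set_index("gene_id")

    rows = []
    for rec in annotation:
        gid = rec.gene_id
        row = {"gene_id": gid}
        seqs = _region_seqs(rec)
        for suffix, rc_key in _REGION_SPECS:
            parts = [s for s in seqs[suffix] if s]
            joined = "".join(parts)
            if suffix != "cds":  # CDS-region GC is the GCcds column itself
                row[f"GCpct_{suffix}"] = gc_content(joined) if joined else np.nan
            row[f"loglen_{suffix}"] = (
                math.log2(len(joined)) if joined else LOG_LEN_FLOOR)
            for assay in ("rna", "ribo"):
                if rc_key is not None and region_counts is not None:
                    c = region_counts.loc[gid, f"{assay}_{rc_key}"]
                elif region_counts is not None:
                    c = region_counts.loc[gid, f"{assay}_{suffix.replace('win', '_win')}"]
                else:
                    c = np.nan
                row[f"posdens_{assay}_{suffix}"] = (
                    c / len(joined) if joined and not pd.isna(c) else 0.0)
        row["intronlen"] = (
            math.log2(sum(len(s) for s in rec.intron_seqs))
            if rec.intron_seqs else LOG_LEN_FLOOR)

        cds = rec.cds_seq
        gc1, gc2, gc3 = codon_position_gc(cds, gid)
        row["GCcds"] = gc_content(cds)
        row["GCpos1"], row["GCpos2"], row["GCpos3"] = gc1, gc2, gc3
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            freqs = codon_frequencies(cds, gid)
        for codon, f in freqs.items():
            row[f"codonfr_{codon}"] = f

        tpm_raw = rna_base[gid] / rec.length
        row["_tpm_raw"] = tpm_raw
        row["base_TE"] = math.log2((ribo_base[gid] + 0.5) / (rna_base[gid] + 0.5))
        if region_counts is not None and rec.intron_seqs:
            exn = region_counts.loc[gid, "rna_cds"] + \
                region_counts.loc[gid, "rna_five_utr"] + \
                region_counts.loc[gid, "rna_three_utr"]
            intr = region_counts.loc[gid, "rna_introns"]
            exon_len = rec.length
            intron_len = sum(len(s) for s in rec.intron_seqs)
            row["mature_level"] = math.log2(
                ((exn + 0.5) / exon_len) / ((intr + 0.5) / intron_len))
        else:
            row["mature_level"] = 0.0
        rows.append(row)

    table = pd.DataFrame(rows).set_index("gene_id")
    # per-million scaling of the length-normalized counts -> log TPM
    scale = table["_tpm_raw"].sum()
    table["log_TPM"] = np.log2(table.pop("_tpm_raw") / scale * 1e6 + 0.5)
    # region GC of absent regions: undefined composition -> neutral 0.5
    gc_cols = [c for c in table.columns if c.startswith("GCpct_")]
    table[gc_cols] = table[gc_cols].fillna(0.5)
    if codon_optimality is not None:
        opt = codon_optimality.set_index("gene_id")["score"]
        table["codon_optimality"] = opt.reindex(table.index).fillna(opt.median())
    table = table.sort_index()
    return table


def partition_by_gc(values: pd.Series, gc: pd.Series, n_groups: int = 3,
                    scheme: str = "width"):
    """Partition genes by GCcds and test pairwise value differences.

    ``scheme='width'`` cuts the GCcds *range* into equal-width bins (the
    default); ``'quantile'`` uses tertile-style quantile bins.  Returns
    ``(assignments, summary, tests)`` where tests holds two-sided Wilcoxon
    rank-sum p-values for every group pair (skipped when a group has
    fewer than two members).
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    common = values.index.intersection(gc.index)
    values, gc = values.loc[common], gc.loc[common]
    if scheme == "width":
        bins = pd.cut(gc, bins=n_groups, labels=False, duplicates="drop")
    elif scheme == "quantile":
        bins = pd.qcut(gc, q=n_groups, labels=False, duplicates="drop")
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    assignments = pd.Series(bins, index=common, name="gc_group")

    summary = (pd.DataFrame({"value": values, "gc_group": assignments})
               .groupby("gc_group")["value"]
               .agg(["count", "median", "mean"]).reset_index())
    groups = sorted(assignments.dropna().unique())
    tests = []
    for a, b in itertools.combinations(groups, 2):
        va = values[assignments == a]
        vb = values[assignments == b]
        if len(va) < 2 or len(vb) < 2:
            tests.append((a, b, len(va), len(vb), np.nan, "skipped"))
            continue
        p = stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue
        tests.append((a, b, len(va), len(vb), p, "ok"))
    tests = pd.DataFrame(tests, columns=["group_a", "group_b", "n_a", "n_b",
                                         "pvalue", "status"])
    return assignments, summary, tests
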