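"""Synthetic multimodal-regulation data with planted GC-dependent stabilization.

The generator emulates a degron time course (two conditions, five
timepoints) profiled by paired RNA-seq/Ribo-seq, plus SLAM-seq chase
conversion tables and per-transcript 5' coverage tracks.  Planted
structure:

* ``TE_down`` genes lose ribosome occupancy early and gain mRNA later
  (translation suppression followed by stabilization); ``TE_up`` genes
  mirror this.
* The late RNA stabilization amplitude of ``TE_down`` genes grows
  linearly with coding-sequence GC content (``gc_effect_size`` log2FC
  units per unit GCcds, anchored at the bottom of the GC range so the
  amplitude stays positive and monotone).
* Decay half-lives are negatively coupled to GCcds and lengthen under
  treatment for stabilized genes.
* 5' coverage onsets erode with cumulative decay exposure; stabilized
  genes erode more slowly under treatment.  3' profiles are fixed across
  conditions.

Counts are negative binomial with a shared dispersion ``alpha``
(``var = mu + alpha * mu**2``); coverage noise is Poisson; conversion
counts are binomial.  All draws flow from ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from gcdecay.annotation import TranscriptAnnotation, TranscriptRecord

BASES = np.array(list("ACGT"))
STOPS = ("TAA", "TAG", "TGA")

CONTROL, TREATED = "control", "treated"


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic degron time course."""

    n_genes: int = 4000
    timepoints: tuple = (4.0, 8.0, 16.0, 24.0, 48.0)
    n_replicates: int = 2
    frac_te_down: float = 0.15
    frac_te_up: float = 0.10
    gc_effect_size: float = 10.0      # log2FC per unit GCcds
    dispersion: float = 0.05          # NB alpha
    lag_hours: float = 12.0           # RNA onset delay after translation onset
    decay_erosion_rate: float = 10.0  # nt of 5' recession per unit exposure
    gc_range: tuple = (0.35, 0.75)
    ribo_amp: float = 1.5             # |log2FC| of the early translation response
    rna_base_amp: float = 0.75        # RNA amplitude at the bottom of the GC range
    ramp_len: int = 50                # nt of the 5' coverage ramp
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.frac_te_down + self.frac_te_up > 1:
            raise ValueError("frac_te_down + frac_te_up must be <= 1")
        tp = np.asarray(self.timepoints, float)
        if len(tp) < 1 or np.any(tp <= 0) or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be strictly increasing and positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        lo, hi = self.gc_range
        if not (0 <= lo < hi <= 1):
            raise ValueError("gc_range must satisfy 0 <= lo < hi <= 1")

    def rng(self, stage: int) -> np.random.Generator:
        """Independent stream per pipeline stage, all derived from ``seed``."""
        return np.random.default_rng([int(self.seed), stage])


@dataclass
class GroundTruth:
    """Per-gene planted truth: the acceptance oracle for parameter recovery."""

    genes: pd.DataFrame                 # one row per gene
    timepoints: tuple
    rna_l2fc: pd.DataFrame              # gene x timepoint, treated vs control
    ribo_l2fc: pd.DataFrame
    cov_start: pd.DataFrame             # gene x (condition, timepoint) onset

    @property
    def gene_ids(self):
        return self.genes["gene_id"].tolist()

    def to_tsv(self, path) -> None:
        wide = self.genes.copy()
        for t in self.timepoints:
            wide[f"rna_l2fc_t{t:g}"] = self.rna_l2fc[t].values
            wide[f"ribo_l2fc_t{t:g}"] = self.ribo_l2fc[t].values
        for col in self.cov_start.columns:
            wide[f"cov_start_{col[0]}_t{col[1]:g}"] = self.cov_start[col].values
        wide.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequence / annotation simulation
# ---------------------------------------------------------------------------

def _random_seq(rng, n, gc):
    """iid nucleotides with P(G)+P(C)=gc."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)])


def _random_cds(rng, n_codons, gc):
    """ATG + internal sense codons at target GC + one stop codon."""
    codons = ["ATG"]
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    need = n_codons - 2
    while len(codons) < need + 1:
        block = BASES[rng.choice(4, size=3 * (need + 8), p=p)]
        for i in range(0, len(block) - 2, 3):
            c = "".join(block[i : i + 3])
            if c not in STOPS:
                codons.append(c)
                if len(codons) == need + 1:
                    break
    codons.append(STOPS[rng.integers(3)])
    return "".join(codons)


def simulate_annotation(config: SimConfig):
    """Build one single-transcript gene per row of the planted design.

    Returns ``(TranscriptAnnotation, GroundTruth)``; the truth table is
    later augmented by the count/coverage/SLAM stages but the per-gene
    class labels, GC values, baselines, half-lives and trajectories are
    all fixed here so every stage sees one consistent planted state.
    """
    rng = config.rng(1)
    n = config.n_genes
    lo, hi = config.gc_range
    gc_target = rng.uniform(lo, hi, size=n)

    # class labels
    n_down = int(round(config.frac_te_down * n))
    n_up = int(round(config.frac_te_up * n))
    labels = np.array(["TE_down"] * n_down + ["TE_up"] * n_up
                      + ["NS"] * (n - n_down - n_up))
    rng.shuffle(labels)

    records, gc_true = [], np.empty(n)
    cursor = 1
    for i in range(n):
        utr5 = _random_seq(rng, int(rng.integers(100, 300)), rng.uniform(0.3, 0.7))
        utr3 = _random_seq(rng, int(rng.integers(300, 900)), rng.uniform(0.3, 0.7))
        cds = _random_cds(rng, int(rng.integers(150, 600)), gc_target[i])
        seq = utr5 + cds + utr3
        introns = []
        for k in range(int(rng.integers(0, 3))):
            pos = int(rng.integers(1, len(seq)))
            iseq = _random_seq(rng, int(rng.integers(80, 400)), rng.uniform(0.3, 0.6))
            introns.append((pos, iseq))
        introns.sort(key=lambda x: x[0])
        strand = "+" if rng.random() < 0.5 else "-"
        rec = TranscriptRecord(
            gene_id=f"g{i:05d}", transcript_id=f"t{i:05d}",
            chrom="chrS", strand=strand, genome_start=cursor,
            seq=seq, cds_start=len(utr5) + 1, cds_end=len(utr5) + len(cds),
            introns=introns)
        cursor += rec.pre_length + 1000
        s = rec.cds_seq
        gc_true[i] = (s.count("G") + s.count("C")) / len(s)
        records.append(rec)

    annotation = TranscriptAnnotation(records)
    truth = _build_truth(config, rng, annotation, labels, gc_true)
    return annotation, truth


def _build_truth(config, rng, annotation, labels, gc):
    n = config.n_genes
    tps = np.asarray(config.timepoints, float)
    lo, _ = config.gc_range

    baseline_rna = np.exp(rng.normal(5.0, 1.0, size=n)).clip(5, None)
    baseline_ribo = baseline_rna * np.exp(rng.normal(0.0, 0.5, size=n))

    # response shapes: fast translation onset, RNA onset delayed by lag_hours
    s_ribo = 1.0 - 2.0 ** (-tps / 4.0)
    t_rna = np.clip(tps - config.lag_hours, 0, None)
    s_rna = np.where(tps > config.lag_hours, 1.0 - 2.0 ** (-t_rna / 8.0), 0.0)

    amp_rna = config.rna_base_amp + config.gc_effect_size * (gc - lo)
    sign = np.where(labels == "TE_down", 1.0,
                    np.where(labels == "TE_up", -1.0, 0.0))
    # TE_up RNA amplitude is not GC-coupled (only stabilization is planted on GC)
    amp = np.where(labels == "TE_down", amp_rna,
                   np.where(labels == "TE_up", 1.0, 0.0))
    rna = np.outer(sign * amp, s_rna)
    ribo = np.outer(-sign * config.ribo_amp, s_ribo)

    # decay half-lives (hours): negatively GC-coupled; treatment stabilizes
    # TE_down genes (x2) and destabilizes TE_up genes (x0.5)
    hl_control = np.exp(np.log(8.0) - 1.5 * (gc - 0.55)
                        + rng.normal(0, 0.15, size=n))
    stab = np.where(labels == "TE_down", 2.0,
                    np.where(labels == "TE_up", 0.5, 1.0))
    hl_treated = hl_control * stab

    # 5' coverage onset trajectories: erosion per unit exposure; treated
    # exposure scales with the decay-rate ratio (stabilized genes recede less)
    baseline_start = rng.integers(40, 80, size=n)
    idx = np.arange(len(tps), dtype=float)
    ratio = hl_control / hl_treated
    onsets = {}
    for cond, scale in ((CONTROL, np.ones(n)), (TREATED, ratio)):
        for j, t in enumerate(tps):
            onsets[(cond, t)] = baseline_start + np.rint(
                config.decay_erosion_rate * idx[j] * scale).astype(int)
    cov_start = pd.DataFrame(onsets)
    cov_start.columns = pd.MultiIndex.from_tuples(cov_start.columns)

    genes = pd.DataFrame({
        "gene_id": annotation.gene_ids,
        "class_label": labels,
        "gc_cds": gc,
        "baseline_rna": baseline_rna,
        "baseline_ribo": baseline_ribo,
        "half_life_control": hl_control,
        "half_life_treated": hl_treated,
        "cov_baseline_start": baseline_start,
    })
    rna_df = pd.DataFrame(rna, columns=list(tps))
    ribo_df = pd.DataFrame(ribo, columns=list(tps))
    return GroundTruth(genes=genes, timepoints=tuple(tps),
                       rna_l2fc=rna_df, ribo_l2fc=ribo_df, cov_start=cov_start)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb_draws(rng, mu, alpha):
    """NB draws parameterized by mean and dispersion (var = mu + alpha mu^2)."""
    mu = np.asarray(mu, float)
    if np.any(mu <= 0):
        raise ValueError("non-positive NB mean")
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_counts(config: SimConfig, annotation, truth: GroundTruth):
    """Per-gene NB counts for every assay x condition x timepoint x replicate.

    Returns ``(counts, design, region_counts)``: counts is gene x sample,
    design holds sample metadata, and region_counts apportions each
    gene's pooled control reads over transcript regions (used for the
    positional-density and mature-level features).
    """
    if annotation.gene_ids != truth.gene_ids:
        raise ValueError("annotation and truth gene ids differ")
    rng = config.rng(2)
    tps = list(truth.timepoints)
    n = config.n_genes
    alpha = config.dispersion

    l2fc = {"RNA": truth.rna_l2fc, "Ribo": truth.ribo_l2fc}
    base = {"RNA": truth.genes["baseline_rna"].values,
            "Ribo": truth.genes["baseline_ribo"].values}

    cols, meta = {}, []
    for assay in ("RNA", "Ribo"):
        for cond in (CONTROL, TREATED):
            for t in tps:
                fc = l2fc[assay][t].values if cond == TREATED else np.zeros(n)
                for rep in range(1, config.n_replicates + 1):
                    depth = rng.uniform(0.7, 1.3)
                    name = f"{assay}_{cond}_t{t:g}_r{rep}"
                    mu = base[assay] * (2.0 ** fc) * depth
                    cols[name] = _nb_draws(rng, mu, alpha)
                    meta.append((name, assay, cond, t, rep, depth))
    counts = pd.DataFrame(cols, index=truth.gene_ids)
    counts.index.name = "gene_id"
    design = pd.DataFrame(
        meta, columns=["sample", "assay", "condition", "timepoint",
                       "replicate", "depth_factor"])
    region_counts = _simulate_region_counts(rng, annotation, counts, design)
    return counts, design, region_counts


_REGIONS = ("five_utr", "cds", "three_utr", "introns", "ncexon")


def _simulate_region_counts(rng, annotation, counts, design):
    """Split pooled control reads across regions ~ length (introns damped)."""
    ctrl = design[design.condition == CONTROL]
    rows = []
    for rec in annotation:
        lens = {
            "five_utr": len(rec.utr5_seq),
            "cds": len(rec.cds_seq),
            "three_utr": len(rec.utr3_seq),
            "introns": sum(len(s) for s in rec.intron_seqs),
            "ncexon": sum(len(s) for s in rec.noncoding_internal_exons()),
        }
        w = np.array([lens["five_utr"], lens["cds"], lens["three_utr"],
                      0.1 * lens["introns"], lens["ncexon"]], float)
        row = {"gene_id": rec.gene_id}
        for assay in ("RNA", "Ribo"):
            total = int(counts.loc[
                rec.gene_id, ctrl[ctrl.assay == assay]["sample"]].sum())
            if w.sum() > 0 and total > 0:
                split = rng.multinomial(total, w / w.sum())
            else:
                split = np.zeros(5, int)
            for reg, c in zip(_REGIONS, split):
                row[f"{assay.lower()}_{reg}"] = int(c)
                row[f"len_{reg}"] = lens[reg]
            # start/stop windows drawn out of the CDS share
            p = min(1.0, 51.0 / max(lens["cds"], 1))
            row[f"{assay.lower()}_start_win"] = int(rng.binomial(split[1], p))
            row[f"{assay.lower()}_stop_win"] = int(rng.binomial(split[1], p))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def simulate_coverage(config: SimConfig, annotation, truth: GroundTruth,
                      depth_range=(20.0, 80.0), noise: bool = True):
    """Per-transcript Poisson coverage tracks, one per condition x timepoint.

    Profile: zero before the 5' onset, linear ramp over ``ramp_len`` nt up
    to a plateau, then a fixed 3' ramp-down (last 60..20 nt).  The onset
    follows the planted ``truth.cov_start`` trajectory.  Transcripts too
    short for ramp + window geometry are excluded and reported.
    """
    from gcdecay.coverage import CoverageSet

    rng = config.rng(3)
    tps = list(truth.timepoints)
    genes = truth.genes.set_index("gene_id")
    depth = rng.uniform(*depth_range, size=config.n_genes)
    depth_by_gene = dict(zip(truth.gene_ids, depth))

    min_len = int(truth.cov_start.to_numpy().max()) + config.ramp_len + 200
    excluded = [r.gene_id for r in annotation if r.length < min_len]
    keep = [r for r in annotation if r.length >= min_len]

    tracks, meta = {}, []
    for cond in (CONTROL, TREATED):
        for t in tps:
            name = f"cov_{cond}_t{t:g}"
            meta.append((name, cond, t))
            onset_col = truth.cov_start[(cond, t)]
            onset_by_gene = dict(zip(truth.gene_ids, onset_col))
            sample_tracks = {}
            for rec in keep:
                prof = _profile(rec.length, int(onset_by_gene[rec.gene_id]),
                                config.ramp_len, depth_by_gene[rec.gene_id])
                if noise:
                    prof = rng.poisson(prof).astype(float)
                sample_tracks[rec.transcript_id] = prof
            tracks[name] = sample_tracks
    samples = pd.DataFrame(meta, columns=["sample", "condition", "timepoint"])
    tx2gene = {r.transcript_id: r.gene_id for r in keep}
    return CoverageSet(tracks=tracks, samples=samples, tx2gene=tx2gene,
                       excluded=excluded)


def _profile(length, onset, ramp_len, depth):
    """Deterministic expected coverage: 5' ramp, plateau, fixed 3' ramp."""
    x = np.zeros(length)
    # ramp value at position onset+k-1 (1-based) is k/ramp_len, k=1..ramp_len
    ramp = np.arange(1, ramp_len + 1) / ramp_len
    end = min(onset - 1 + ramp_len, length)
    x[onset - 1 : end] = ramp[: end - (onset - 1)]
    x[end:] = 1.0
    # fixed 3' down-ramp: plateau ends at length-60, zero from length-20
    p3, z3 = length - 60, length - 20
    down = np.arange(z3 - p3 - 1, -1, -1) / (z3 - p3)
    x[p3:z3] = down
    x[z3:] = 0.0
    return x * depth


# ---------------------------------------------------------------------------
# SLAM-seq conversion tables
# ---------------------------------------------------------------------------

def simulate_slam(config: SimConfig, truth: GroundTruth,
                  initial_frac: float = 0.5, background: float = 0.01,
                  mean_depth_scale: float = 0.5, n_replicates: int = 2,
                  conversion_overdispersion: float = 0.01):
    """T>C conversion tables for a labeling + chase design.

    Labeled (4sU) samples at chase time ``t`` convert with fraction
    ``background + (initial - background) * 2**(-t/half_life)`` where the
    half-life is condition-specific; unlabeled (DMSO-label) samples sit at
    the background rate.  Chase-0 samples are collected before degron
    induction and carry control status.

    Conversion counts are beta-binomial: the per-sample conversion
    fraction is jittered around its expectation with intra-class
    correlation ``conversion_overdispersion``, emulating the
    labeling/chemistry efficiency variability seen between real
    libraries (a purely binomial draw conditional on the total would be
    underdispersed relative to any count model with a total-reads
    offset).  Set it to 0 for exact binomial draws.
    """
    from gcdecay.slam import ConversionTable

    rng = config.rng(4)
    genes = truth.genes
    base_mu = genes["baseline_rna"].values * mean_depth_scale
    hl = {CONTROL: genes["half_life_control"].values,
          TREATED: genes["half_life_treated"].values}

    cells = [("4sU", 0.0, CONTROL), ("4sU", 8.0, CONTROL), ("4sU", 8.0, TREATED),
             ("DMSO", 0.0, CONTROL), ("DMSO", 8.0, CONTROL), ("DMSO", 8.0, TREATED)]
    rows, meta = [], []
    for labeling, chase, degron in cells:
        for rep in range(1, n_replicates + 1):
            name = f"slam_{labeling}_chase{chase:g}_{degron}_r{rep}"
            meta.append((name, labeling, degron, chase, rep))
            total = _nb_draws(rng, base_mu, config.dispersion)
            if labeling == "4sU":
                frac = background + (initial_frac - background) * \
                    2.0 ** (-chase / hl[degron])
            else:
                frac = np.full(config.n_genes, background)
            rho = conversion_overdispersion
            if rho > 0 and labeling == "4sU":
                # labeling/alkylation efficiency jitter; the sequencing-error
                # background of unlabeled libraries is platform-stable
                nu = (1.0 - rho) / rho
                frac = rng.beta(np.clip(frac * nu, 1e-6, None),
                                np.clip((1.0 - frac) * nu, 1e-6, None))
            tc = rng.binomial(total, frac)
            for g, tot, c in zip(genes["gene_id"], total, tc):
                rows.append((g, name, int(tot), int(c)))
    counts = pd.DataFrame(rows, columns=["gene_id", "sample",
                                         "total_reads", "tc_reads"])
    samples = pd.DataFrame(meta, columns=["sample", "labeling", "degron",
                                          "chase_h", "replicate"])
    return ConversionTable(counts=counts, samples=samples)


# ---------------------------------------------------------------------------
# one-call driver + file output
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    config: SimConfig
    annotation: TranscriptAnnotation
    truth: GroundTruth
    counts: pd.DataFrame
    design: pd.DataFrame
    region_counts: pd.DataFrame
    coverage: object
    conversion: object


def simulate_all(config: SimConfig, outdir: Optional[Path] = None,
                 coverage: bool = True, slam: bool = True) -> SimResult:
    """Run every simulation stage; optionally write all standard-format files."""
    annotation, truth = simulate_annotation(config)
    counts, design, region_counts = simulate_counts(config, annotation, truth)
    cov = simulate_coverage(config, annotation, truth) if coverage else None
    conv = simulate_slam(config, truth) if slam else None
    result = SimResult(config, annotation, truth, counts, design,
                       region_counts, cov, conv)
    if outdir is not None:
        write_simulation(result, Path(outdir))
    return result


def write_simulation(result: SimResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.annotation.to_gtf(outdir / "annotation.gtf")
    result.annotation.to_fasta(outdir / "transcripts.fa",
                               introns_path=outdir / "introns.fa")
    result.counts.to_csv(outdir / "counts.tsv", sep="\t")
    result.design.to_csv(outdir / "design.tsv", sep="\t", index=False)
    result.region_counts.to_csv(outdir / "region_counts.tsv", sep="\t",
                                index=False)
    result.truth.to_tsv(outdir / "ground_truth.tsv")
    if result.coverage is not None:
        covdir = outdir / "coverage"
        covdir.mkdir(exist_ok=True)
        result.coverage.to_bedgraph_dir(covdir)
    if result.conversion is not None:
        result.conversion.counts.to_csv(outdir / "slam_counts.tsv", sep="\t",
                                        index=False)
        result.conversion.samples.to_csv(outdir / "slam_design.tsv", sep="\t",
                                         index=False)
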