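"""Transcript annotation container and GTF/FASTA round-tripping.

A :class:`TranscriptRecord` stores one transcript in *mature* (spliced,
5'->3') coordinates -- the coordinate system every downstream statistic
(coverage starts, window log2FCs, region features) operates in -- together
with enough genomic layout (chromosome, strand, genome start, intron
insertion points) to emit a conventional 1-based, closed-interval GTF.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class TranscriptRecord:
    """One gene with a single annotated transcript.

    ``seq`` is the mature transcript sequence.  ``cds_start``/``cds_end``
    are 1-based closed positions in mature coordinates.  ``introns`` is a
    list of ``(after_pos, sequence)`` pairs: the intron sits after mature
    position ``after_pos`` (1-based) in the pre-mRNA.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    genome_start: int
    seq: str
    cds_start: int
    cds_end: int
    introns: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        cds_len = self.cds_end - self.cds_start + 1
        if cds_len % 3 != 0:
            raise ValueError(
                f"CDS length {cds_len} of {self.transcript_id} not divisible by 3"
            )
        if not (1 <= self.cds_start <= self.cds_end <= len(self.seq)):
            raise ValueError(f"CDS outside transcript for {self.transcript_id}")

    # -- mature-coordinate region accessors -------------------------------
    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def utr5_seq(self) -> str:
        return self.seq[: self.cds_start - 1]

    @property
    def cds_seq(self) -> str:
        return self.seq[self.cds_start - 1 : self.cds_end]

    @property
    def utr3_seq(self) -> str:
        return self.seq[self.cds_end :]

    @property
    def intron_seqs(self) -> list:
        return [s for _, s in self.introns if s is not None]

    def window_around(self, pos: int, half: int = 25) -> str:
        """Sequence in ``[pos-half, pos+half]`` mature coords, clipped."""
        lo = max(1, pos - half)
        hi = min(self.length, pos + half)
        return self.seq[lo - 1 : hi]

    @property
    def start_window(self) -> str:
        return self.window_around(self.cds_start)

    @property
    def stop_window(self) -> str:
        return self.window_around(self.cds_end)

    # -- pre-mRNA / genomic layout ----------------------------------------
    def exon_blocks_mature(self) -> list:
        """Exon intervals in mature coordinates (1-based closed)."""
        cuts = sorted(p for p, _ in self.introns)
        blocks, lo = [], 1
        for c in cuts:
            blocks.append((lo, c))
            lo = c + 1
        blocks.append((lo, self.length))
        return blocks

    def noncoding_internal_exons(self) -> list:
        """Internal exons (not first/last) that lie entirely outside the CDS."""
        blocks = self.exon_blocks_mature()
        out = []
        for lo, hi in blocks[1:-1]:
            if hi < self.cds_start or lo > self.cds_end:
                out.append(self.seq[lo - 1 : hi])
        return out

    def _mature_to_pre(self, pos: int) -> int:
        """Map a mature coordinate to pre-mRNA coordinate."""
        shift = sum(len(s) if s is not None else l
                    for (p, s), l in zip(self.introns, self._intron_lens())
                    if p < pos)
        return pos + shift

    def _intron_lens(self) -> list:
        return [len(s) if s is not None else 0 for _, s in self.introns]

    @property
    def pre_length(self) -> int:
        return self.length + sum(self._intron_lens())

    def _pre_to_genome(self, lo: int, hi: int) -> tuple:
        """Map a pre-mRNA interval to genomic (1-based closed)."""
        if self.strand == "+":
            return self.genome_start + lo - 1, self.genome_start + hi - 1
        g_hi = self.genome_start + self.pre_length - lo
        g_lo = self.genome_start + self.pre_length - hi
        return g_lo, g_hi

    def genomic_intervals(self, lo_m: int, hi_m: int) -> list:
        """Genomic intervals for a mature-coordinate span, split at introns."""
        out = []
        for b_lo, b_hi in self.exon_blocks_mature():
            s, e = max(lo_m, b_lo), min(hi_m, b_hi)
            if s > e:
                continue
            out.append(self._pre_to_genome(self._mature_to_pre(s),
                                           self._mature_to_pre(s) + (e - s)))
        return sorted(out)


class TranscriptAnnotation:
    """Ordered collection of :class:`TranscriptRecord`, one per gene."""

    def __init__(self, records: list):
        self.records = list(records)
        self._by_gene = {r.gene_id: r for r in self.records}
        if len(self._by_gene) != len(self.records):
            raise ValueError("duplicate gene ids in annotation")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, gene_id: str) -> TranscriptRecord:
        return self._by_gene[gene_id]

    @property
    def gene_ids(self) -> list:
        return [r.gene_id for r in self.records]

    # -- writers -----------------------------------------------------------
    def to_gtf(self, path) -> None:
        rows = []
        for r in self.records:
            attrs = f'gene_id "{r.gene_id}"; transcript_id "{r.transcript_id}";'

            def add(feat, g_lo, g_hi):
                rows.append((r.chrom, "gcdecay", feat, g_lo, g_hi, ".",
                             r.strand, ".", attrs))

            g_lo, g_hi = r._pre_to_genome(1, r.pre_length)
            add("gene", g_lo, g_hi)
            add("transcript", g_lo, g_hi)
            for lo, hi in r.genomic_intervals(1, r.length):
                add("exon", lo, hi)
            for lo, hi in r.genomic_intervals(r.cds_start, r.cds_end):
                add("CDS", lo, hi)
            if r.cds_start > 1:
                for lo, hi in r.genomic_intervals(1, r.cds_start - 1):
                    add("five_prime_utr", lo, hi)
            if r.cds_end < r.length:
                for lo, hi in r.genomic_intervals(r.cds_end + 1, r.length):
                    add("three_prime_utr", lo, hi)
        df = pd.DataFrame(rows)
        df.to_csv(path, sep="\t", header=False, index=False, quoting=3)

    def to_fasta(self, path, introns_path=None) -> None:
        recs = [SeqRecord(Seq(r.seq), id=r.transcript_id, description=r.gene_id)
                for r in self.records]
        SeqIO.write(recs, str(path), "fasta")
        if introns_path is not None:
            irecs = []
            for r in self.records:
                for i, (_, s) in enumerate(r.introns):
                    if s is not None:
                        irecs.append(SeqRecord(Seq(s),
                                               id=f"{r.transcript_id}|intron{i}",
                                               description=r.gene_id))
            SeqIO.write(irecs, str(introns_path), "fasta")

    # -- readers -----------------------------------------------------------
    @classmethod
    def from_files(cls, gtf_path, fasta_path, introns_path=None):
        """Rebuild an annotation from a GTF plus transcript FASTA.

        Intron sequences are recovered from ``introns_path`` when given;
        otherwise intron placeholders carry ``None`` sequences (their
        lengths are still known from the exon chain).
        """
        gtf = pd.read_csv(
            gtf_path, sep="\t", header=None, comment="#",
            names=["chrom", "source", "feature", "start", "end",
                   "score", "strand", "frame", "attrs"],
        )

        def attr(s, key):
            m = re.search(rf'{key} "([^"]+)"', s)
            return m.group(1) if m else None

        gtf["transcript_id"] = gtf["attrs"].map(lambda s: attr(s, "transcript_id"))
        gtf["gene_id"] = gtf["attrs"].map(lambda s: attr(s, "gene_id"))

        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
        intron_seqs = {}
        if introns_path is not None:
            for rec in SeqIO.parse(str(introns_path), "fasta"):
                tid, label = rec.id.rsplit("|", 1)
                intron_seqs[(tid, int(label.replace("intron", "")))] = str(rec.seq)

        records = []
        for tid, grp in gtf.groupby("transcript_id", sort=False):
            strand = grp["strand"].iloc[0]
            gene_id = grp["gene_id"].iloc[0]
            chrom = grp["chrom"].iloc[0]
            exons = grp[grp.feature == "exon"][["start", "end"]].sort_values("start")
            exons = list(exons.itertuples(index=False, name=None))
            cds = grp[grp.feature == "CDS"][["start", "end"]].sort_values("start")
            cds = list(cds.itertuples(index=False, name=None))
            if not cds:
                continue
            genome_start = min(s for s, _ in exons)
            # order exons 5'->3' along the transcript
            chain = exons if strand == "+" else exons[::-1]
            # genomic -> mature projection
            offsets, m = [], 0
            for s, e in chain:
                offsets.append((s, e, m))
                m += e - s + 1
            mature_len = m

            def to_mature(g):
                for s, e, off in offsets:
                    if s <= g <= e:
                        return off + (g - s + 1 if strand == "+" else e - g + 1)
                raise ValueError(f"position {g} outside exons of {tid}")

            cds_pts = [to_mature(s) for s, e in cds] + [to_mature(e) for s, e in cds]
            cds_start, cds_end = min(cds_pts), max(cds_pts)
            # introns: gaps between genomically adjacent exons
            introns = []
            prev_end = None
            gaps = []
            for s, e in exons:
                if prev_end is not None and s > prev_end + 1:
                    gaps.append((prev_end + 1, s - 1))
                prev_end = e
            # intron insertion point in mature coords = cumulative exon length
            # 5'->3' before the gap
            gap_chain = gaps if strand == "+" else gaps[::-1]
            cum = 0
            for k, (s, e) in enumerate(chain):
                cum += e - s + 1
                if k < len(gap_chain):
                    g_lo, g_hi = gap_chain[k]
                    fallback = "N" * (g_hi - g_lo + 1)  # keeps layout lengths
                    introns.append((cum, intron_seqs.get((tid, k), fallback)))
            seq = seqs[tid]
            if len(seq) != mature_len:
                raise ValueError(f"FASTA/GTF length mismatch for {tid}")
            records.append(TranscriptRecord(
                gene_id=gene_id, transcript_id=tid, chrom=chrom, strand=strand,
                genome_start=genome_start, seq=seq,
                cds_start=cds_start, cds_end=cds_end, introns=introns))
        return cls(records)
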