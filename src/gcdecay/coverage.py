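"""5'-end coverage-decay statistics.

5'->3' exonucleolytic decay erodes the 5' boundary of RNA-seq coverage,
so the first transcript position whose min/max-normalized coverage
exceeds a threshold (default 0.15) serves as a per-sample "coverage
start".  Movement of that start -- and of mean normalized coverage in a
window around the pooled start -- across a time course (regression
slope) or between two conditions (difference) quantifies per-transcript
decay changes.  Normalization is per transcript, which controls for
expression-level changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CoverageSet:
    """Per-sample, per-transcript coverage vectors in transcript coords."""

    tracks: dict                     # sample -> {transcript_id: np.ndarray}
    samples: pd.DataFrame            # sample, condition, timepoint
    tx2gene: dict
    excluded: list = field(default_factory=list)

    @property
    def transcript_ids(self) -> list:
        first = next(iter(self.tracks.values()))
        return list(first)

    def get(self, sample: str, transcript_id: str) -> np.ndarray:
        return self.tracks[sample][transcript_id]

    def pooled(self, transcript_id: str) -> np.ndarray:
        return np.sum([t[transcript_id] for t in self.tracks.values()], axis=0)

    # -- bedGraph I/O (0-based half-open, transcript name as chromosome) --
    def to_bedgraph_dir(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sample, tx in self.tracks.items():
            rows = []
            for tid, vec in tx.items():
                for lo, hi, val in _run_lengths(vec):
                    rows.append((tid, lo, hi, val))
            pd.DataFrame(rows).to_csv(outdir / f"{sample}.bedgraph",
                                      sep="\t", header=False, index=False)
        self.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        pd.DataFrame(sorted(self.tx2gene.items()),
                     columns=["transcript_id", "gene_id"]).to_csv(
            outdir / "tx2gene.tsv", sep="\t", index=False)

    @classmethod
    def from_bedgraph_dir(cls, indir):
        from pathlib import Path

        indir = Path(indir)
        samples = pd.read_csv(indir / "samples.tsv", sep="\t")
        tx2gene = dict(pd.read_csv(indir / "tx2gene.tsv", sep="\t").values)
        tracks = {}
        for sample in samples["sample"]:
            df = pd.read_csv(indir / f"{sample}.bedgraph", sep="\t",
                             header=None, names=["tid", "lo", "hi", "val"])
            lens = df.groupby("tid")["hi"].max()
            tx = {tid: np.zeros(int(n)) for tid, n in lens.items()}
            for tid, lo, hi, val in df.itertuples(index=False):
                tx[tid][int(lo):int(hi)] = val
            tracks[sample] = tx
        return cls(tracks=tracks, samples=samples, tx2gene=tx2gene)


def _run_lengths(vec):
    vec = np.asarray(vec)
    change = np.nonzero(np.diff(vec))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(vec)]])
    for s, e in zip(starts, ends):
        if vec[s] != 0:
            yield int(s), int(e), float(vec[s])


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def normalize_profile(vec, max_only: bool = False):
    """Min/max normalize to [0, 1]; returns None for flat profiles."""
    vec = np.asarray(vec, float)
    lo = 0.0 if max_only else vec.min()
    hi = vec.max()
    if hi <= lo:
        return None
    return (vec - lo) / (hi - lo)


def detect_start(vec, threshold: float = 0.15, max_only: bool = False):
    """First 1-based position whose normalized coverage exceeds threshold.

    Returns ``None`` for flat (undetectable) profiles, which callers
    exclude and report.
    """
    norm = normalize_profile(vec, max_only=max_only)
    if norm is None:
        return None
    above = np.nonzero(norm > threshold)[0]
    if len(above) == 0:
        return None
    return int(above[0]) + 1


def select_major_isoform(covset: CoverageSet):
    """One transcript per gene: maximal pooled coverage, ties broken by
    longer transcript then lexicographically smaller id.  Genes with zero
    coverage everywhere are excluded and reported."""
    best, zero_genes = {}, []
    totals = {}
    for tid in covset.transcript_ids:
        pooled = covset.pooled(tid)
        totals[tid] = (float(pooled.sum()), len(pooled))
    by_gene = {}
    for tid, (tot, ln) in totals.items():
        by_gene.setdefault(covset.tx2gene[tid], []).append((tid, tot, ln))
    for gene, cands in by_gene.items():
        cands.sort(key=lambda c: (-c[1], -c[2], c[0]))
        if cands[0][1] <= 0:
            zero_genes.append(gene)
            continue
        best[gene] = cands[0][0]
    return best, sorted(zero_genes)


def window_mean(norm_vec, center: int, half_window: int):
    """Mean normalized coverage in [center-h, center+h], clipped to bounds.

    Returns ``None`` when the window misses the transcript entirely.
    """
    lo = max(1, center - half_window)
    hi = min(len(norm_vec), center + half_window)
    if lo > len(norm_vec) or hi < 1:
        return None
    return float(np.mean(norm_vec[lo - 1 : hi]))


def window_log2fc(treated_mean, control_mean, floor):
    """log2 ratio of window means with a pseudo-value guard.

    When either mean is zero, the smallest positive normalized value on
    the transcript (``floor``) is added to both, avoiding infinities
    while preserving ordering.
    """
    if treated_mean == 0 or control_mean == 0:
        treated_mean, control_mean = treated_mean + floor, control_mean + floor
    return float(np.log2(treated_mean / control_mean))


def trajectory_beta(values, times=None, mode: str = "regression",
                    intercept: bool = True):
    """Summarize a per-timepoint series into one slope or difference.

    Regression mode fits OLS against ``times`` (default: 0, 1, 2, ...
    ordinal index); ``intercept=False`` forces the line through the
    origin (used for log2FC series, whose first value is 0 by
    construction).  Difference mode requires exactly two values and
    returns ``values[1] - values[0]`` (treated minus control).
    """
    values = np.asarray(values, float)
    if mode == "difference":
        if len(values) != 2:
            raise ValueError("difference mode needs exactly two values")
        return float(values[1] - values[0])
    if mode != "regression":
        raise ValueError(f"unknown mode {mode!r}")
    if len(values) < 3:
        raise ValueError("regression mode needs >= 3 timepoints")
    x = np.arange(len(values), dtype=float) if times is None \
        else np.asarray(times, float)
    if intercept:
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.lstsq(X, values, rcond=None)[0]
        return float(beta[1])
    return float(np.sum(x * values) / np.sum(x * x))


# ---------------------------------------------------------------------------
# per-transcript statistics across a sample set
# ---------------------------------------------------------------------------

def coverage_stats(covset: CoverageSet, threshold: float = 0.15,
                   window: int = 250, mode: str = "regression",
                   end: str = "five", max_only: bool = False,
                   time_axis: str = "index") -> pd.DataFrame:
    """Per-transcript start positions, windowed log2FCs and betas.

    For each transcript: the pooled coverage start (all samples summed),
    per-sample starts, the windowed mean normalized coverage around the
    pooled start, and log2FC of treated vs control at each timepoint.
    ``mode='regression'`` (time course) regresses the start-position
    difference (with intercept) and the windowed log2FC (through the
    origin) on time; ``mode='difference'`` (single-timepoint two-condition
    designs) reports treated minus control.  ``end='three'`` runs the
    identical machinery on reversed profiles (the 3' negative control).

    Flat transcripts and windows outside the transcript are excluded and
    listed in ``.attrs['excluded']``.
    """
    half = window // 2
    meta = covset.samples
    tps = sorted(meta["timepoint"].unique())
    if mode == "regression" and len(tps) < 3:
        raise ValueError("regression mode needs >= 3 timepoints")
    if mode == "difference" and len(tps) != 1:
        raise ValueError("difference mode expects a single timepoint")
    sample_of = {(c, t): s for s, c, t in
                 meta[["sample", "condition", "timepoint"]]
                 .itertuples(index=False)}

    rows, excluded = [], []
    if time_axis == "index":
        xs = np.arange(len(tps), dtype=float)
    elif time_axis == "hours":
        xs = np.asarray(tps, float)
    else:
        raise ValueError(f"unknown time_axis {time_axis!r}")

    for tid in covset.transcript_ids:
        def vec_of(sample):
            v = covset.get(sample, tid)
            return v[::-1] if end == "three" else v

        pooled = covset.pooled(tid)
        if end == "three":
            pooled = pooled[::-1]
        pooled_start = detect_start(pooled, threshold, max_only)
        if pooled_start is None:
            excluded.append((tid, "flat pooled profile"))
            continue

        starts, l2fcs, ok = {}, {}, True
        for t in tps:
            per_cond = {}
            for cond in ("control", "treated"):
                v = vec_of(sample_of[(cond, t)])
                norm = normalize_profile(v, max_only)
                if norm is None:
                    ok = False
                    break
                per_cond[cond] = {
                    "start": detect_start(v, threshold, max_only),
                    "wmean": window_mean(norm, pooled_start, half),
                    "floor": float(norm[norm > 0].min()),
                }
            if not ok or any(c["start"] is None or c["wmean"] is None
                             for c in per_cond.values()):
                ok = False
                break
            starts[t] = (per_cond["control"]["start"],
                         per_cond["treated"]["start"])
            floor = min(per_cond["control"]["floor"],
                        per_cond["treated"]["floor"])
            l2fcs[t] = window_log2fc(per_cond["treated"]["wmean"],
                                     per_cond["control"]["wmean"], floor)
        if not ok:
            excluded.append((tid, "flat or out-of-bounds sample profile"))
            continue

        d_start = np.array([starts[t][1] - starts[t][0] for t in tps], float)
        l2fc_series = np.array([l2fcs[t] for t in tps])
        if mode == "regression":
            beta_start = trajectory_beta(d_start, xs, "regression",
                                         intercept=True)
            beta_cov = trajectory_beta(l2fc_series, xs, "regression",
                                       intercept=False)
        else:
            beta_start = float(d_start[0])
            beta_cov = float(l2fc_series[0])
        row = {"transcript_id": tid, "gene_id": covset.tx2gene[tid],
               "pooled_start": pooled_start,
               "beta_start": beta_start, "beta_cov": beta_cov}
        for t in tps:
            row[f"start_control_t{t:g}"] = starts[t][0]
            row[f"start_treated_t{t:g}"] = starts[t][1]
            row[f"l2fc_t{t:g}"] = l2fcs[t]
        rows.append(row)

    out = pd.DataFrame(rows)
    out.attrs["excluded"] = excluded
    out.attrs["params"] = {"threshold": threshold, "window": window,
                           "mode": mode, "end": end, "max_only": max_only}
    return out


# ---------------------------------------------------------------------------
# class selection and comparison
# ---------------------------------------------------------------------------

def select_gene_classes(diff: pd.DataFrame, tpm: pd.Series, n_top: int = 250,
                        n_control: int = 1500, control_p: float = 0.2,
                        control_tpm: float = 3.0, rng=None) -> pd.Series:
    """Stabilized / degraded / control labels from RNA-seq differential results.

    Top ``n_top`` stabilized (RNA up) and degraded (RNA down) genes by
    RNA-seq p-value (ties broken by |log2FC| descending, stable);
    ``n_control`` controls sampled from non-regulated genes with p >
    ``control_p`` and TPM > ``control_tpm``.  Counts scale down when
    fewer genes qualify.
    """
    rng = np.random.default_rng(rng)
    d = diff.copy()
    d["tpm"] = tpm.reindex(d.index)
    ranked = d.sort_values(["rna_pvalue", "rna_l2fc"],
                           key=lambda s: s if s.name == "rna_pvalue"
                           else -s.abs(), kind="stable")
    stab = ranked[ranked["rna_l2fc"] > 0].index[:n_top]
    degr = ranked[ranked["rna_l2fc"] < 0].index[:n_top]
    pool = d[(d["rna_pvalue"] > control_p) & (d["tpm"] > control_tpm)]
    pool = pool.index.difference(stab.union(degr))
    n_ctrl = min(n_control, len(pool))
    ctrl = pd.Index(rng.choice(pool, size=n_ctrl, replace=False)) \
        if n_ctrl else pd.Index([])
    labels = pd.Series("unassigned", index=d.index, name="cov_class")
    labels.loc[stab] = "stabilized"
    labels.loc[degr] = "degraded"
    labels.loc[ctrl] = "control"
    return labels


def compare_classes(stats_df: pd.DataFrame, classes: pd.Series) -> pd.DataFrame:
    """One-sided Wilcoxon rank-sum tests of coverage betas between classes.

    Stabilized transcripts should show higher windowed-coverage betas and
    more negative start-position betas than controls; degraded
    transcripts the opposite.  Empty classes skip their tests.
    """
    df = stats_df.set_index("gene_id")
    cls = classes.reindex(df.index)
    groups = {k: df[cls == k] for k in ("stabilized", "degraded", "control")}
    specs = [
        ("beta_cov", "stabilized", "greater"),
        ("beta_cov", "degraded", "less"),
        ("beta_start", "stabilized", "less"),
        ("beta_start", "degraded", "greater"),
    ]
    rows = []
    for col, grp, alt in specs:
        a, b = groups[grp][col].dropna(), groups["control"][col].dropna()
        if len(a) < 2 or len(b) < 2:
            rows.append((col, grp, alt, len(a), len(b),
                         np.nan, np.nan, np.nan, "skipped"))
            continue
        p = stats.mannwhitneyu(a, b, alternative=alt).pvalue
        rows.append((col, grp, alt, len(a), len(b),
                     float(a.median()), float(b.median()), float(p), "ok"))
    return pd.DataFrame(rows, columns=[
        "statistic", "group", "alternative", "n_group", "n_control",
        "median_group", "median_control", "pvalue", "status"])
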