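"""End-to-end orchestration: simulate -> features -> diff -> slam -> model
-> coverage -> report, with one config, structured logs and a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gcdecay import __version__
from gcdecay.simulate import SimConfig, simulate_all

log = logging.getLogger("gcdecay")

#: analysis thresholds with their provenance ("convention" marks choices
#: this package makes where the method description leaves them open)
DEFAULT_THRESHOLDS = {
    "fdr": (0.05, "FDR cutoff of 0.05 (TE likelihood-ratio test)"),
    "slam_p": (0.05, "stability p-value cutoff of 0.05"),
    "coverage_threshold": (0.15, "first position at normalized value > 0.15"),
    "coverage_window": (250, "250nt window around the pooled coverage start"),
    "n_bins": (70, "70 bins per axis of the fold-change plane"),
    "n_folds": (5, "5-fold cross-validation"),
    "top_n": (250, "top 250 stabilized / degraded genes"),
    "control_n": (1500, "1500 control RNAs"),
    "control_p": (0.2, "control genes at p > 0.2"),
    "control_tpm": (3.0, "control genes at TPM > 3"),
    "rf_trees": (200, "convention: forest size traded against runtime"),
}


@dataclass
class RunConfig:
    """One-file configuration for a full synthetic run."""

    outdir: str = "gcdecay_run"
    seed: int = 0
    sim: dict = field(default_factory=dict)        # SimConfig overrides
    stages: dict = field(default_factory=lambda: {
        "features": True, "diff": True, "slam": True,
        "model": True, "cov5": True})
    thresholds: dict = field(
        default_factory=lambda: {k: v for k, (v, _) in
                                 DEFAULT_THRESHOLDS.items()})

    def __post_init__(self) -> None:
        for k in self.thresholds:
            if k not in DEFAULT_THRESHOLDS:
                raise ValueError(f"unknown threshold {k!r}")

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute all enabled stages in dependency order; returns the outdir.

    Every stage writes TSV outputs into its own subdirectory; the
    manifest records the package version, seed, config hash, per-stage
    row counts and content hashes of every output file.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = {k: config.thresholds.get(k, v) for k, (v, _) in
          DEFAULT_THRESHOLDS.items()}
    manifest = {"version": __version__, "seed": config.seed,
                "config_sha256": hashlib.sha256(
                    json.dumps(asdict(config), sort_keys=True).encode()
                ).hexdigest(),
                "stages": {}}

    stage = "simulate"
    try:
        sim_kwargs = dict(config.sim)
        sim_kwargs["seed"] = config.seed
        cfg = SimConfig(**sim_kwargs)
        simdir = outdir / "simulate"
        result = simulate_all(cfg, outdir=simdir,
                              coverage=config.stages.get("cov5", True),
                              slam=config.stages.get("slam", True))
        truth = result.truth.genes.set_index("gene_id")
        manifest["stages"]["simulate"] = {
            "n_genes": cfg.n_genes,
            "excluded_coverage": len(result.coverage.excluded)
            if result.coverage else None}
        log.info("simulate: %d genes", cfg.n_genes)

        features = diff = None
        if config.stages.get("features", True):
            stage = "features"
            from gcdecay.features import region_features
            features = region_features(result.annotation, result.counts,
                                       result.design, result.region_counts)
            fdir = outdir / "features"
            fdir.mkdir(exist_ok=True)
            features.to_csv(fdir / "feature_table.tsv", sep="\t")
            manifest["stages"]["features"] = {"n_genes": len(features),
                                              "n_features": features.shape[1]}

        if config.stages.get("diff", True):
            stage = "diff"
            from gcdecay.differential import te_test, vector_field
            ddir = outdir / "diff"
            ddir.mkdir(exist_ok=True)
            results_by_time = {}
            for t in result.truth.timepoints:
                r = te_test(result.counts, result.design, timepoint=t,
                            fdr=th["fdr"])
                results_by_time[t] = r
                r.to_csv(ddir / f"te_t{t:g}.tsv", sep="\t")
            diff = results_by_time[result.truth.timepoints[-1]]
            vf = vector_field(results_by_time, truth["gc_cds"],
                              n_bins=th["n_bins"], fdr=th["fdr"])
            vf.to_csv(ddir / "vector_field.tsv", sep="\t", index=False)
            manifest["stages"]["diff"] = {
                "n_genes": len(diff),
                "n_te_sig": int((diff["padj"] < th["fdr"]).sum()),
                "excluded": len(diff.attrs["excluded"])}
            log.info("diff: %d TE-significant genes",
                     manifest["stages"]["diff"]["n_te_sig"])

        if config.stages.get("slam", True):
            stage = "slam"
            from gcdecay.slam import class_retention_test, stability_test
            sdir = outdir / "slam"
            sdir.mkdir(exist_ok=True)
            st = stability_test(result.conversion, p_cutoff=th["slam_p"])
            st.to_csv(sdir / "stability.tsv", sep="\t")
            classes = (diff["te_class"] if diff is not None
                       else truth["class_label"])
            ret = class_retention_test(result.conversion, classes)
            pd.DataFrame([ret]).to_csv(sdir / "retention_test.tsv",
                                       sep="\t", index=False)
            manifest["stages"]["slam"] = {
                "n_genes": len(st),
                "n_stabilized": int((st.stability_class == "stabilized").sum()),
                "excluded": len(st.attrs["excluded"])}

        if config.stages.get("model", True) and features is not None:
            stage = "model"
            from gcdecay.model import fit_lasso_cv, fit_rf_cv
            mdir = outdir / "model"
            mdir.mkdir(exist_ok=True)
            if diff is not None:
                target = diff["dte_l2fc"]
                genes = diff.index[diff["te_class"] == "TE_down"]
            else:
                target = truth["half_life_treated"]
                genes = truth.index
            genes = features.index.intersection(genes)
            reports = {}
            if len(genes) >= 50:
                reports["rf"] = fit_rf_cv(
                    features.loc[genes], target.loc[genes],
                    n_folds=th["n_folds"], seed=config.seed,
                    n_estimators=th["rf_trees"])
                reports["lasso"] = fit_lasso_cv(
                    features.loc[genes], target.loc[genes],
                    n_folds=th["n_folds"], seed=config.seed)
                imp = pd.DataFrame({k: r.importance
                                    for k, r in reports.items()})
                imp.to_csv(mdir / "importance.tsv", sep="\t")
                perf = pd.DataFrame({k: r.performance
                                     for k, r in reports.items()})
                perf.to_csv(mdir / "performance.tsv", sep="\t")
                manifest["stages"]["model"] = {
                    "n_genes": int(len(genes)),
                    "rf_top_feature": reports["rf"].importance.idxmax(),
                    "rf_spearman": reports["rf"].performance["spearman"]}
            else:
                manifest["stages"]["model"] = {
                    "n_genes": int(len(genes)),
                    "skipped": "fewer than 50 TE_down genes"}

        if config.stages.get("cov5", True) and result.coverage is not None:
            stage = "cov5"
            from gcdecay.coverage import (compare_classes, coverage_stats,
                                          select_gene_classes)
            cdir = outdir / "cov5"
            cdir.mkdir(exist_ok=True)
            stats5 = coverage_stats(result.coverage,
                                    threshold=th["coverage_threshold"],
                                    window=th["coverage_window"])
            stats5.to_csv(cdir / "coverage_stats_5p.tsv", sep="\t",
                          index=False)
            if diff is not None:
                tpm = _tpm(result)
                classes = select_gene_classes(
                    diff, tpm, n_top=th["top_n"], n_control=th["control_n"],
                    control_p=th["control_p"], control_tpm=th["control_tpm"],
                    rng=config.seed)
                tests5 = compare_classes(stats5, classes)
                tests5.to_csv(cdir / "class_tests_5p.tsv", sep="\t",
                              index=False)
                stats3 = coverage_stats(result.coverage,
                                        threshold=th["coverage_threshold"],
                                        window=th["coverage_window"],
                                        end="three")
                compare_classes(stats3, classes).to_csv(
                    cdir / "class_tests_3p.tsv", sep="\t", index=False)
            manifest["stages"]["cov5"] = {
                "n_transcripts": len(stats5),
                "excluded": len(stats5.attrs["excluded"])}
    except Exception as err:
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    manifest["files"] = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*")) if p.is_file()}
    manifest["thresholds"] = {
        k: {"value": th[k], "source": DEFAULT_THRESHOLDS[k][1]}
        for k in DEFAULT_THRESHOLDS}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    report(outdir)
    return outdir


def _tpm(result) -> pd.Series:
    design = result.design
    ctrl = design[(design.condition == "control") & (design.assay == "RNA")]
    base = result.counts[ctrl["sample"]].mean(axis=1)
    lens = pd.Series({r.gene_id: r.length for r in result.annotation})
    rate = base / lens.reindex(base.index)
    return rate / rate.sum() * 1e6


def report(outdir) -> Path:
    """Assemble a markdown summary from whatever stage outputs exist."""
    outdir = Path(outdir)
    lines = ["# gcdecay run report", ""]
    sections = [
        ("Vector field", outdir / "diff" / "vector_field.tsv",
         _summarize_vector_field),
        ("Feature importance", outdir / "model" / "importance.tsv",
         _summarize_importance),
        ("Coverage class tests", outdir / "cov5" / "class_tests_5p.tsv",
         _summarize_tsv),
        ("SLAM retention", outdir / "slam" / "retention_test.tsv",
         _summarize_tsv),
    ]
    for title, path, fn in sections:
        lines.append(f"## {title}")
        if path.exists():
            lines.extend(fn(path))
        else:
            lines.append(f"_section omitted: {path.name} not produced_")
        lines.append("")
    out = outdir / "report.md"
    out.write_text("\n".join(lines))
    return out


def _summarize_tsv(path):
    df = pd.read_csv(path, sep="\t")
    return [df.to_markdown(index=False)]


def _summarize_importance(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    top = df.sort_values(df.columns[0], ascending=False).head(10)
    return [top.to_markdown()]


def _summarize_vector_field(path):
    df = pd.read_csv(path, sep="\t")
    out = []
    for tr, grp in df.groupby("transition"):
        w = grp["n"].values
        out.append(f"- {tr}: {int(w.sum())} gene-moves, "
                   f"mean dRNA {np.average(grp['d_rna'], weights=w):+.3f}, "
                   f"mean dRibo {np.average(grp['d_ribo'], weights=w):+.3f}")
    return out
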