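"""Differential analysis of paired RNA-seq/Ribo-seq counts.

The translation-efficiency (TE) test fits, per gene, an NB GLM with
``~ condition + assay + condition:assay`` (log link, median-of-ratios
size factors as offsets) and compares it by likelihood-ratio test against
the reduced model without the interaction -- i.e. against the assumption
that RNA-seq and Ribo-seq respond identically to the condition.  Genes
with BH-adjusted LRT p below the FDR cutoff are called TE_up/TE_down by
the sign of the interaction term.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from gcdecay.nbglm import (bh_adjust, fit_nb_glm_single, lr_test,
                           moderated_dispersions, size_factors)

LN2 = np.log(2.0)


def _design_matrices(design):
    cond = (design["condition"].values == "treated").astype(float)
    assay = (design["assay"].values == "Ribo").astype(float)
    ones = np.ones_like(cond)
    X_full = np.column_stack([ones, cond, assay, cond * assay])
    X_reduced = np.column_stack([ones, cond, assay])
    return X_full, X_reduced


def fit_nb_glm(counts: pd.DataFrame, design: pd.DataFrame, terms=("condition",),
               refine_dispersion: bool = True):
    """Fit per-gene NB GLMs for the given design terms.

    ``terms`` may contain ``condition``, ``assay`` and
    ``condition:assay``.  Returns a DataFrame of natural-log
    coefficients, log-likelihood, moderated dispersion and fit flags;
    all-zero genes are excluded (listed in ``.attrs['excluded']``).
    """
    design = design.set_index("sample").loc[counts.columns].reset_index()
    cond = (design["condition"].values == "treated").astype(float)
    assay = (design["assay"].values == "Ribo").astype(float)
    cols = {"intercept": np.ones_like(cond)}
    for t in terms:
        if t == "condition":
            cols["condition"] = cond
        elif t == "assay":
            cols["assay"] = assay
        elif t == "condition:assay":
            cols["condition:assay"] = cond * assay
        else:
            raise ValueError(f"unknown term {t!r}")
    X = np.column_stack(list(cols.values()))
    sf = size_factors(counts.values)
    offset = np.log(sf)

    mat = counts.values
    keep = mat.sum(axis=1) > 0
    excluded = list(counts.index[~keep])
    genes = counts.index[keep]
    mat = mat[keep]

    alphas, _ = moderated_dispersions(mat, X, offset,
                                      refine=refine_dispersion)

    rows = []
    for y, a in zip(mat, alphas):
        fit = fit_nb_glm_single(y, X, offset, alpha=a)
        rows.append(list(fit["beta"]) + [fit["llf"], a, fit["fallback"]])
    out = pd.DataFrame(rows, index=genes,
                       columns=list(cols) + ["llf", "alpha", "fallback"])
    out.attrs["excluded"] = excluded
    out.attrs["size_factors"] = sf
    return out


def te_test(counts: pd.DataFrame, design: pd.DataFrame, timepoint=None,
            fdr: float = 0.05, refine_dispersion: bool = True) -> pd.DataFrame:
    """Interaction-covariate TE test at one contrast (treated vs control).

    Returns one row per gene: per-assay log2FC and significance, the
    delta-TE log2FC (interaction term), LRT p-value and BH-adjusted p,
    regulation class and coordinate group.
    """
    d = design.copy()
    if timepoint is not None:
        d = d[d["timepoint"] == timepoint]
    for assay in ("RNA", "Ribo"):
        sub = d[d.assay == assay]
        if sub.empty or set(sub.condition) != {"control", "treated"}:
            raise ValueError(f"missing assay/condition cells for {assay!r}")
    d = d.sort_values(["assay", "condition", "replicate"]).reset_index(drop=True)
    sub_counts = counts[d["sample"]]
    X_full, X_reduced = _design_matrices(d)
    sf = size_factors(sub_counts.values)
    offset = np.log(sf)

    mat = sub_counts.values
    keep = mat.sum(axis=1) > 0
    excluded = list(counts.index[~keep])
    genes = counts.index[keep]
    mat = mat[keep]

    alphas, _ = moderated_dispersions(mat, X_full, offset,
                                      refine=refine_dispersion)

    assay_is_ribo = (d["assay"].values == "Ribo")
    X_assay = X_full[:, :2]  # intercept + condition, per assay subset

    rows = []
    for y, a in zip(mat, alphas):
        full = fit_nb_glm_single(y, X_full, offset, alpha=a)
        red = fit_nb_glm_single(y, X_reduced, offset, alpha=a)
        p = lr_test(full["llf"], red["llf"], df=1)
        beta = full["beta"]
        rna_l2fc = beta[1] / LN2
        ribo_l2fc = (beta[1] + beta[3]) / LN2
        dte_l2fc = beta[3] / LN2
        per_assay = {}
        for name, mask in (("rna", ~assay_is_ribo), ("ribo", assay_is_ribo)):
            ya, Xa, off = y[mask], X_assay[mask], offset[mask]
            fa = fit_nb_glm_single(ya, Xa, off, alpha=a)
            f0 = fit_nb_glm_single(ya, Xa[:, :1], off, alpha=a)
            per_assay[name] = lr_test(fa["llf"], f0["llf"], df=1)
        rows.append((rna_l2fc, ribo_l2fc, dte_l2fc, p,
                     per_assay["rna"], per_assay["ribo"], full["fallback"]))

    res = pd.DataFrame(rows, index=genes, columns=[
        "rna_l2fc", "ribo_l2fc", "dte_l2fc", "pvalue",
        "rna_pvalue", "ribo_pvalue", "fallback"])
    res["padj"] = bh_adjust(res["pvalue"])
    res["rna_padj"] = bh_adjust(res["rna_pvalue"])
    res["ribo_padj"] = bh_adjust(res["ribo_pvalue"])
    res["te_class"] = _te_classes(res, fdr)
    res["coord_group"] = classify_coordinate_groups(res, fdr)
    res.attrs["excluded"] = excluded
    res.attrs["fdr"] = fdr
    return res


def _te_classes(res: pd.DataFrame, fdr: float) -> pd.Series:
    """TE_up/TE_down by interaction sign when the LRT is significant;
    otherwise RNA_only / concordant / NS from the per-assay calls."""
    te_sig = res["padj"] < fdr
    rna_sig = res["rna_padj"] < fdr
    ribo_sig = res["ribo_padj"] < fdr
    same_sign = np.sign(res["rna_l2fc"]) == np.sign(res["ribo_l2fc"])
    out = np.where(
        te_sig, np.where(res["dte_l2fc"] < 0, "TE_down", "TE_up"),
        np.where(rna_sig & ribo_sig & same_sign, "concordant",
                 np.where(rna_sig & ~ribo_sig, "RNA_only", "NS")))
    return pd.Series(out, index=res.index)


def classify_coordinate_groups(res: pd.DataFrame, fdr: float = 0.05) -> pd.Series:
    """Coordinate-plane groups on the (RNA log2FC, Ribo log2FC) plane.

    ``x``: only the RNA axis changes significantly; ``y``: only Ribo;
    ``xy``: both, same sign; ``-xy``: both, opposite sign (stability and
    translation anti-correlated); ``NS`` otherwise.  Pure function of the
    two log2FCs and the per-axis significance calls.
    """
    rna_sig = (res["rna_padj"] < fdr).values
    ribo_sig = (res["ribo_padj"] < fdr).values
    same = (np.sign(res["rna_l2fc"]) == np.sign(res["ribo_l2fc"])).values
    out = np.where(rna_sig & ribo_sig, np.where(same, "xy", "-xy"),
                   np.where(rna_sig, "x", np.where(ribo_sig, "y", "NS")))
    return pd.Series(out, index=res.index)


def vector_field(results_by_time: dict, gc: pd.Series, n_bins: int = 70,
                 fdr: float = 0.05) -> pd.DataFrame:
    """Binned vector field of fold-change movement between timepoints.

    Genes are restricted to those with a significant TE change at the
    last timepoint.  For each consecutive timepoint pair, genes are
    binned by their (RNA log2FC, Ribo log2FC) position at the earlier
    timepoint on a symmetric ``n_bins x n_bins`` grid spanning the data
    range, and the mean movement along each axis, the gene count and the
    mean GCcds are recorded per cell.
    """
    times = sorted(results_by_time)
    if len(times) < 2:
        raise ValueError("vector field needs at least two timepoints")
    last = results_by_time[times[-1]]
    sig_genes = last.index[last["padj"] < fdr]
    if len(sig_genes) == 0:
        raise ValueError("no significant genes at the final timepoint")

    coords = {t: results_by_time[t].loc[
        results_by_time[t].index.intersection(sig_genes),
        ["rna_l2fc", "ribo_l2fc"]] for t in times}
    lim = max(float(np.abs(c.values).max()) for c in coords.values())
    lim = lim if lim > 0 else 1.0
    edges = np.linspace(-lim, lim, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    rows = []
    for t0, t1 in zip(times[:-1], times[1:]):
        a, b = coords[t0], coords[t1]
        common = a.index.intersection(b.index)
        a, b = a.loc[common], b.loc[common]
        bx = np.clip(np.digitize(a["rna_l2fc"], edges) - 1, 0, n_bins - 1)
        by = np.clip(np.digitize(a["ribo_l2fc"], edges) - 1, 0, n_bins - 1)
        d = b.values - a.values
        df = pd.DataFrame({
            "bin_x": bx, "bin_y": by,
            "d_rna": d[:, 0], "d_ribo": d[:, 1],
            "gc": gc.reindex(common).values})
        agg = df.groupby(["bin_x", "bin_y"]).agg(
            d_rna=("d_rna", "mean"), d_ribo=("d_ribo", "mean"),
            n=("d_rna", "size"), mean_gc=("gc", "mean")).reset_index()
        agg.insert(0, "transition", f"t{t0:g}_to_t{t1:g}")
        agg["x_center"] = centers[agg["bin_x"]]
        agg["y_center"] = centers[agg["bin_y"]]
        rows.append(agg)
    out = pd.concat(rows, ignore_index=True)
    out.attrs["n_genes"] = len(sig_genes)
    out.attrs["limit"] = lim
    return out
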