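"""Random Forest and Lasso feature-importance modelling with cross-validation.

Both models predict a per-gene response (delta-TE log2FC for degron-style
analyses, RNA log2FC for knockdown panels) from the feature table.
Importance is "mean decrease in accuracy": permutation importance
evaluated on the held-out fold of a 5-fold cross-validation, averaged
over folds, for the Random Forest; standardized coefficients (inner-CV
regularization choice) for the Lasso.  Performance is the correlation
between predicted and observed values on held-out folds only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler


@dataclass
class ImportanceReport:
    """Per-feature importances and held-out CV performance for one model."""

    model: str
    importance: pd.Series          # mean over folds, one value per feature
    importance_sd: pd.Series
    performance: dict              # pearson / spearman mean over folds
    fold_performance: pd.DataFrame
    fold_assignments: pd.Series    # gene -> fold id (disjoint, exhaustive)
    n_genes: int
    dropped_features: list = field(default_factory=list)

    def top_features(self, n: int = 10) -> pd.Series:
        return self.importance.sort_values(ascending=False).head(n)

    def rank_of(self, feature: str) -> int:
        order = self.importance.sort_values(ascending=False)
        return int(order.index.get_loc(feature)) + 1


def _prepare(features: pd.DataFrame, target: pd.Series, min_genes: int):
    common = features.index.intersection(target.dropna().index)
    X = features.loc[common]
    y = target.loc[common]
    if len(common) < min_genes:
        raise ValueError(f"need >= {min_genes} genes, got {len(common)}")
    if y.nunique() <= 1:
        raise ValueError("constant target")
    var = X.var(axis=0)
    dropped = list(var.index[var == 0])
    if dropped:
        warnings.warn(f"dropping zero-variance features: {dropped}")
        X = X.drop(columns=dropped)
    return X, y, dropped


def _fold_corr(y_true, y_pred):
    pe = stats.pearsonr(y_true, y_pred).statistic
    sp = stats.spearmanr(y_true, y_pred).statistic
    return float(pe), float(sp)


def _heldout_permutation_importance(model, X, y, base_pred, n_repeats, rng):
    """Mean decrease in held-out R^2 when one column is permuted.

    All permuted copies are stacked into a single prediction call, which
    is far cheaper for tree ensembles than one predict per column.
    """
    n, p = X.shape
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return np.zeros(p)
    base_r2 = 1.0 - np.sum((y - base_pred) ** 2) / ss_tot
    out = np.empty(p)
    chunk = max(1, int(2e6 // (n * n_repeats)))  # bound stacked-array size
    for j0 in range(0, p, chunk):
        cols = range(j0, min(j0 + chunk, p))
        stacked = np.repeat(X[None, :, :], len(cols) * n_repeats, axis=0)
        for i, j in enumerate(cols):
            for r in range(n_repeats):
                stacked[i * n_repeats + r, :, j] = rng.permutation(X[:, j])
        preds = model.predict(stacked.reshape(-1, p))
        preds = preds.reshape(len(cols) * n_repeats, n)
        r2 = 1.0 - np.sum((y[None, :] - preds) ** 2, axis=1) / ss_tot
        out[j0 : j0 + len(cols)] = base_r2 - \
            r2.reshape(len(cols), n_repeats).mean(axis=1)
    return out


def fit_rf_cv(features: pd.DataFrame, target: pd.Series, n_folds: int = 5,
              seed: int = 0, n_estimators: int = 500,
              n_permutation_repeats: int = 5,
              min_genes: int = 50) -> ImportanceReport:
    """Random Forest regression under K-fold CV with held-out permutation
    importance.

    Defaults follow the conventional regression settings: 500 trees and
    one third of the features considered per split.  Importance for each
    fold is the drop in held-out R^2 when one column is permuted,
    averaged over ``n_permutation_repeats`` shuffles.
    """
    X, y, dropped = _prepare(features, target, min_genes)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    imps, perf, fold_ids = [], [], pd.Series(-1, index=X.index, dtype=int)
    for k, (tr, te) in enumerate(kf.split(X)):
        rf = RandomForestRegressor(
            n_estimators=n_estimators, max_features=1.0 / 3.0,
            random_state=seed + k, n_jobs=1)
        rf.fit(X.iloc[tr].values, y.iloc[tr].values)
        pred = rf.predict(X.iloc[te].values)
        pe, sp = _fold_corr(y.iloc[te], pred)
        perf.append((k, pe, sp))
        imps.append(_heldout_permutation_importance(
            rf, X.iloc[te].values, y.iloc[te].values, pred,
            n_permutation_repeats, np.random.default_rng(seed + k)))
        fold_ids.iloc[te] = k
    imps = np.array(imps)
    fold_perf = pd.DataFrame(perf, columns=["fold", "pearson", "spearman"])
    return ImportanceReport(
        model="random_forest",
        importance=pd.Series(imps.mean(axis=0), index=X.columns),
        importance_sd=pd.Series(imps.std(axis=0), index=X.columns),
        performance={"pearson": float(fold_perf.pearson.mean()),
                     "spearman": float(fold_perf.spearman.mean())},
        fold_performance=fold_perf, fold_assignments=fold_ids,
        n_genes=len(X), dropped_features=dropped)


def fit_lasso_cv(features: pd.DataFrame, target: pd.Series, n_folds: int = 5,
                 seed: int = 0, min_genes: int = 50) -> ImportanceReport:
    """Lasso on standardized predictors; penalty chosen by inner CV.

    The regularization strength follows the one-standard-error rule
    (sparsest model within one s.e. of the inner-CV optimum), the usual
    convention when the Lasso is used for feature selection.  Scaling
    parameters come from the training folds only (no leakage into the
    held-out fold).  Reported coefficients are on the scaled predictors,
    averaged over outer folds.
    """
    X, y, dropped = _prepare(features, target, min_genes)
    if np.linalg.matrix_rank(X.values) == 0:
        raise ValueError("degenerate (rank-0) predictor matrix")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    coefs, perf, fold_ids = [], [], pd.Series(-1, index=X.index, dtype=int)
    for k, (tr, te) in enumerate(kf.split(X)):
        scaler = StandardScaler().fit(X.iloc[tr])
        Xtr = scaler.transform(X.iloc[tr])
        Xte = scaler.transform(X.iloc[te])
        lasso = LassoCV(cv=5, random_state=seed + k, max_iter=20000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lasso.fit(Xtr, y.iloc[tr])
            # one-standard-error rule: the sparsest model whose inner-CV
            # error is within one s.e. of the minimum (glmnet convention)
            mse = lasso.mse_path_.mean(axis=1)
            se = lasso.mse_path_.std(axis=1) / np.sqrt(lasso.mse_path_.shape[1])
            best = int(np.argmin(mse))
            ok = np.nonzero(mse <= mse[best] + se[best])[0]
            alpha_1se = float(lasso.alphas_[ok.min()])  # alphas_ descend
            lasso = Lasso(alpha=alpha_1se, max_iter=20000).fit(Xtr, y.iloc[tr])
        pred = lasso.predict(Xte)
        if np.std(pred) == 0:  # fully regularized model predicts a constant
            perf.append((k, 0.0, 0.0))
        else:
            pe, sp = _fold_corr(y.iloc[te], pred)
            perf.append((k, pe, sp))
        coefs.append(lasso.coef_)
        fold_ids.iloc[te] = k
    coefs = np.array(coefs)
    fold_perf = pd.DataFrame(perf, columns=["fold", "pearson", "spearman"])
    return ImportanceReport(
        model="lasso",
        importance=pd.Series(np.abs(coefs).mean(axis=0), index=X.columns),
        importance_sd=pd.Series(np.abs(coefs).std(axis=0), index=X.columns),
        performance={"pearson": float(fold_perf.pearson.mean()),
                     "spearman": float(fold_perf.spearman.mean())},
        fold_performance=fold_perf, fold_assignments=fold_ids,
        n_genes=len(X), dropped_features=dropped)


def fit_per_class(features: pd.DataFrame, target: pd.Series,
                  classes: pd.Series, fitter=fit_rf_cv, min_genes: int = 50,
                  **kwargs) -> dict:
    """Independent model fits per regulation class (plus 'all')."""
    out = {"all": fitter(features, target, min_genes=min_genes, **kwargs)}
    for cls in sorted(classes.dropna().unique()):
        genes = classes.index[classes == cls]
        genes = features.index.intersection(genes)
        if len(genes) < min_genes:
            continue
        out[cls] = fitter(features.loc[genes], target.loc[genes],
                          min_genes=min_genes, **kwargs)
    return out


def importance_vs_performance(reports: dict, feature: str = "GCcds",
                              comparison_features=("log_TPM", "base_TE")
                              ) -> pd.DataFrame:
    """Scatter table of feature importance vs held-out Spearman performance.

    One row per dataset in ``reports``; supports testing whether the
    importance of GCcds predicts model performance across a panel of
    perturbation datasets.
    """
    rows = []
    for name, rep in reports.items():
        row = {"dataset": name,
               f"importance_{feature}": float(rep.importance.get(feature, np.nan)),
               "spearman": rep.performance["spearman"],
               "pearson": rep.performance["pearson"],
               "n_genes": rep.n_genes}
        for f in comparison_features:
            row[f"importance_{f}"] = float(rep.importance.get(f, np.nan))
        rows.append(row)
    return pd.DataFrame(rows)
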