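"""Noise-model based feature selection.

Informative genes are those whose coefficient of variation exceeds what
a technical-noise model predicts for their mean.  The noise model is a
support-vector regression of log2(CV) on log2(mean) across all genes
with positive mean; a gene's score is its residual (observed minus
predicted log2 CV).  A sibling-exclusion step removes genes peculiar to
the sibling branch of a cluster split before re-clustering, so that
carryover or contamination from the sibling cannot seed spurious
subclusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .matrix import ExpressionMatrix


@dataclass
class NoiseModel:
    """Fitted log2(CV) ~ log2(mean) regression with per-gene residuals."""

    svr: SVR
    residuals: pd.Series  # observed - predicted log2 CV, positive-mean genes
    means: pd.Series  # per-gene mean over cells (positive-mean genes)
    gamma: float = 0.06

    def predict_log2_cv(self, mean: np.ndarray) -> np.ndarray:
        mean = np.asarray(mean, dtype=float)
        if np.any(mean <= 0):
            raise ValueError("noise model is defined for positive means only")
        return self.svr.predict(np.log2(mean).reshape(-1, 1))


def fit_noise_model(
    matrix: ExpressionMatrix,
    gamma: float = 0.06,
    trim_quantile: float = 0.9,
    n_passes: int = 2,
) -> NoiseModel:
    """SVR of log2(CV) on log2(mean) over genes with positive mean.

    The regression is refit after trimming the genes above the
    ``trim_quantile`` of residuals, so genuinely variable genes do not
    drag the noise floor up toward themselves; the final residuals are
    reported for all genes against the trimmed fit.
    """
    mu = matrix.counts.mean(axis=1)
    pos = mu > 0
    if pos.sum() < 50:
        raise ValueError("need >= 50 genes with positive mean to fit the noise model")
    sd = matrix.counts[pos].std(axis=1, ddof=0)
    if np.all(sd == 0):
        raise ValueError("degenerate input: all genes constant")
    log_mu = np.log2(mu[pos])
    # CV of an all-constant positive gene is 0; floor to keep the log finite
    cv = np.maximum(sd / mu[pos], 1e-10)
    log_cv = np.log2(cv)
    X = log_mu.reshape(-1, 1)
    keep = np.ones(len(log_cv), dtype=bool)
    svr = SVR(gamma=gamma)
    for _ in range(max(n_passes, 1)):
        svr = SVR(gamma=gamma)
        svr.fit(X[keep], log_cv[keep])
        resid = log_cv - svr.predict(X)
        keep = resid <= np.quantile(resid, trim_quantile)
    genes = matrix.genes[pos]
    return NoiseModel(
        svr=svr,
        residuals=pd.Series(resid, index=genes),
        means=pd.Series(mu[pos], index=genes),
        gamma=gamma,
    )


def select_variable_genes(
    matrix: ExpressionMatrix, model: NoiseModel, n: int
) -> list[str]:
    """The n genes with largest CV excess over the noise model.

    Ties break toward the higher-mean gene, then lexicographic ID, so the
    selection is a pure function of the matrix and hyperparameters.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(model.residuals):
        raise ValueError("n exceeds the number of positive-mean genes")
    df = pd.DataFrame({"resid": model.residuals, "mean": model.means})
    # stable sort over a lexicographically sorted base order implements
    # the (residual desc, mean desc, gene ID asc) tie-break
    df = df.sort_index().sort_values(
        by=["resid", "mean"], ascending=[False, False], kind="mergesort"
    )
    return list(df.index[:n])


def exclude_sibling_genes(
    matrix: ExpressionMatrix,
    sibling_gene_set: list[str],
    core_corr: float = 0.5,
    expand_corr: float = 0.3,
    core_fraction: float = 0.5,
) -> list[str]:
    """Genes to exclude before re-clustering a cluster's sibling.

    Starting from the genes the biclustering assigned to the sibling, a
    core of mutually correlated sibling genes is defined (mean pairwise
    Pearson correlation on log1p counts >= ``core_corr``); any gene in the
    matrix correlated >= ``expand_corr`` with at least ``core_fraction``
    of the core joins the excluded set.  Returns core ∪ expansion.
    """
    if not sibling_gene_set:
        raise ValueError("sibling_gene_set must be non-empty")
    sib = [g for g in sibling_gene_set if g in matrix.genes]
    log_all = np.log1p(matrix.counts.astype(float))
    gi = matrix.genes.get_indexer(sib)
    X = log_all[gi]
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.corrcoef(X)
    C = np.nan_to_num(np.atleast_2d(C), nan=0.0)
    np.fill_diagonal(C, np.nan)
    mean_corr = np.nanmean(C, axis=1) if len(sib) > 1 else np.array([np.nan])
    core_mask = mean_corr >= core_corr
    if not core_mask.any():
        warnings.warn(
            "no core of correlated sibling genes; returning the sibling set unchanged"
        )
        return list(sibling_gene_set)
    core_idx = gi[core_mask]
    core = [matrix.genes[i] for i in core_idx]

    core_X = log_all[core_idx]
    sd_all = log_all.std(axis=1)
    sd_core = core_X.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = (log_all - log_all.mean(axis=1, keepdims=True)) @ (
            core_X - core_X.mean(axis=1, keepdims=True)
        ).T / matrix.n_cells
        cc /= np.outer(sd_all, sd_core)
    cc = np.nan_to_num(cc, nan=0.0)
    frac = (cc >= expand_corr).mean(axis=1)
    expansion = [g for g, f in zip(matrix.genes, frac) if f >= core_fraction]
    return sorted(set(core) | set(expansion))
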