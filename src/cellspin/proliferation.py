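"""Proliferation index: a learned cell-cycle score per cell.

The score is learned in four steps: (A) restrict the feature space to
cell-cycle-annotated genes that are detected and mutually correlated
(the coherent proliferation module); (B) split cells into cycling /
non-cycling with k-means (k = 2) in that subspace; (C) fit a strongly
L1-regularized linear regression of the 0/1 cycling label on the
log-centered panel expression — deliberately over-regularized so the
score generalizes beyond the k-means split rather than memorizing it;
(D) apply the fitted linear function to score any cell, including cells
from a different dataset than the one the model was trained on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.linear_model import Lasso

from .matrix import ExpressionMatrix


@dataclass
class CycleScoreModel:
    panel: list  # gene panel the weights are defined over
    weights: np.ndarray  # sparse L1-regularized coefficients
    intercept: float
    alpha: float
    gene_means: np.ndarray  # training log1p means used for centering
    training_labels: pd.Series  # cell -> 0/1 k-means split used as target
    call_cutoff: float = 0.5

    def score_frame(self, log_centered: np.ndarray) -> np.ndarray:
        return log_centered @ self.weights + self.intercept


def select_cycle_genes(
    matrix: ExpressionMatrix,
    annotation_genes: list,
    min_molecules: int = 10,
    corr_percentile: float = 99.0,
    min_partners: int = 12,
) -> list:
    """Coherently co-expressed cell-cycle genes.

    Restricts to annotation genes detected at >= ``min_molecules`` total,
    computes their pairwise Pearson correlation (log1p counts), sets the
    threshold at the ``corr_percentile``-th percentile of the
    off-diagonal entries, and keeps genes correlated above it with at
    least ``min_partners`` other genes.
    """
    if not annotation_genes:
        raise ValueError("annotation_genes must be non-empty")
    present = [g for g in annotation_genes if g in matrix.genes]
    sub = matrix.subset_genes(np.sort(matrix.genes.get_indexer(present)))
    totals = sub.gene_totals()
    sub = sub.subset_genes(totals >= min_molecules)
    if sub.n_genes < min_partners + 1:
        raise ValueError(
            f"only {sub.n_genes} annotation genes survive the molecule filter; "
            f"cannot satisfy the {min_partners}-partner rule"
        )
    X = np.log1p(sub.counts.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X)
    C = np.nan_to_num(np.atleast_2d(C), nan=0.0)
    off = C[~np.eye(C.shape[0], dtype=bool)]
    threshold = np.percentile(off, corr_percentile)
    partners = (C >= threshold).sum(axis=1) - 1  # exclude self
    keep = partners >= min_partners
    if keep.sum() == 0:
        raise ValueError("no gene has enough strongly correlated partners")
    return list(sub.genes[keep])


def _log_centered(matrix: ExpressionMatrix, panel: list,
                  means: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Cells x panel log1p expression, per-gene mean-centered.

    Panel genes missing from the matrix are imputed as zero counts (with
    a warning) so a model can score datasets with a reduced gene set.
    """
    X = np.zeros((matrix.n_cells, len(panel)))
    missing = []
    for j, g in enumerate(panel):
        if g in matrix.genes:
            X[:, j] = np.log1p(matrix.counts[matrix.genes.get_loc(g)].astype(float))
        else:
            missing.append(g)
    if missing:
        warnings.warn(f"{len(missing)} panel genes missing from matrix; imputed as 0")
    if means is None:
        means = X.mean(axis=0)
    return X - means, means


def learn_cycle_score(
    matrix: ExpressionMatrix,
    panel: list,
    alpha: float = 0.01,
    seed: int = 0,
    max_reseeds: int = 10,
) -> CycleScoreModel:
    """K-means split then L1-regularized regression of the split label.

    The k-means cluster with the higher mean total panel expression is
    the cycling class (label 1), so the final assignment does not depend
    on k-means' arbitrary cluster indexing.
    """
    X, means = _log_centered(matrix, panel)
    labels = None
    for attempt in range(max_reseeds):
        km = KMeans(n_clusters=2, random_state=seed + attempt, n_init=10)
        fit_labels = km.fit_predict(X)
        if len(np.unique(fit_labels)) == 2:
            labels = fit_labels
            break
    if labels is None:
        raise RuntimeError("k-means produced an empty cluster in every re-seed")

    panel_totals = X.sum(axis=1)
    mean0 = panel_totals[labels == 0].mean()
    mean1 = panel_totals[labels == 1].mean()
    cycling = (labels == (1 if mean1 >= mean0 else 0)).astype(float)

    lasso = Lasso(alpha=alpha, random_state=seed)
    lasso.fit(X, cycling)
    return CycleScoreModel(
        panel=list(panel),
        weights=lasso.coef_.copy(),
        intercept=float(lasso.intercept_),
        alpha=alpha,
        gene_means=means,
        training_labels=pd.Series(cycling.astype(int), index=matrix.cells),
    )


def score_proliferation(
    model: CycleScoreModel, matrix: ExpressionMatrix
) -> pd.DataFrame:
    """Per-cell proliferation score and binary cycling call.

    The model may be applied to a matrix other than the training one
    (e.g. a score learned on embryonic tissue applied to stem-cell
    cultures); centering reuses the training means.
    """
    X, _ = _log_centered(matrix, model.panel, means=model.gene_means)
    score = model.score_frame(X)
    return pd.DataFrame(
        {"score": score, "cycling": (score > model.call_cutoff).astype(int)},
        index=matrix.cells,
    )
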