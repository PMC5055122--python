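"""Principal-curve pseudotime and smooth expression profiles.

Cells of one lineage are ordered by (1) selecting genes that vary
significantly with sampling age — a likelihood-ratio test of a
negative-binomial model with age as a categorical predictor against an
intercept-only null, an ANOVA for overdispersed counts — then (2)
projecting onto the principal components with SD above a cutoff and
fitting a principal curve, the smooth one-dimensional curve passing
through the middle of the cloud; each cell's pseudotime is the arc
length of its projection from the start of the curve.  (3) Per-gene
smooth expression profiles over pseudotime are fit with support-vector
regression (hyperparameters by stratified cross-validation), and (4)
profiles with adequate fit are clustered by affinity propagation into
prototypical dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2
from sklearn.cluster import AffinityPropagation
from sklearn.decomposition import PCA
from sklearn.linear_model import Lasso
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVR
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix
from .features import fit_noise_model, select_variable_genes

PROFILE_GRID = 50


@dataclass
class PseudotimeFit:
    genes: list
    pc_sds: np.ndarray
    n_pcs: int
    curve_points: np.ndarray  # control points in PC space (ordered)
    pseudotime: pd.Series  # cell -> arc length >= 0
    converged: bool
    profiles: pd.DataFrame = None  # genes x PROFILE_GRID, set by profile fit
    r2: pd.Series = None
    profile_labels: pd.Series = None
    grid: np.ndarray = None


# ---------------------------------------------------------------------------
# (1) time-varying gene selection: NB LRT with categorical age
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """NB2 log-likelihood, var = mu + phi mu^2."""
    mu = np.maximum(mu, 1e-8)
    if phi < 1e-10:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))
    r = 1.0 / phi
    return float(
        np.sum(
            gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
            + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
        )
    )


def nb_lrt_categorical(y: np.ndarray, groups: np.ndarray) -> float:
    """p-value of the age effect for one gene.

    With a categorical-only design the NB maximum-likelihood means are
    the group sample means for any fixed dispersion, so the fit is
    closed-form: the dispersion is profiled out under the alternative
    and shared by both models of the test, keeping it calibrated on NB
    null data.  Degrees of freedom = number of ages - 1.
    """
    y = np.asarray(y, dtype=float)
    uniq, inv = np.unique(groups, return_inverse=True)
    mu_alt = np.bincount(inv, weights=y) / np.bincount(inv)
    mu_alt_cells = mu_alt[inv]
    mu_null = np.full_like(y, y.mean())

    def neg_ll(log_phi: float) -> float:
        return -_nb_loglik(y, mu_alt_cells, np.exp(log_phi))

    res = minimize_scalar(neg_ll, bounds=(-12.0, 5.0), method="bounded")
    phi = float(np.exp(res.x))
    stat = 2.0 * (_nb_loglik(y, mu_alt_cells, phi) - _nb_loglik(y, mu_null, phi))
    return float(chi2.sf(max(stat, 0.0), df=len(uniq) - 1))


def select_time_varying_genes(
    matrix: ExpressionMatrix,
    ages: pd.Series,
    fdr: float = 0.01,
    exclusion_set: list = (),
    n_top: int = 5000,
) -> list:
    """Genes that vary significantly with sampling age.

    Pre-selects the ``n_top`` most variable genes by CV excess over the
    noise model, runs the NB likelihood-ratio test per gene, controls
    the FDR by Benjamini-Hochberg at ``fdr``, and removes genes in the
    exclusion set (e.g. genes significant in other cell types).
    """
    ages = ages.reindex(matrix.cells)
    groups = ages.to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 distinct ages")
    model = fit_noise_model(matrix)
    n = min(n_top, len(model.residuals))
    candidates = select_variable_genes(matrix, model, n)

    pvals, tested = [], []
    for g in candidates:
        y = matrix.counts[matrix.genes.get_loc(g)]
        try:
            pvals.append(nb_lrt_categorical(y, groups))
            tested.append(g)
        except (ValueError, FloatingPointError) as err:  # pragma: no cover
            warnings.warn(f"NB fit failed for {g}: {err}; gene dropped")
    if not tested:
        return []
    reject, _, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    selected = [g for g, r in zip(tested, reject) if r]
    excl = set(exclusion_set)
    return [g for g in selected if g not in excl]


# ---------------------------------------------------------------------------
# (2) principal curve
# ---------------------------------------------------------------------------

def _project_to_polyline(Y: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project points onto a polyline; returns (arc_lengths, projections)."""
    seg = V[1:] - V[:-1]  # (m-1, d)
    seglen = np.linalg.norm(seg, axis=1)
    keep = seglen > 1e-12
    seg, starts, seglen = seg[keep], V[:-1][keep], seglen[keep]
    cum = np.concatenate([[0.0], np.cumsum(seglen)])[:-1]
    # t[i, s]: position of point i along segment s, clipped to [0, 1]
    diff = Y[:, None, :] - starts[None, :, :]
    t = np.clip(
        np.einsum("isd,sd->is", diff, seg) / (seglen**2)[None, :], 0.0, 1.0
    )
    proj = starts[None, :, :] + t[:, :, None] * seg[None, :, :]
    d2 = ((Y[:, None, :] - proj) ** 2).sum(axis=2)
    best = np.argmin(d2, axis=1)
    idx = np.arange(len(Y))
    arc = cum[best] + t[idx, best] * seglen[best]
    return arc, proj[idx, best]


def fit_principal_curve(
    Y: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 50,
    lowess_frac: float = 0.3,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Hastie-Stuetzle principal curve by alternating projection/smoothing.

    Initialized on the first principal component; each iteration smooths
    every coordinate against the current arc-length parameter (lowess)
    and re-projects the points onto the resulting polyline, until the
    mean squared displacement of the projections falls below ``tol``.
    Returns (arc_lengths, curve_control_points, converged).
    """
    Y = np.asarray(Y, dtype=float)
    center = Y.mean(axis=0)
    _, _, Vt = np.linalg.svd(Y - center, full_matrices=False)
    lam = (Y - center) @ Vt[0]
    order = np.argsort(lam)
    curve = center + np.outer(lam[order], Vt[0])
    arc, proj_prev = _project_to_polyline(Y, curve)
    converged = False
    for _ in range(max_iter):
        order = np.argsort(arc, kind="mergesort")
        lam_s = arc[order]
        smoothed = np.column_stack(
            [
                lowess(Y[order, d], lam_s, frac=lowess_frac, return_sorted=False)
                for d in range(Y.shape[1])
            ]
        )
        # collapse duplicate parameter values to keep the polyline simple
        uniq, first = np.unique(np.round(lam_s, 10), return_index=True)
        curve = smoothed[first] if len(first) >= 2 else smoothed
        arc, proj = _project_to_polyline(Y, curve)
        shift = float(np.mean((proj - proj_prev) ** 2))
        proj_prev = proj
        if shift < tol:
            converged = True
            break
    return arc, curve, converged


def _normalized_log(matrix: ExpressionMatrix, genes: list) -> np.ndarray:
    """Cells x genes log1p of depth-normalized molecule counts.

    Counts are scaled to the mean library size so that the dominant
    axis of variation is biology rather than sampling depth.
    """
    gi = matrix.genes.get_indexer(genes)
    totals = matrix.cell_totals().astype(float)
    totals[totals == 0] = 1.0
    norm = matrix.counts[gi] / totals[None, :] * totals.mean()
    return np.log1p(norm).T


def fit_principal_curve_pseudotime(
    matrix: ExpressionMatrix,
    genes: list,
    ages: pd.Series | None = None,
    pc_sd_cut: float = 0.25,
    noise_floor: str | None = "permutation",
    seed: int = 0,
) -> PseudotimeFit:
    """PCA -> retained components (SD > cutoff) -> principal curve.

    Components are retained when their SD exceeds both ``pc_sd_cut`` and
    (by default) a parallel-analysis noise floor — the leading PC SD of
    the same data with every gene column independently permuted — which
    makes the retention robust to the absolute expression scale.  At
    least two components are always kept.  Pseudotime is the arc length
    from the start of the curve; the start is chosen so pseudotime
    correlates positively with sampling age (falling back to the first
    PC when no ages are given).
    """
    X = _normalized_log(matrix, genes)
    pca = PCA(random_state=seed)
    Z = pca.fit_transform(X)
    sds = Z.std(axis=0, ddof=1)
    cut = pc_sd_cut
    if noise_floor == "permutation":
        rng = np.random.default_rng(seed)
        Xp = np.column_stack(
            [rng.permutation(X[:, j]) for j in range(X.shape[1])]
        )
        perm_sd = PCA(n_components=1).fit(Xp).singular_values_[0] / np.sqrt(
            X.shape[0] - 1
        )
        cut = max(cut, perm_sd)
    elif noise_floor is not None:
        raise ValueError(f"unknown noise_floor {noise_floor!r}")
    n_pcs = max(int((sds > cut).sum()), 2)
    if Z.shape[1] < 2:
        raise ValueError("fewer than 2 principal components available")
    Z = Z[:, :n_pcs]

    arc, curve, converged = fit_principal_curve(Z)
    anchor = (
        ages.reindex(matrix.cells).to_numpy(dtype=float)
        if ages is not None
        else Z[:, 0]
    )
    if np.std(anchor) > 0 and np.corrcoef(arc, anchor)[0, 1] < 0:
        arc = arc.max() - arc
        curve = curve[::-1]
    return PseudotimeFit(
        genes=list(genes),
        pc_sds=sds,
        n_pcs=n_pcs,
        curve_points=curve,
        pseudotime=pd.Series(arc - arc.min(), index=matrix.cells),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# (3) smooth profiles via SVR with stratified CV
# ---------------------------------------------------------------------------

def _impute_zeros(X: np.ndarray, j: int, n_neighbors: int = 30,
                  alpha: float = 0.1) -> np.ndarray:
    """Replace technical zeros of gene j with an L1-regression prediction
    from its most-correlated genes (zeros only; observed counts kept)."""
    y = X[:, j]
    zeros = y == 0
    if not zeros.any() or zeros.all() or X.shape[1] < 2:
        return y
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X.T)[j]
    corr[j] = -np.inf
    corr = np.nan_to_num(corr, nan=-np.inf)
    nbr = np.argsort(corr)[::-1][: min(n_neighbors, X.shape[1] - 1)]
    model = Lasso(alpha=alpha, max_iter=2000)
    model.fit(X[~zeros][:, nbr], y[~zeros])
    out = y.astype(float).copy()
    out[zeros] = np.maximum(model.predict(X[zeros][:, nbr]), 0.0)
    return out


def fit_pseudotime_profiles(
    fit: PseudotimeFit,
    matrix: ExpressionMatrix,
    genes: list | None = None,
    cv_folds: int = 4,
    impute: bool = True,
    seed: int = 0,
    param_grid: dict | None = None,
) -> PseudotimeFit:
    """Per-gene SVR of log1p expression on pseudotime.

    Hyperparameters are chosen by cross-validation with folds stratified
    on pseudotime quantile bins; the reported R-squared is out-of-fold.
    Constant genes get R-squared 0.  Fills ``fit.profiles``, ``fit.r2``
    and ``fit.grid`` in place and returns the fit.
    """
    genes = list(genes) if genes is not None else list(fit.genes)
    t = fit.pseudotime.reindex(matrix.cells).to_numpy()
    X_all = _normalized_log(matrix, genes)  # cells x genes
    bins = np.minimum(
        np.digitize(t, np.quantile(t, np.linspace(0, 1, cv_folds + 1)[1:-1])),
        cv_folds - 1,
    )
    # splits are built on a canonical (pseudotime, cell-id) ordering so the
    # fitted profiles do not depend on the order cells arrive in
    canon = np.lexsort((matrix.cells.astype(str), t))
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = [
        (canon[tr], canon[te])
        for tr, te in skf.split(t[canon].reshape(-1, 1), bins[canon])
    ]
    grid = np.linspace(t.min(), t.max(), PROFILE_GRID)
    param_grid = param_grid or {"C": [1.0, 10.0], "epsilon": [0.05, 0.2]}
    combos = [
        {"C": c, "epsilon": e} for c in param_grid["C"] for e in param_grid["epsilon"]
    ]

    profiles, r2s = {}, {}
    T = t.reshape(-1, 1)
    for j, g in enumerate(genes):
        y = X_all[:, j].copy()
        if y.std() == 0:
            profiles[g] = np.full(PROFILE_GRID, y[0])
            r2s[g] = 0.0
            continue
        if impute:
            y = _impute_zeros(X_all, j)
        best_r2, best_params = -np.inf, combos[0]
        for params in combos:
            pred = np.empty_like(y)
            for tr, te in splits:
                svr = SVR(**params)
                svr.fit(T[tr], y[tr])
                pred[te] = svr.predict(T[te])
            ss_res = np.sum((y - pred) ** 2)
            ss_tot = np.sum((y - y.mean()) ** 2)
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
            if r2 > best_r2:
                best_r2, best_params = r2, params
        svr = SVR(**best_params)
        svr.fit(T[canon], y[canon])  # canonical order: order-invariant fit
        profiles[g] = svr.predict(grid.reshape(-1, 1))
        r2s[g] = float(best_r2)

    fit.profiles = pd.DataFrame(profiles).T
    fit.profiles.columns = range(PROFILE_GRID)
    fit.r2 = pd.Series(r2s)
    fit.grid = grid
    return fit


# ---------------------------------------------------------------------------
# (4) profile clustering
# ---------------------------------------------------------------------------

def cluster_profiles(
    fit: PseudotimeFit, r2_cut: float = 0.35, seed: int = 0
) -> tuple[pd.Series, pd.DataFrame]:
    """Affinity-propagation clustering of standardized profiles.

    Profiles with R-squared below ``r2_cut`` are considered not
    significant and carry no label.  Similarity is the negative squared
    distance between per-gene standardized profiles on the pseudotime
    grid; the preference is the median similarity (the sklearn default),
    so the number of prototypical dynamics is data-driven.  Returns
    (labels, exemplar profiles).
    """
    if fit.profiles is None or fit.r2 is None:
        raise ValueError("run fit_pseudotime_profiles first")
    passing = fit.r2[fit.r2 >= r2_cut].index
    if len(passing) == 0:
        fit.profile_labels = pd.Series(dtype=object)
        return fit.profile_labels, pd.DataFrame()
    P = fit.profiles.loc[passing].to_numpy(dtype=float)
    mu = P.mean(axis=1, keepdims=True)
    sd = P.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (P - mu) / sd
    if len(passing) == 1:
        labels = pd.Series([0], index=passing)
        fit.profile_labels = labels
        return labels, fit.profiles.loc[passing]
    ap = AffinityPropagation(random_state=seed)
    raw = ap.fit_predict(Z)
    labels = pd.Series(raw, index=passing)
    exemplars = fit.profiles.loc[passing[ap.cluster_centers_indices_]]
    fit.profile_labels = labels
    return labels, exemplars


def profile_direction(profile: np.ndarray) -> str:
    """'up' / 'down' / 'flat' read from the profile endpoints."""
    lo, hi = profile[0], profile[-1]
    span = np.ptp(profile)
    if span < 1e-9 or abs(hi - lo) < 0.1 * max(span, 1e-9):
        return "flat"
    return "up" if hi > lo else "down"
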