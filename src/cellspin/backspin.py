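"""SPIN sorting and BackSPIN recursive biclustering.

SPIN (sorting points into neighborhoods) permutes a symmetric
dissimilarity matrix so that similar items end up at nearby positions.
The energy of a permutation is

    E(order) = sum_{i,j} D[order[i], order[j]] * G[i, j],

with ``G[i, j] = exp(-(i - j)^2 / w^2)`` a Gaussian neighborhood weight
on positional distance; the sort iterates reassignments under a
gradually decreasing width ``w``, accepting a new order only when it
lowers the energy.

BackSPIN extends SPIN with a recursive two-way split: at each node the
sorted cell-correlation matrix is divided at the position ``x`` (size of
the left block) maximizing

    f(x) = [ sum_{i,j <= x, i != j} C_ij + sum_{i,j > x, i != j} C_ij ]
           / [ x^2 + (n - x)^2 ],

and every gene is handed to the daughter cluster in which its
expression center of mass falls.  Recursion stops when the best split's
objective does not exceed the node's mean off-diagonal correlation by a
factor ``stop_const``, when the depth limit is reached, or when a node
becomes too small.  Feature selection is re-run at every node, with
genes peculiar to the sibling branch excluded, so each sub-clustering
happens in its own informative subspace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .features import fit_noise_model, select_variable_genes, exclude_sibling_genes


@dataclass
class BackspinParams:
    numLevels: int = 7
    runs_iters: int = 12
    runs_step: float = 0.1
    stop_const: float = 1.1
    stop_mode: str = "normalized"  # "normalized" or "raw"
    min_split_score: float = 0.1  # floor on post-split within-block correlation
    min_node_cells: int = 4
    n_features: int = 200
    first_width_factor: float = 0.5  # initial width = factor * n

    def __post_init__(self) -> None:
        if self.numLevels < 1 or self.runs_iters < 1:
            raise ValueError("numLevels and runs_iters must be >= 1")
        if not (0 < self.runs_step <= 1):
            raise ValueError("runs_step must lie in (0, 1]")
        if self.stop_const <= 0:
            raise ValueError("stop_const must be positive")


@dataclass
class SortedMatrix:
    C: np.ndarray  # correlation matrix in the ORIGINAL index order
    order: np.ndarray  # permutation: order[k] = original index at position k
    width_schedule: list = field(default_factory=list)
    energy_trace: list = field(default_factory=list)  # (width, [energies])

    @property
    def sorted_C(self) -> np.ndarray:
        return self.C[np.ix_(self.order, self.order)]


@dataclass
class SplitResult:
    x_s: int  # size of the left block
    f: float
    f_curve: np.ndarray  # f at x = 1 .. n-1
    n: int


@dataclass
class ClusterNode:
    cells: list  # cell identifiers
    genes: list  # gene identifiers assigned to this node
    depth: int
    split: SplitResult | None = None
    children: list = field(default_factory=list)
    label: str | None = None  # set on leaves
    cell_order: list | None = None  # SPIN order of cells within the node
    gene_order: list | None = None  # SPIN order of genes (leaves only)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["ClusterNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for child in self.children for leaf in child.leaves()]

    def leaf_labels(self) -> pd.Series:
        pairs = [(c, leaf.label) for leaf in self.leaves() for c in leaf.cells]
        return pd.Series(dict(pairs))

    def to_dict(self) -> dict:
        d = {
            "cells": list(self.cells),
            "genes": list(self.genes),
            "depth": self.depth,
            "label": self.label,
        }
        if self.split is not None:
            d["split"] = {
                "x_s": self.split.x_s,
                "f": self.split.f,
                "f_curve": list(map(float, self.split.f_curve)),
            }
        if self.children:
            d["children"] = [c.to_dict() for c in self.children]
        return d


# ---------------------------------------------------------------------------
# SPIN sorting
# ---------------------------------------------------------------------------

def _neighborhood_weights(n: int, width: float) -> np.ndarray:
    pos = np.arange(n)
    return np.exp(-((pos[:, None] - pos[None, :]) ** 2) / max(width, 1e-9) ** 2)


def _energy(D: np.ndarray, order: np.ndarray, G: np.ndarray) -> float:
    return float(np.sum(D[np.ix_(order, order)] * G))


def spin_sort(
    C: np.ndarray,
    params: BackspinParams | None = None,
    seed: int = 0,
    is_distance: bool = False,
) -> SortedMatrix:
    """Sort a correlation (or distance) matrix with decreasing-width SPIN.

    ``C`` is interpreted as a similarity unless ``is_distance`` is set;
    internally the sort minimizes the Gaussian-neighborhood energy of the
    dissimilarity ``D = 1 - C``.  The reassignment step ranks items by
    the weighted positional center of their fit profile (how well each
    item sits at each position) and re-sorts; a candidate order is kept
    only if it lowers the energy, which makes the recorded energy trace
    non-increasing within each width.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("input must be a square matrix")
    if np.max(np.abs(C - C.T)) > 1e-8:
        raise ValueError("input matrix is not symmetric")
    n = C.shape[0]
    D = C.copy() if is_distance else 1.0 - C
    np.fill_diagonal(D, 0.0)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    widths, trace = [], []
    width = max(params.first_width_factor * n if params else 0.5 * n, 1.0)
    runs_iters = params.runs_iters if params else 12
    runs_step = params.runs_step if params else 0.1

    while True:
        G = _neighborhood_weights(n, width)
        energies = [_energy(D, order, G)]
        for _ in range(runs_iters):
            # fit[i, p]: mismatch cost of placing item i at position p
            fit = D[:, order] @ G
            # weighted positional center of the (inverted) mismatch profile
            goodness = fit.max(axis=1, keepdims=True) - fit
            norm = goodness.sum(axis=1)
            norm[norm == 0] = 1.0
            center = (goodness * np.arange(n)).sum(axis=1) / norm
            # ties broken by previous position
            prev_pos = np.empty(n)
            prev_pos[order] = np.arange(n)
            cand = np.lexsort((prev_pos, np.round(center, 12)))
            e_new = _energy(D, cand, G)
            if e_new < energies[-1] - 1e-12:
                order = cand
                energies.append(e_new)
            else:
                energies.append(energies[-1])
                break
        widths.append(width)
        trace.append((width, energies))
        if width <= 1.0:
            break
        width = max(width * runs_step, 1.0) if width * runs_step >= 1.0 else 1.0
    return SortedMatrix(C=C, order=order, width_schedule=widths, energy_trace=trace)


# ---------------------------------------------------------------------------
# Split objective
# ---------------------------------------------------------------------------

def split_score(C_sorted: np.ndarray, x: int) -> float:
    """Block-mean split objective at left-block size ``x``.

    Sums the off-diagonal correlations inside the two blocks of sizes
    ``x`` and ``n - x`` and normalizes by ``x^2 + (n - x)^2``.
    """
    C_sorted = np.asarray(C_sorted, dtype=float)
    n = C_sorted.shape[0]
    if not (1 <= x <= n - 1):
        raise ValueError(f"x must lie in [1, {n - 1}], got {x}")
    left = C_sorted[:x, :x]
    right = C_sorted[x:, x:]
    num = (left.sum() - np.trace(left)) + (right.sum() - np.trace(right))
    return float(num / (x**2 + (n - x) ** 2))


def find_split(sorted_matrix: SortedMatrix | np.ndarray) -> SplitResult:
    """Exhaustive maximization of the split objective; ties go to smaller x."""
    Cs = (
        sorted_matrix.sorted_C
        if isinstance(sorted_matrix, SortedMatrix)
        else np.asarray(sorted_matrix, dtype=float)
    )
    n = Cs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to split")
    curve = np.array([split_score(Cs, x) for x in range(1, n)])
    x_s = int(np.argmax(curve)) + 1  # argmax returns the first (smallest x) max
    return SplitResult(x_s=x_s, f=float(curve[x_s - 1]), f_curve=curve, n=n)


def assign_genes_center_of_mass(
    A: np.ndarray, x_s: int
) -> tuple[np.ndarray, np.ndarray]:
    """Assign genes to daughter clusters by expression center of mass.

    ``A`` is genes x cells with columns already in the sorted cell order;
    positions are 1..n.  A gene goes left (K) when its center of mass is
    <= ``x_s``, else right (L).  All-zero genes go left.  Returns boolean
    masks (K, L) over genes.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[1]
    pos = np.arange(1, n + 1)
    totals = A.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cm = (A * pos).sum(axis=1) / totals
    cm = np.where(totals > 0, cm, 0.0)  # all-zero genes -> left
    K = cm <= x_s
    return K, ~K


# ---------------------------------------------------------------------------
# Recursive biclustering
# ---------------------------------------------------------------------------

def _default_feature_selector(
    sub: ExpressionMatrix, excluded: set, n_features: int
) -> list[str]:
    candidates = sub.subset_genes(~sub.genes.isin(list(excluded)))
    try:
        model = fit_noise_model(candidates)
    except ValueError:
        return [g for g in sub.genes if g not in excluded]
    n = min(n_features, len(model.residuals))
    return select_variable_genes(candidates, model, n)


def _cell_correlation(matrix: ExpressionMatrix, genes: list[str]) -> np.ndarray:
    gi = matrix.genes.get_indexer(genes)
    X = np.log1p(matrix.counts[gi].astype(float))
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X.T)
    C = np.nan_to_num(np.atleast_2d(C), nan=0.0)
    np.fill_diagonal(C, 1.0)
    # constant cells correlate with nothing; their rows stay 0 off-diagonal
    C[sd == 0, :] = 0.0
    C[:, sd == 0] = 0.0
    np.fill_diagonal(C, 1.0)
    return C


def _mean_offdiag(C: np.ndarray) -> float:
    n = C.shape[0]
    return float((C.sum() - np.trace(C)) / (n * (n - 1)))


def backspin(
    matrix: ExpressionMatrix,
    params: BackspinParams | None = None,
    feature_selector: Callable[[ExpressionMatrix, set, int], list[str]] | None = None,
    seed: int = 0,
) -> ClusterNode:
    """Recursive SPIN-based biclustering of cells and genes.

    At every node: select features (excluding genes peculiar to the
    sibling cluster), correlate cells on log1p counts over those
    features, SPIN-sort, evaluate the split objective, and recurse when
    ``f(x_s) > stop_const * mean off-diagonal correlation`` of the node
    and the depth limit is not reached.  Genes are partitioned between
    the daughters by center of mass; leaves receive labels and a
    SPIN-sorted gene order (the within-cluster gene correlation view).
    """
    params = params or BackspinParams()
    selector = feature_selector or _default_feature_selector

    def recurse(sub: ExpressionMatrix, genes: list[str], excluded: set, depth: int,
                node_seed: int) -> ClusterNode:
        node = ClusterNode(cells=list(sub.cells), genes=list(genes), depth=depth)
        if sub.n_cells < max(params.min_node_cells, 4) or depth >= params.numLevels:
            return node
        features = selector(sub.subset_genes(sub.genes.isin(genes)), excluded,
                            params.n_features)
        if len(features) < 2:
            return node
        C = _cell_correlation(sub, features)
        sm = spin_sort(C, params, seed=node_seed)
        node.cell_order = [sub.cells[i] for i in sm.order]
        split = find_split(sm)
        node.split = split
        if params.stop_mode == "raw":
            proceed = split.f > params.stop_const
        else:
            # normalized rule: the split must beat the node's background
            # correlation by the stop factor AND leave a within-block
            # average correlation above an absolute floor — the ratio
            # alone is meaningless when the background is near zero
            proceed = (
                split.f > params.stop_const * _mean_offdiag(sm.sorted_C)
                and split.f > params.min_split_score
            )
        if not proceed:
            return node
        if split.x_s < params.min_node_cells or split.n - split.x_s < params.min_node_cells:
            return node

        gi = sub.genes.get_indexer(genes)
        A_sorted = sub.counts[np.ix_(gi, sm.order)]
        K_mask, L_mask = assign_genes_center_of_mass(A_sorted, split.x_s)
        genes_arr = np.asarray(genes, dtype=object)
        genes_K = list(genes_arr[K_mask])
        genes_L = list(genes_arr[L_mask])

        left_cells = sm.order[: split.x_s]
        right_cells = sm.order[split.x_s:]
        sub_L = sub.subset_cells(np.sort(left_cells))
        sub_R = sub.subset_cells(np.sort(right_cells))

        # genes peculiar to the sibling are excluded when re-clustering
        excl_for_left = excluded | _sibling_exclusion(sub, genes_L)
        excl_for_right = excluded | _sibling_exclusion(sub, genes_K)

        node.children = [
            recurse(sub_L, genes_K, excl_for_left, depth + 1, node_seed * 2 + 1),
            recurse(sub_R, genes_L, excl_for_right, depth + 1, node_seed * 2 + 2),
        ]
        return node

    def _sibling_exclusion(sub: ExpressionMatrix, sibling_genes: list[str]) -> set:
        if not sibling_genes:
            return set()
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            return set(exclude_sibling_genes(sub, sibling_genes))

    root = recurse(matrix, list(matrix.genes), set(), 0, seed + 1)
    _label_and_sort_leaves(root, matrix, params)
    return root


def _label_and_sort_leaves(root: ClusterNode, matrix: ExpressionMatrix,
                           params: BackspinParams) -> None:
    for i, leaf in enumerate(root.leaves()):
        leaf.label = f"C{i:02d}"
        if len(leaf.genes) >= 3 and len(leaf.cells) >= 2:
            sub = matrix.subset_cells(np.sort(matrix.cells.get_indexer(leaf.cells)))
            gi = sub.genes.get_indexer(leaf.genes)
            X = np.log1p(sub.counts[gi].astype(float))
            keep = X.std(axis=1) > 0
            if keep.sum() >= 3:
                Cg = np.corrcoef(X[keep])
                Cg = np.nan_to_num(np.atleast_2d(Cg), nan=0.0)
                light = BackspinParams(runs_iters=min(params.runs_iters, 6))
                order = spin_sort(Cg, light, seed=0).order
                kept = np.asarray(leaf.genes, dtype=object)[keep]
                leaf.gene_order = list(kept[order])


# ---------------------------------------------------------------------------
# Within-species cluster correlation summary
# ---------------------------------------------------------------------------

def cluster_correlation_matrix(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    binarized: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Pearson correlation between clusters on the binarized marker matrix.

    Genes enter the calculation when they are significant (binarized 1)
    in at least one cluster AND are detected at >= 1 molecule per cell on
    average in at least one cluster.  Rows/columns are ordered by SPIN
    for display.
    """
    clusters = list(binarized.columns)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    labels = labels.reindex(matrix.cells)
    means = pd.DataFrame(
        {
            cl: matrix.counts[:, (labels == cl).to_numpy()].mean(axis=1)
            for cl in clusters
        },
        index=matrix.genes,
    )
    bin_aligned = binarized.reindex(means.index).fillna(0)
    keep = (bin_aligned.sum(axis=1) >= 1) & (means.max(axis=1) >= 1.0)
    B = bin_aligned.loc[keep].to_numpy(dtype=float)
    if B.shape[0] < 2:
        raise ValueError("fewer than 2 genes pass the correlation filter")
    C = np.corrcoef(B.T)
    C = np.nan_to_num(np.atleast_2d(C), nan=0.0)
    np.fill_diagonal(C, 1.0)
    order = spin_sort(C, seed=seed).order
    ordered = [clusters[i] for i in order]
    return pd.DataFrame(C[np.ix_(order, order)], index=ordered, columns=ordered)
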