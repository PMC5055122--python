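"""Prototype-based probabilistic scoring of query cells.

A multinomial logistic-regression classifier is trained on reference
(in vivo) cell clusters grouped into broader *prototypes* — idealized
expression classes that may merge several biologically related fine
clusters.  Query cells (e.g. stem-cell-derived cultures) are scored as
softmax probability vectors over the prototypes, so a cell of mixed or
intermediate identity is described by its full probability profile
rather than forced into one cluster.

For display, cells are placed on a "wheel plot": prototypes sit at the
vertices of a regular polygon and each cell at the probability-weighted
sum of the unit vectors to the vertices; the vertex order is chosen to
minimize the number of cells collapsing into the center.  Scrambling
gene values within each cell provides a negative control that should
fall toward the center.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedShuffleSplit

from .matrix import ExpressionMatrix
from .features import fit_noise_model, select_variable_genes


@dataclass
class PrototypeModel:
    classes: list  # prototype names (classifier order)
    grouping: dict  # cluster label -> prototype name
    panel: list  # gene panel
    clf: LogisticRegression
    gene_max: np.ndarray  # per-gene training max of log1p counts
    C: float
    cv_accuracy: pd.Series = None  # accuracy trace over a C grid, if computed


@dataclass
class WheelLayout:
    vertex_order: list  # prototype names, clockwise from the top
    unit_vectors: np.ndarray  # K x 2
    central_radius: float = 0.2


# ---------------------------------------------------------------------------
# gene panel
# ---------------------------------------------------------------------------

def _features(matrix: ExpressionMatrix, panel: list, gene_max: np.ndarray | None = None):
    """log1p counts max-normalized per gene (training max for queries)."""
    idx = matrix.genes.get_indexer(panel)
    missing = idx < 0
    X = np.zeros((matrix.n_cells, len(panel)))
    X[:, ~missing] = np.log1p(matrix.counts[idx[~missing]].astype(float)).T
    if missing.any():
        warnings.warn(f"{int(missing.sum())} panel genes missing; set to 0")
    if gene_max is None:
        gene_max = X.max(axis=0)
    denom = np.where(gene_max > 0, gene_max, 1.0)
    return X / denom, gene_max


def select_training_genes(
    reference: ExpressionMatrix,
    labels: pd.Series,
    outgroup: ExpressionMatrix,
    n_initial: int = 4500,
    min_outgroup_var_frac: float = 0.10,
    min_panel: int = 100,
) -> list:
    """Cell-type-informative gene panel for the prototype classifier.

    Starts from the ``n_initial`` most variable genes of the combined
    reference + outgroup data (CV excess over the noise model), drops
    genes whose variance within the outgroup experiment is below
    ``min_outgroup_var_frac`` of their combined-data variance (features
    that never move in the query-like culture would be learned as
    culture-vs-tissue markers), then halves the list keeping the top
    genes under three cell-type-specificity heuristics: fold-increase,
    fold-increase * fraction-positive, and
    fold-increase * sqrt(fraction-positive).
    """
    shared = reference.genes.intersection(outgroup.genes)
    ref = reference.subset_genes(np.sort(reference.genes.get_indexer(shared)))
    out = outgroup.subset_genes(np.sort(outgroup.genes.get_indexer(shared)))
    combined = ExpressionMatrix(
        np.concatenate([ref.counts, out.counts], axis=1),
        ref.genes,
        pd.Index(list(ref.cells) + [f"out:{c}" for c in out.cells]),
    )
    model = fit_noise_model(combined)
    n0 = min(n_initial, len(model.residuals))
    initial = select_variable_genes(combined, model, n0)

    gi_ref = ref.genes.get_indexer(initial)
    gi_out = out.genes.get_indexer(initial)
    gi_comb = combined.genes.get_indexer(initial)
    var_out = out.counts[gi_out].astype(float).var(axis=1)
    var_comb = combined.counts[gi_comb].astype(float).var(axis=1)
    keep = var_out >= min_outgroup_var_frac * np.maximum(var_comb, 1e-12)
    survivors = [g for g, k in zip(initial, keep) if k]

    labels = labels.reindex(ref.cells)
    clusters = sorted(labels.dropna().unique())
    gi = ref.genes.get_indexer(survivors)
    cluster_means = np.stack(
        [ref.counts[gi][:, (labels == cl).to_numpy()].mean(axis=1) for cl in clusters],
        axis=1,
    )
    frac_pos = np.stack(
        [(ref.counts[gi][:, (labels == cl).to_numpy()] > 0).mean(axis=1) for cl in clusters],
        axis=1,
    )
    order = np.argsort(cluster_means, axis=1)
    top, second = order[:, -1], order[:, -2]
    rows = np.arange(len(survivors))
    fold = cluster_means[rows, top] / np.maximum(cluster_means[rows, second], 1e-9)
    fp = frac_pos[rows, top]
    heuristics = [fold, fold * fp, fold * np.sqrt(fp)]

    target = int(np.ceil(len(survivors) / 2))
    best_rank = np.full(len(survivors), np.inf)
    for h in heuristics:
        ranks = np.empty(len(survivors))
        ranks[np.argsort(-h, kind="mergesort")] = np.arange(len(survivors))
        best_rank = np.minimum(best_rank, ranks)
    chosen = np.argsort(best_rank, kind="mergesort")[:target]
    panel = [survivors[i] for i in sorted(chosen)]
    if len(panel) < min_panel:
        raise ValueError(f"gene panel too small ({len(panel)} < {min_panel})")
    return panel


# ---------------------------------------------------------------------------
# training and scoring
# ---------------------------------------------------------------------------

def _prototype_labels(labels: pd.Series, grouping: dict) -> pd.Series:
    missing = set(labels.dropna().unique()) - set(grouping)
    if missing:
        raise ValueError(f"clusters without a prototype: {sorted(missing)}")
    return labels.map(grouping)


def train_prototype_classifier(
    reference: ExpressionMatrix,
    labels: pd.Series,
    grouping: dict,
    panel: list,
    C: float = 0.01,
    seed: int = 0,
    min_cells: int = 5,
) -> PrototypeModel:
    """Multinomial L2-penalized logistic regression on prototype labels.

    Features are log1p counts max-normalized per gene over the training
    set; the per-gene training maxima are recorded and reused verbatim
    when scoring query cells.
    """
    proto = _prototype_labels(labels.reindex(reference.cells), grouping)
    sizes = proto.value_counts()
    small = sizes[sizes < min_cells]
    if len(small):
        raise ValueError(f"prototypes with < {min_cells} cells: {dict(small)}")
    X, gene_max = _features(reference, panel)
    clf = LogisticRegression(C=C, max_iter=2000, random_state=seed)
    clf.fit(X, proto.to_numpy())
    return PrototypeModel(
        classes=list(clf.classes_),
        grouping=dict(grouping),
        panel=list(panel),
        clf=clf,
        gene_max=gene_max,
        C=C,
    )


def choose_regularization(
    reference: ExpressionMatrix,
    labels: pd.Series,
    grouping: dict,
    panel: list,
    C_grid: list,
    n_iters: int = 35,
    test_frac: float = 0.15,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Accuracy curve over a C grid; pick the plateau onset.

    For each C, the data is split ``n_iters`` times into stratified
    85/15 train/test parts; the curve of mean held-out accuracy is
    returned and the chosen C is the smallest one within one standard
    error of the grid maximum — the point of maximum accuracy before
    the plateau.
    """
    C_grid = list(C_grid)
    if C_grid != sorted(C_grid):
        raise ValueError("C_grid must be sorted ascending")
    proto = _prototype_labels(labels.reindex(reference.cells), grouping).to_numpy()
    X, _ = _features(reference, panel)
    splitter = StratifiedShuffleSplit(
        n_splits=n_iters, test_size=test_frac, random_state=seed
    )
    splits = list(splitter.split(X, proto))
    rows = []
    for C in C_grid:
        accs = []
        for tr, te in splits:
            clf = LogisticRegression(C=C, max_iter=2000, random_state=seed)
            clf.fit(X[tr], proto[tr])
            accs.append(float(np.mean(clf.predict(X[te]) == proto[te])))
        accs = np.asarray(accs)
        rows.append(
            {"C": C, "accuracy": accs.mean(), "se": accs.std(ddof=1) / np.sqrt(len(accs))}
        )
    curve = pd.DataFrame(rows)
    best = curve["accuracy"].max()
    se_at_best = float(curve.loc[curve["accuracy"].idxmax(), "se"])
    ok = curve[curve["accuracy"] >= best - se_at_best]
    return float(ok["C"].iloc[0]), curve


def score_cells(model: PrototypeModel, query: ExpressionMatrix) -> pd.DataFrame:
    """Softmax probability of each prototype for every query cell."""
    present = query.genes.intersection(model.panel)
    if len(present) == 0:
        raise ValueError("query shares no genes with the model panel")
    X, _ = _features(query, model.panel, gene_max=model.gene_max)
    probs = model.clf.predict_proba(X)
    return pd.DataFrame(probs, index=query.cells, columns=model.clf.classes_)


def scrambled_control(
    reference: ExpressionMatrix, model: PrototypeModel, seed: int = 0
) -> pd.DataFrame:
    """Score cells whose gene values were permuted within each cell.

    Scrambling destroys gene identity while preserving every cell's
    molecule-count distribution (and total), so structure-driven scores
    should collapse toward the uniform center.
    """
    rng = np.random.default_rng(seed)
    counts = reference.counts.copy()
    for j in range(counts.shape[1]):
        counts[:, j] = counts[rng.permutation(counts.shape[0]), j]
    scrambled = ExpressionMatrix(
        counts, reference.genes, reference.cells, reference.cell_meta
    )
    return score_cells(model, scrambled)


# ---------------------------------------------------------------------------
# wheel plot geometry
# ---------------------------------------------------------------------------

def _unit_vectors(K: int) -> np.ndarray:
    angles = np.pi / 2 - 2 * np.pi * np.arange(K) / K  # clockwise from the top
    return np.column_stack([np.cos(angles), np.sin(angles)])


def _positions(P: np.ndarray, U: np.ndarray) -> np.ndarray:
    return P @ U


def _central_count(P: np.ndarray, order: tuple, U: np.ndarray, rho: float) -> int:
    pos = _positions(P[:, list(order)], U)
    return int((np.linalg.norm(pos, axis=1) < rho).sum())


def wheel_layout(
    probabilities: pd.DataFrame,
    central_radius: float = 0.2,
    exhaustive_max: int = 8,
) -> tuple[pd.DataFrame, WheelLayout]:
    """Place cells at probability-weighted combinations of polygon vertices.

    The position of a cell with probability vector p is sum_i p_i u_i,
    with u_i the unit vector from the polygon center to vertex i.  The
    circular order of the vertices is chosen to minimize the number of
    cells inside the central area (|x| < ``central_radius``): by
    exhaustive search over circular orders up to ``exhaustive_max``
    prototypes, and by a greedy heuristic placing the most-confused
    prototype pairs adjacent beyond that.
    """
    P = probabilities.to_numpy(dtype=float)
    if np.any(P < 0) or np.max(np.abs(P.sum(axis=1) - 1.0)) > 1e-6:
        raise ValueError("probability rows must lie on the simplex")
    names = list(probabilities.columns)
    K = len(names)
    U = _unit_vectors(K)
    if K <= 2:
        best_order = tuple(range(K))
    elif K <= exhaustive_max:
        best_order, best_count = None, None
        # fix vertex 0 and halve by reflection to enumerate circular orders
        for rest in itertools.permutations(range(1, K)):
            if rest[0] > rest[-1]:
                continue
            order = (0,) + rest
            cnt = _central_count(P, order, U, central_radius)
            if best_count is None or cnt < best_count:
                best_order, best_count = order, cnt
    else:
        best_order = _greedy_order(P, K)
    layout = WheelLayout(
        vertex_order=[names[i] for i in best_order],
        unit_vectors=U,
        central_radius=central_radius,
    )
    pos = _positions(P[:, list(best_order)], U)
    coords = pd.DataFrame(pos, index=probabilities.index, columns=["x", "y"])
    return coords, layout


def _greedy_order(P: np.ndarray, K: int) -> tuple:
    """Chain prototypes so the most-confused pairs sit adjacent."""
    co = P.T @ P  # co-probability mass between prototype pairs
    np.fill_diagonal(co, -np.inf)
    pairs = sorted(
        ((co[i, j], i, j) for i in range(K) for j in range(i + 1, K)), reverse=True
    )
    # greedily build a Hamiltonian path, then close it into the circle
    adj: dict[int, list[int]] = {i: [] for i in range(K)}
    comp = list(range(K))

    def find(i):
        while comp[i] != i:
            comp[i] = comp[comp[i]]
            i = comp[i]
        return i

    for _, i, j in pairs:
        if len(adj[i]) < 2 and len(adj[j]) < 2 and find(i) != find(j):
            adj[i].append(j)
            adj[j].append(i)
            comp[find(i)] = find(j)
    ends = [i for i in range(K) if len(adj[i]) < 2]
    start = ends[0] if ends else 0
    order, prev = [start], None
    while len(order) < K:
        nxt = [n for n in adj[order[-1]] if n != prev]
        if not nxt:
            remaining = [i for i in range(K) if i not in order]
            nxt = [remaining[0]]
        prev = order[-1]
        order.append(nxt[0])
    return tuple(order)
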