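"""SPIN/BackSPIN: split-objective oracle, sorting, gene assignment, tree."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from cellspin.backspin import (
    BackspinParams,
    assign_genes_center_of_mass,
    backspin,
    cluster_correlation_matrix,
    find_split,
    spin_sort,
    split_score,
)
from cellspin.synth import SyntheticSpec, make_clustered_counts


def brute_force_split(C):
    """Independent evaluation of the split objective over all x."""
    n = C.shape[0]
    best_x, best_f, curve = None, -np.inf, []
    for x in range(1, n):
        num = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if (i < x and j < x) or (i >= x and j >= x):
                    num += C[i, j]
        f = num / (x**2 + (n - x) ** 2)
        curve.append(f)
        if f > best_f + 1e-15:
            best_f, best_x = f, x
    return best_x, best_f, np.array(curve)


def test_split_worked_example_two_perfect_blocks():
    C = np.array(
        [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]], dtype=float
    )
    assert split_score(C, 2) == pytest.approx(0.5)
    assert split_score(C, 1) == pytest.approx(0.2)
    res = find_split(C)
    assert res.x_s == 2 and res.f == pytest.approx(0.5)


def test_split_zero_offdiagonal_gives_zero_curve():
    C = np.eye(5)
    assert all(split_score(C, x) == 0.0 for x in range(1, 5))


def test_split_planted_3_plus_3_blocks():
    C = np.full((6, 6), 0.0)
    C[:3, :3] = 0.8
    C[3:, 3:] = 0.8
    np.fill_diagonal(C, 1.0)
    res = find_split(C)
    bx, bf, _ = brute_force_split(C)
    assert res.x_s == bx == 3
    assert res.f == pytest.approx(bf)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(2, 12), st.integers(0, 10**6))
def test_find_split_equals_brute_force_oracle(n, seed):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(n, n))
    C = (A + A.T) / 2
    np.fill_diagonal(C, 1.0)
    res = find_split(C)
    bx, bf, bcurve = brute_force_split(C)
    assert res.x_s == bx
    assert res.f == pytest.approx(bf)
    np.testing.assert_allclose(res.f_curve, bcurve)


def test_split_range_errors():
    C = np.eye(4)
    with pytest.raises(ValueError):
        split_score(C, 0)
    with pytest.raises(ValueError):
        split_score(C, 4)
    with pytest.raises(ValueError):
        find_split(np.eye(1))


# -- SPIN sorting ------------------------------------------------------------

def _line_correlation(n, seed, scale=5.0):
    rng = np.random.default_rng(seed)
    true = rng.permutation(n)
    pos = np.empty(n)
    pos[true] = np.arange(n)
    C = np.exp(-np.abs(pos[:, None] - pos[None, :]) / scale)
    return C, pos


def test_spin_recovers_planted_1d_order():
    C, pos = _line_correlation(40, seed=0)
    sm = spin_sort(C, BackspinParams(), seed=1)
    recovered = np.empty(40)
    recovered[sm.order] = np.arange(40)
    rho = spearmanr(recovered, pos).statistic
    assert abs(rho) >= 0.95


def test_spin_energy_nonincreasing_within_each_width():
    C, _ = _line_correlation(30, seed=2)
    sm = spin_sort(C, BackspinParams(), seed=3)
    for _, energies in sm.energy_trace:
        assert all(a >= b - 1e-9 for a, b in zip(energies, energies[1:]))


def test_spin_two_items_deterministic():
    C = np.array([[1.0, 0.3], [0.3, 1.0]])
    a = spin_sort(C, seed=5).order
    b = spin_sort(C, seed=5).order
    np.testing.assert_array_equal(a, b)


def test_spin_permutation_equivariance():
    C, _ = _line_correlation(25, seed=7)
    rng = np.random.default_rng(8)
    P = rng.permutation(25)
    sm1 = spin_sort(C, BackspinParams(), seed=9)
    sm2 = spin_sort(C[np.ix_(P, P)], BackspinParams(), seed=9)
    s1 = sm1.sorted_C
    s2 = sm2.sorted_C
    same = np.allclose(s1, s2) or np.allclose(s1, s2[::-1, ::-1])
    assert same


def test_spin_rejects_asymmetric_input():
    C = np.array([[1.0, 0.5], [0.2, 1.0]])
    with pytest.raises(ValueError):
        spin_sort(C)


# -- center-of-mass gene assignment -----------------------------------------

def test_center_of_mass_left_expressed_gene_goes_left():
    A = np.zeros((1, 10))
    A[0, :4] = 5.0
    K, L = assign_genes_center_of_mass(A, x_s=4)
    assert K[0] and not L[0]


def test_center_of_mass_uniform_gene_goes_right():
    A = np.ones((1, 10))
    K, L = assign_genes_center_of_mass(A, x_s=5)  # cm = 5.5 > 5
    assert L[0]


def test_center_of_mass_scale_invariant_and_zero_gene_left():
    rng = np.random.default_rng(10)
    A = rng.poisson(2.0, size=(20, 12)).astype(float)
    A[3] = 0.0
    K1, _ = assign_genes_center_of_mass(A, 6)
    K2, _ = assign_genes_center_of_mass(A * 7.5, 6)
    np.testing.assert_array_equal(K1, K2)
    assert K1[3]


# -- recursive clustering ----------------------------------------------------

def test_backspin_recovers_planted_types(small_clustered):
    from sklearn.metrics import adjusted_rand_score

    m, truth = small_clustered
    tree = backspin(m, BackspinParams(), seed=1)
    labels = tree.leaf_labels().reindex(m.cells)
    ari = adjusted_rand_score(truth.type_of_cell.reindex(m.cells), labels)
    assert ari >= 0.9


def test_backspin_tree_invariants(small_clustered):
    m, _ = small_clustered
    tree = backspin(m, BackspinParams(), seed=1)

    def check(node):
        if node.children:
            kids_cells = sorted(node.children[0].cells + node.children[1].cells)
            assert kids_cells == sorted(node.cells)
            kids_genes = sorted(node.children[0].genes + node.children[1].genes)
            assert kids_genes == sorted(node.genes)
            assert node.depth < BackspinParams().numLevels
            for child in node.children:
                check(child)

    check(tree)
    leaf_genes = [g for leaf in tree.leaves() for g in leaf.genes]
    assert sorted(leaf_genes) == sorted(m.genes)


def test_backspin_single_type_single_leaf():
    spec = SyntheticSpec(n_genes=800, n_cells=150, n_types=1, marker_fold=1.0, seed=3)
    m, _ = make_clustered_counts(spec)
    tree = backspin(m, BackspinParams(), seed=1)
    assert len(tree.leaves()) == 1


def test_backspin_deterministic(small_clustered):
    m, _ = small_clustered
    l1 = backspin(m, BackspinParams(), seed=4).leaf_labels()
    l2 = backspin(m, BackspinParams(), seed=4).leaf_labels()
    pd.testing.assert_series_equal(l1, l2)


# -- cluster correlation summary ---------------------------------------------

def test_cluster_correlation_identical_and_disjoint_patterns():
    rng = np.random.default_rng(11)
    counts = rng.poisson(3.0, size=(20, 60))
    m = matrix = None
    from cellspin.matrix import ExpressionMatrix

    matrix = ExpressionMatrix(counts, [f"g{i}" for i in range(20)],
                              [f"c{i}" for i in range(60)])
    labels = pd.Series(["A"] * 20 + ["B"] * 20 + ["C"] * 20, index=matrix.cells)
    binary = pd.DataFrame(
        {"A": [1] * 10 + [0] * 10, "B": [1] * 10 + [0] * 10, "C": [0] * 10 + [1] * 10},
        index=matrix.genes,
    )
    S = cluster_correlation_matrix(matrix, labels, binary, seed=0)
    assert S.loc["A", "B"] == pytest.approx(1.0)
    assert S.loc["A", "C"] == pytest.approx(-1.0)
    np.testing.assert_allclose(S.to_numpy(), S.to_numpy().T)
    np.testing.assert_allclose(np.diag(S.to_numpy()), 1.0)


def test_cluster_correlation_needs_two_clusters():
    from cellspin.matrix import ExpressionMatrix

    m = ExpressionMatrix(np.ones((4, 4), dtype=int),
                         [f"g{i}" for i in range(4)], [f"c{i}" for i in range(4)])
    labels = pd.Series(["A"] * 4, index=m.cells)
    binary = pd.DataFrame({"A": [1, 0, 1, 0]}, index=m.genes)
    with pytest.raises(ValueError):
        cluster_correlation_matrix(m, labels, binary)
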