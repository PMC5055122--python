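import numpy as np
import pandas as pd
import pytest

from cellspin.prototypes import (
    WheelLayout,
    choose_regularization,
    score_cells,
    scrambled_control,
    select_training_genes,
    train_prototype_classifier,
    wheel_layout,
    _greedy_order,
)
from cellspin.synth import (
    SyntheticSpec,
    make_clustered_counts,
    mixture_weights_for_pairs,
)


@pytest.fixture(scope="module")
def reference_setup():
    spec = SyntheticSpec(n_genes=1500, n_cells=600, n_types=5, marker_fold=8.0,
                         markers_per_type=40, seed=41)
    ref, truth = make_clustered_counts(spec)
    # outgroup: a differentiation-experiment-like culture whose cells are
    # mixtures over the in-vivo types, so cell-type genes vary in it too
    rng = np.random.default_rng(42)
    w = rng.dirichlet(np.full(5, 0.5), size=150)
    outg, _ = make_clustered_counts(
        SyntheticSpec(n_genes=1500, n_cells=150, n_types=5, marker_fold=8.0,
                      markers_per_type=40, seed=42),
        mixture_weights=w,
    )
    labels = truth.type_of_cell
    panel = select_training_genes(ref, labels, outg, n_initial=1200)
    grouping = {f"T{t}": f"P{t}" for t in range(5)}
    return ref, labels, outg, panel, grouping


def test_panel_contains_planted_markers_and_halves(reference_setup):
    ref, labels, outg, panel, _ = reference_setup
    markers = {f"Gene{i:05d}" for i in range(200)}
    assert len(markers & set(panel)) >= 150
    # constant genes can never enter
    zero_var = ref.counts.var(axis=1) == 0
    assert not (set(ref.genes[zero_var]) & set(panel))


def test_panel_is_half_of_survivors(reference_setup):
    ref, labels, outg, panel, _ = reference_setup
    # re-run the first two stages to count survivors independently
    from cellspin.features import fit_noise_model, select_variable_genes
    from cellspin.matrix import ExpressionMatrix

    shared = ref.genes.intersection(outg.genes)
    combined = ExpressionMatrix(
        np.concatenate([ref.counts, outg.counts], axis=1),
        ref.genes,
        list(ref.cells) + [f"o{c}" for c in outg.cells],
    )
    model = fit_noise_model(combined)
    initial = select_variable_genes(combined, model, min(1200, len(model.residuals)))
    gi_out = outg.genes.get_indexer(initial)
    gi_comb = combined.genes.get_indexer(initial)
    var_out = outg.counts[gi_out].astype(float).var(axis=1)
    var_comb = combined.counts[gi_comb].astype(float).var(axis=1)
    survivors = (var_out >= 0.10 * np.maximum(var_comb, 1e-12)).sum()
    assert abs(len(panel) - int(np.ceil(survivors / 2))) <= 1


def test_training_separable_prototypes(reference_setup):
    ref, labels, _, panel, grouping = reference_setup
    model = train_prototype_classifier(ref, labels, grouping, panel, C=1.0, seed=0)
    probs = score_cells(model, ref)
    acc = (probs.idxmax(axis=1) == labels.map(grouping)).mean()
    assert acc == 1.0
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)


def test_small_prototype_rejected(reference_setup):
    ref, labels, _, panel, grouping = reference_setup
    bad_labels = labels.copy()
    bad_labels.iloc[:3] = "rare"
    bad_grouping = dict(grouping, rare="Prare")
    with pytest.raises(ValueError):
        train_prototype_classifier(ref, bad_labels, bad_grouping, panel)


def test_vanishing_C_gives_uniform_probabilities(reference_setup):
    ref, labels, _, panel, grouping = reference_setup
    model = train_prototype_classifier(ref, labels, grouping, panel, C=1e-8, seed=0)
    probs = score_cells(model, ref)
    assert np.allclose(probs.to_numpy(), 0.2, atol=0.01)


def test_choose_regularization_plateau(reference_setup):
    ref, labels, _, panel, grouping = reference_setup
    grid = [1e-4, 1e-2, 1.0]
    C_best, curve = choose_regularization(
        ref, labels, grouping, panel, grid, n_iters=5, seed=0
    )
    assert C_best in grid
    assert curve["accuracy"].between(0, 1).all()
    # accuracy non-decreasing up to the plateau within noise
    accs = curve["accuracy"].to_numpy()
    assert accs.argmax() >= 0 and accs[-1] >= accs[0] - 0.02
    single_C, _ = choose_regularization(
        ref, labels, grouping, panel, [0.5], n_iters=3, seed=0
    )
    assert single_C == 0.5
    with pytest.raises(ValueError):
        choose_regularization(ref, labels, grouping, panel, [1.0, 0.1], n_iters=2)


def test_scoring_missing_panel_genes_warns_and_empty_errors(reference_setup):
    ref, labels, _, panel, grouping = reference_setup
    model = train_prototype_classifier(ref, labels, grouping, panel, C=1.0, seed=0)
    reduced = ref.subset_genes(ref.genes.isin(panel[: len(panel) // 2]))
    with pytest.warns(UserWarning):
        probs = score_cells(model, reduced)
    assert np.allclose(probs.sum(axis=1), 1.0)
    no_overlap = ref.subset_genes(~ref.genes.isin(panel))
    with pytest.raises(ValueError):
        score_cells(model, no_overlap)


# -- wheel geometry ----------------------------------------------------------

def test_wheel_one_hot_lands_on_vertex_uniform_in_center():
    P = pd.DataFrame(np.vstack([np.eye(5)[0], np.full(5, 0.2)]),
                     columns=[f"P{i}" for i in range(5)])
    coords, layout = wheel_layout(P)
    radii = np.linalg.norm(coords.to_numpy(), axis=1)
    assert radii[0] == pytest.approx(1.0, abs=1e-12)
    assert radii[1] == pytest.approx(0.0, abs=1e-12)


def test_wheel_positions_inside_unit_disk():
    rng = np.random.default_rng(0)
    P = rng.dirichlet(np.ones(6), size=200)
    coords, _ = wheel_layout(pd.DataFrame(P, columns=[f"P{i}" for i in range(6)]))
    assert (np.linalg.norm(coords.to_numpy(), axis=1) <= 1.0 + 1e-12).all()


def test_wheel_rejects_off_simplex_rows():
    with pytest.raises(ValueError):
        wheel_layout(pd.DataFrame([[0.5, 0.2]], columns=["a", "b"]))


def test_wheel_order_minimizes_central_cells():
    # cells confused between two prototypes spread along an edge when the
    # pair is adjacent, but cross the center when the pair sits opposite
    rng = np.random.default_rng(1)
    w = rng.uniform(0.3, 0.7, 100)
    P = np.zeros((100, 4))
    P[:, 0], P[:, 2] = w, 1 - w
    coords, layout = wheel_layout(pd.DataFrame(P, columns=list("abcd")))
    order = layout.vertex_order
    ia, ic = order.index("a"), order.index("c")
    assert min((ia - ic) % 4, (ic - ia) % 4) == 1  # adjacent
    assert (np.linalg.norm(coords.to_numpy(), axis=1) > layout.central_radius).all()


def test_greedy_order_agrees_with_exhaustive_for_small_k():
    # the objective is the number of cells in the central area; the
    # greedy adjacency heuristic must match the exhaustive optimum on
    # pairwise-confused data, and place the confused pair adjacent
    from cellspin.prototypes import _central_count, _unit_vectors

    rng = np.random.default_rng(2)
    U = _unit_vectors(5)
    for trial in range(5):
        w = rng.uniform(0.25, 0.75, 150)
        pair = rng.choice(5, size=2, replace=False)
        P = np.full((150, 5), 0.08)
        P[:, pair[0]], P[:, pair[1]] = w, 1 - w
        P /= P.sum(axis=1, keepdims=True)
        df = pd.DataFrame(P, columns=[f"P{i}" for i in range(5)])
        _, lay_ex = wheel_layout(df, exhaustive_max=8)
        _, lay_gr = wheel_layout(df, exhaustive_max=2)
        names = list(df.columns)
        counts = {}
        for tag, lay in (("ex", lay_ex), ("gr", lay_gr)):
            order = tuple(names.index(v) for v in lay.vertex_order)
            counts[tag] = _central_count(P, order, U, 0.2)
        assert counts["gr"] == counts["ex"]
        i = lay_gr.vertex_order.index(f"P{pair[0]}")
        j = lay_gr.vertex_order.index(f"P{pair[1]}")
        assert min((i - j) % 5, (j - i) % 5) == 1


def test_scrambled_control_properties(reference_setup):
    ref, labels, _, panel, grouping = reference_setup
    model = train_prototype_classifier(ref, labels, grouping, panel, C=1.0, seed=0)
    s1 = scrambled_control(ref, model, seed=0)
    s2 = scrambled_control(ref, model, seed=0)
    s3 = scrambled_control(ref, model, seed=1)
    pd.testing.assert_frame_equal(s1, s2)
    assert not s1.equals(s3)
    assert np.allclose(s1.sum(axis=1), 1.0, atol=1e-9)


def test_scrambling_preserves_cell_totals(reference_setup):
    ref, labels, _, panel, grouping = reference_setup
    import numpy as np
    from cellspin.matrix import ExpressionMatrix

    rng = np.random.default_rng(0)
    counts = ref.counts.copy()
    for j in range(counts.shape[1]):
        counts[:, j] = counts[rng.permutation(counts.shape[0]), j]
    np.testing.assert_array_equal(counts.sum(axis=0), ref.counts.sum(axis=0))


def test_mixture_cells_land_between_their_vertices():
    spec = SyntheticSpec(n_genes=1000, n_cells=1000, n_types=4, marker_fold=8.0,
                         markers_per_type=30, gene_mean_cv=0.0, libsize_cv=0.0,
                         seed=50)
    ref, truth = make_clustered_counts(spec)
    outg, _ = make_clustered_counts(
        SyntheticSpec(n_genes=1000, n_cells=200, n_types=1, seed=51,
                      gene_mean_cv=0.0, libsize_cv=0.0)
    )
    panel = select_training_genes(ref, truth.type_of_cell, outg, n_initial=800)
    grouping = {f"T{t}": f"P{t}" for t in range(4)}
    model = train_prototype_classifier(ref, truth.type_of_cell, grouping, panel,
                                       C=1.0, seed=0)
    w = mixture_weights_for_pairs(40, 4, [(1, 2)])
    q, _ = make_clustered_counts(
        SyntheticSpec(n_genes=1000, n_cells=40, n_types=4, marker_fold=8.0,
                      markers_per_type=30, gene_mean_cv=0.0, libsize_cv=0.0,
                      seed=52),
        mixture_weights=w,
    )
    probs = score_cells(model, q)
    # dominant mass on the two source prototypes
    assert (probs["P1"] + probs["P2"]).mean() > 0.8
    coords, layout = wheel_layout(score_cells(model, ref))
    order_idx = [list(probs.columns).index(v) for v in layout.vertex_order]
    pos = probs.to_numpy()[:, order_idx] @ layout.unit_vectors
    u1 = layout.unit_vectors[layout.vertex_order.index("P1")]
    u2 = layout.unit_vectors[layout.vertex_order.index("P2")]
    lo, hi = sorted([np.arctan2(*u1[::-1]), np.arctan2(*u2[::-1])])
    ang = np.arctan2(pos[:, 1], pos[:, 0])
    within = ((ang >= lo - 0.2) & (ang <= hi + 0.2)).mean()
    if hi - lo <= np.pi:  # arc does not wrap
        assert within >= 0.9
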