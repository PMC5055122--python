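import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from cellspin.pseudotime import (
    cluster_profiles,
    fit_principal_curve,
    fit_principal_curve_pseudotime,
    fit_pseudotime_profiles,
    nb_lrt_categorical,
    profile_direction,
    select_time_varying_genes,
)
from cellspin.synth import SyntheticSpec, make_trajectory


@pytest.fixture(scope="module")
def trajectory_data():
    spec = SyntheticSpec(n_genes=2000, n_cells=500, n_types=1, marker_fold=10.0,
                         seed=21)
    return make_trajectory(spec, n_dynamic_genes=50)


@pytest.fixture(scope="module")
def clean_trajectory():
    """Well-expressed, low-noise up/down genes for profile work."""
    spec = SyntheticSpec(n_genes=500, n_cells=300, n_types=1, base_mean=3.0,
                         marker_fold=8.0, dispersion=0.05, gene_mean_cv=0.5, seed=30)
    return make_trajectory(spec, n_dynamic_genes=40,
                           shapes=("monotone-up", "monotone-down"))


def test_lrt_selects_dynamic_genes_controls_false_positives(trajectory_data):
    m, truth = trajectory_data
    selected = select_time_varying_genes(m, m.cell_meta["age"], n_top=2000)
    dynamic = {f"Gene{i:05d}" for i in range(50)}
    assert len(dynamic & set(selected)) >= 45
    false = set(selected) - dynamic
    assert len(false) <= 0.01 * (2000 - 50)


def test_lrt_null_calibration():
    rng = np.random.default_rng(0)
    groups = np.repeat([11, 12, 13, 14], 50)
    pvals = [
        nb_lrt_categorical(rng.poisson(2.0, 200), groups) for _ in range(200)
    ]
    # uniform-ish p-values under the null: 5% band at alpha=0.05 has
    # binomial SE ~1.5%, allow a generous margin
    assert np.mean(np.array(pvals) < 0.05) < 0.12


def test_exclusion_set_never_returned(trajectory_data):
    m, _ = trajectory_data
    excl = [f"Gene{i:05d}" for i in range(0, 50, 2)]
    selected = select_time_varying_genes(
        m, m.cell_meta["age"], exclusion_set=excl, n_top=2000
    )
    assert not (set(excl) & set(selected))


def test_null_trajectory_selects_nothing():
    empty = 0
    for s in range(10):
        spec = SyntheticSpec(n_genes=400, n_cells=200, n_types=1, seed=100 + s)
        m, _ = make_trajectory(spec, n_dynamic_genes=0)
        sel = select_time_varying_genes(m, m.cell_meta["age"], n_top=400)
        empty += len(sel) == 0
    assert empty >= 9


def test_principal_curve_collinear_data_is_exact():
    t = np.linspace(0, 1, 100)
    direction = np.array([2.0, -1.0, 0.5])
    Y = np.outer(t, direction)
    arc, _, _ = fit_principal_curve(Y)
    r = np.corrcoef(arc, t)[0, 1]
    assert abs(r) >= 1 - 1e-9


def test_pseudotime_recovers_latent_time(trajectory_data):
    m, truth = trajectory_data
    genes = select_time_varying_genes(m, m.cell_meta["age"], n_top=2000)
    fit = fit_principal_curve_pseudotime(m, genes, ages=m.cell_meta["age"])
    rho = spearmanr(fit.pseudotime, truth.latent_time.reindex(m.cells)).statistic
    assert abs(rho) >= 0.9
    assert (fit.pseudotime >= 0).all()
    # orientation anchored to age: positive correlation
    assert np.corrcoef(fit.pseudotime, m.cell_meta["age"])[0, 1] > 0


def test_pseudotime_invariant_to_cell_duplication(clean_trajectory):
    m, truth = clean_trajectory
    genes = [f"Gene{i:05d}" for i in range(40)]
    fit1 = fit_principal_curve_pseudotime(m, genes, ages=m.cell_meta["age"])
    from cellspin.matrix import ExpressionMatrix

    dup = ExpressionMatrix(
        np.concatenate([m.counts, m.counts], axis=1),
        m.genes,
        list(m.cells) + [f"{c}_dup" for c in m.cells],
        pd.concat([m.cell_meta,
                   m.cell_meta.set_index(m.cell_meta.index + "_dup")]),
    )
    fit2 = fit_principal_curve_pseudotime(dup, genes, ages=dup.cell_meta["age"])
    rho = spearmanr(
        fit1.pseudotime.to_numpy(), fit2.pseudotime.iloc[: m.n_cells].to_numpy()
    ).statistic
    assert abs(rho) >= 0.98


def test_profiles_noiseless_monotone_gene_high_r2():
    rng = np.random.default_rng(1)
    t = rng.uniform(0, 1, 300)
    # a large constant background keeps library sizes flat, so depth
    # normalization leaves the deterministic gene untouched
    counts = np.vstack([
        np.round(200 * t).astype(int),  # deterministic monotone gene
        np.full((50, 300), 100),
    ])
    from cellspin.matrix import ExpressionMatrix

    m = ExpressionMatrix(counts, ["mono"] + [f"bg{i}" for i in range(50)],
                         [f"c{i}" for i in range(300)])
    from cellspin.pseudotime import PseudotimeFit

    fit = PseudotimeFit(
        genes=["mono"], pc_sds=np.array([1.0, 1.0]), n_pcs=2,
        curve_points=np.zeros((2, 2)),
        pseudotime=pd.Series(t, index=m.cells), converged=True,
    )
    fit = fit_pseudotime_profiles(fit, m, genes=["mono"], impute=False, seed=0)
    assert fit.r2["mono"] >= 0.99


def test_flat_genes_rarely_pass_r2_cut(clean_trajectory):
    m, _ = clean_trajectory
    genes = [f"Gene{i:05d}" for i in range(40)]
    flat = [f"Gene{i:05d}" for i in range(100, 140)]
    fit = fit_principal_curve_pseudotime(m, genes, ages=m.cell_meta["age"])
    fit = fit_pseudotime_profiles(fit, m, genes=flat, seed=0)
    assert (fit.r2 >= 0.35).mean() <= 0.05


def test_profiles_invariant_to_cell_permutation(clean_trajectory):
    m, _ = clean_trajectory
    genes = [f"Gene{i:05d}" for i in range(5)]
    fit = fit_principal_curve_pseudotime(m, [f"Gene{i:05d}" for i in range(40)],
                                         ages=m.cell_meta["age"])
    f1 = fit_pseudotime_profiles(fit, m, genes=genes, impute=False, seed=0)
    p1 = f1.profiles.copy()
    perm = np.random.default_rng(3).permutation(m.n_cells)
    m_perm = m.subset_cells(perm)
    fit.pseudotime = fit.pseudotime  # same mapping cell -> time
    f2 = fit_pseudotime_profiles(fit, m_perm, genes=genes, impute=False, seed=0)
    np.testing.assert_allclose(p1.to_numpy(), f2.profiles.to_numpy(), atol=1e-8)


def test_cluster_profiles_separates_planted_shapes(clean_trajectory):
    m, truth = clean_trajectory
    genes = [f"Gene{i:05d}" for i in range(40)]
    fit = fit_principal_curve_pseudotime(m, genes, ages=m.cell_meta["age"])
    fit = fit_pseudotime_profiles(fit, m, genes=genes, seed=0)
    labels, exemplars = cluster_profiles(fit)
    shape = truth.mean_matrix["shape"]
    truth_labels = [0 if shape[g] == "monotone-up" else 1 for g in labels.index]
    assert adjusted_rand_score(truth_labels, labels.to_numpy()) == 1.0
    assert len(exemplars) == labels.nunique()


def test_cluster_profiles_shift_invariance_and_single_gene(clean_trajectory):
    m, _ = clean_trajectory
    genes = [f"Gene{i:05d}" for i in range(40)]
    fit = fit_principal_curve_pseudotime(m, genes, ages=m.cell_meta["age"])
    fit = fit_pseudotime_profiles(fit, m, genes=genes, seed=0)
    labels1, _ = cluster_profiles(fit, seed=0)
    fit.profiles = fit.profiles + 100.0  # constant offset
    labels2, _ = cluster_profiles(fit, seed=0)
    pd.testing.assert_series_equal(labels1, labels2)
    # single passing gene forms its own cluster
    fit.r2 = pd.Series({g: 0.0 for g in fit.r2.index})
    fit.r2.iloc[0] = 0.9
    labels3, ex3 = cluster_profiles(fit)
    assert len(labels3) == 1 and len(ex3) == 1


def test_up_only_simulation_has_no_downregulated_calls():
    spec = SyntheticSpec(n_genes=300, n_cells=300, n_types=1, base_mean=3.0,
                         marker_fold=8.0, dispersion=0.05, gene_mean_cv=0.5, seed=31)
    m, _ = make_trajectory(spec, n_dynamic_genes=30, shapes=("monotone-up",))
    genes = [f"Gene{i:05d}" for i in range(30)]
    fit = fit_principal_curve_pseudotime(m, genes, ages=m.cell_meta["age"])
    fit = fit_pseudotime_profiles(fit, m, genes=genes, seed=0)
    passing = fit.r2[fit.r2 >= 0.35].index
    directions = [profile_direction(fit.profiles.loc[g].to_numpy()) for g in passing]
    assert len(passing) >= 20
    assert directions.count("down") == 0
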