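"""Synthetic UMI-count generators with known ground truth.

Every downstream stage of the pipeline assumes a specific statistical
structure in the data: negative-binomially distributed molecule counts
with cell-type-specific means and per-cell library-size variation, a
correlated cell-cycle module active in a subpopulation, genes varying
smoothly along a latent maturation axis, two species sharing homologous
genes with planted cluster correspondences, and in-vitro-like cells that
are convex mixtures of reference profiles.  The generators here plant
each of those structures explicitly and return a :class:`GroundTruth`
sufficient to verify every downstream result without re-reading
generator internals.

Counts are drawn from a negative binomial parameterized by mean ``mu``
and overdispersion ``phi`` with ``variance = mu + phi * mu**2`` (the
mean/dispersion form; ``phi -> 0`` recovers Poisson).  Per-cell library
size factors are log-normal with unit mean and the requested coefficient
of variation: strictly positive with a heavy-ish right tail, like real
UMI depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

TRAJECTORY_SHAPES = ("monotone-up", "monotone-down", "transient")


@dataclass
class SyntheticSpec:
    """Parameters of the clustered-count generator.

    ``base_mean`` is the median expected molecules/cell of a background
    gene; per-gene base means are drawn log-normal around it with
    coefficient of variation ``gene_mean_cv`` (real UMI data spans
    orders of magnitude in gene mean, and the CV-vs-mean noise model
    downstream presumes that continuum; set 0 for a flat mean profile).
    Markers of a type have mean ``fold x`` their own base in that type.
    ``libsize_cv`` is the coefficient of variation of the per-cell
    library-size factor; ``dispersion`` is ``phi`` in
    ``var = mu + phi mu^2``.
    """

    n_genes: int = 1000
    n_cells: int = 500
    n_types: int = 5
    base_mean: float = 0.5
    marker_fold: float = 10.0
    markers_per_type: int = 20
    libsize_cv: float = 0.3
    dispersion: float = 0.5
    gene_mean_cv: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_cells", "n_types", "markers_per_type"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        for name, lo in (("base_mean", 0.0), ("marker_fold", 1.0),
                         ("libsize_cv", 0.0), ("dispersion", 0.0),
                         ("gene_mean_cv", 0.0)):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < lo or (name == "base_mean" and v <= 0):
                raise ValueError(f"{name} must be finite and >= {lo}, got {v!r}")
        if self.n_types * self.markers_per_type > self.n_genes:
            raise ValueError("marker panels exceed the gene count")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset."""

    type_of_cell: pd.Series = None  # cell -> type label
    mean_matrix: pd.DataFrame = None  # genes x types expected molecules/cell
    cycling_flags: pd.Series = None  # cell -> bool
    latent_time: pd.Series = None  # cell -> float in [0, 1]
    homolog_map: pd.DataFrame = None  # columns gene_a, gene_b (one-to-one)
    planted_matches: list = field(default_factory=list)  # (type_a, type_b)
    libsize_factors: pd.Series = None  # cell -> positive scale factor

    def to_json(self, path) -> None:
        def ser(obj):
            if isinstance(obj, pd.Series):
                return obj.to_dict()
            if isinstance(obj, pd.DataFrame):
                return obj.to_dict()
            return obj

        payload = {k: ser(v) for k, v in self.__dict__.items()}
        Path(path).write_text(json.dumps(payload, default=str, indent=1))


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB draw with var = mu + phi mu^2; Poisson in the phi -> 0 limit."""
    mean = np.asarray(mean, dtype=float)
    if phi < 1e-12:
        return rng.poisson(mean)
    r = 1.0 / phi
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    # gamma-Poisson mixture: lambda ~ Gamma(r, scale=mu/r), y ~ Poisson(lambda)
    lam = rng.gamma(r, mean[pos] / r)
    out[pos] = rng.poisson(lam)
    return out


def _libsize_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    if cv <= 0:
        return np.ones(n)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)


def _marker_blocks(spec: SyntheticSpec) -> list[np.ndarray]:
    """Deterministic contiguous marker blocks, one per type, disjoint."""
    return [
        np.arange(t * spec.markers_per_type, (t + 1) * spec.markers_per_type)
        for t in range(spec.n_types)
    ]


def _base_means(spec: SyntheticSpec) -> np.ndarray:
    """Per-gene base means: log-normal with median base_mean, CV gene_mean_cv.

    Drawn from a dedicated substream of the spec seed so the mean matrix
    is deterministic and shared by every generator built on this spec.
    """
    if spec.gene_mean_cv <= 0:
        return np.full(spec.n_genes, spec.base_mean)
    sigma = np.sqrt(np.log1p(spec.gene_mean_cv**2))
    rng = np.random.default_rng([spec.seed, 17])
    return spec.base_mean * rng.lognormal(mean=0.0, sigma=sigma, size=spec.n_genes)


def _mean_matrix(spec: SyntheticSpec) -> np.ndarray:
    base = _base_means(spec)
    mm = np.tile(base[:, None], (1, spec.n_types))
    for t, block in enumerate(_marker_blocks(spec)):
        mm[block, t] = base[block] * spec.marker_fold
    return mm


def _gene_ids(n: int, prefix: str = "Gene") -> pd.Index:
    return pd.Index([f"{prefix}{i:05d}" for i in range(n)])


def _cell_ids(n: int, prefix: str = "Cell") -> pd.Index:
    return pd.Index([f"{prefix}{i:05d}" for i in range(n)])


def make_clustered_counts(
    spec: SyntheticSpec,
    mixture_weights: np.ndarray | None = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate NB counts for cells drawn from discrete types.

    Cells are split evenly over ``spec.n_types`` types, each with a
    disjoint block of ``markers_per_type`` marker genes at
    ``marker_fold`` times the background mean.  If ``mixture_weights``
    (``n_cells x n_types``, rows on the simplex) is given, each cell's
    expected profile is the convex mixture of the type means — the
    "intermediate identity" structure of stem-cell-derived cells.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mm = _mean_matrix(spec)
    if mixture_weights is not None:
        w = np.asarray(mixture_weights, dtype=float)
        if w.shape != (spec.n_cells, spec.n_types):
            raise ValueError("mixture_weights must be n_cells x n_types")
        if np.any(w < 0) or np.any(np.abs(w.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("mixture_weights rows must be convex weights")
        type_label = np.array([f"T{np.argmax(row)}" for row in w])
    else:
        types = np.repeat(np.arange(spec.n_types), _even_split(spec.n_cells, spec.n_types))
        w = np.eye(spec.n_types)[types]
        type_label = np.array([f"T{t}" for t in types])

    lib = _libsize_factors(rng, spec.n_cells, spec.libsize_cv)
    mu = (mm @ w.T) * lib[None, :]  # genes x cells
    counts = _nb_sample(rng, mu, spec.dispersion)

    genes, cells = _gene_ids(spec.n_genes), _cell_ids(spec.n_cells)
    meta = pd.DataFrame({"type": type_label}, index=cells)
    matrix = ExpressionMatrix(counts, genes, cells, meta)
    truth = GroundTruth(
        type_of_cell=pd.Series(type_label, index=cells),
        mean_matrix=pd.DataFrame(mm, index=genes,
                                 columns=[f"T{t}" for t in range(spec.n_types)]),
        cycling_flags=pd.Series(False, index=cells),
        libsize_factors=pd.Series(lib, index=cells),
    )
    return matrix, truth


def _even_split(n: int, k: int) -> np.ndarray:
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    return sizes


def make_species_pair(
    spec: SyntheticSpec,
    n_shared_types: int,
    divergence: float,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Two homologous datasets with planted cell-type correspondences.

    Both "species" carry ``spec.n_types`` types over homologous gene
    panels; the first ``n_shared_types`` types correspond one-to-one.
    In log-mean space the matched type of species B is the convex blend
    ``(1 - divergence) * logm_A + divergence * eps`` with ``eps`` an
    independent redraw, so matched mean vectors correlate perfectly at
    ``divergence = 0`` and decorrelate as it grows.
    """
    spec.validate()
    if not (0.0 <= divergence <= 1.0):
        raise ValueError(f"divergence must lie in [0, 1], got {divergence}")
    if n_shared_types > spec.n_types:
        raise ValueError("n_shared_types exceeds n_types")
    rng = np.random.default_rng(spec.seed)

    log_a = np.log(_mean_matrix(spec))
    # independent alternative profile: same marginal structure, shuffled blocks
    alt_spec = SyntheticSpec(**{**asdict(spec), "seed": spec.seed + 1})
    log_eps = np.log(_mean_matrix(alt_spec))
    perm = rng.permutation(spec.n_genes)
    log_eps = log_eps[perm]

    log_b = log_a.copy()
    shared = np.arange(n_shared_types)
    log_b[:, shared] = (1 - divergence) * log_a[:, shared] + divergence * log_eps[:, shared]
    # non-shared types of B get their own marker blocks, displaced
    base = _base_means(spec)
    for t in range(n_shared_types, spec.n_types):
        log_b[:, t] = np.log(base)
        block = (np.arange(spec.markers_per_type)
                 + (t * spec.markers_per_type + spec.n_genes // 2)) % spec.n_genes
        log_b[block, t] = np.log(base[block] * spec.marker_fold)

    def _draw(logm: np.ndarray, seed: int, gene_prefix: str, cell_prefix: str):
        sub = np.random.default_rng(seed)
        types = np.repeat(np.arange(spec.n_types), _even_split(spec.n_cells, spec.n_types))
        lib = _libsize_factors(sub, spec.n_cells, spec.libsize_cv)
        mu = np.exp(logm)[:, types] * lib[None, :]
        counts = _nb_sample(sub, mu, spec.dispersion)
        genes = _gene_ids(spec.n_genes, gene_prefix)
        cells = _cell_ids(spec.n_cells, cell_prefix)
        meta = pd.DataFrame({"type": [f"T{t}" for t in types]}, index=cells)
        return ExpressionMatrix(counts, genes, cells, meta), types

    mat_a, _ = _draw(log_a, spec.seed + 10, "GA", "CA")
    mat_b, _ = _draw(log_b, spec.seed + 11, "GB", "CB")

    homologs = pd.DataFrame({"gene_a": mat_a.genes, "gene_b": mat_b.genes})
    truth = GroundTruth(
        type_of_cell=pd.concat(
            [mat_a.cell_meta["type"], mat_b.cell_meta["type"]]
        ),
        mean_matrix=pd.DataFrame(np.exp(log_a), index=mat_a.genes,
                                 columns=[f"T{t}" for t in range(spec.n_types)]),
        homolog_map=homologs,
        planted_matches=[(f"T{t}", f"T{t}") for t in shared],
    )
    return mat_a, mat_b, truth


def _shape_curve(shape: str, t: np.ndarray, low: float, high: float) -> np.ndarray:
    if shape == "monotone-up":
        return low + (high - low) * t
    if shape == "monotone-down":
        return high - (high - low) * t
    if shape == "transient":
        return low + (high - low) * np.exp(-((t - 0.5) ** 2) / (2 * 0.15**2))
    raise ValueError(f"unknown trajectory shape {shape!r}")


def make_trajectory(
    spec: SyntheticSpec,
    n_dynamic_genes: int,
    shapes: Sequence[str] = TRAJECTORY_SHAPES,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Cells along a latent [0, 1] maturation axis.

    Dynamic genes follow the requested smooth shapes of latent time
    (linear up/down, or a Gaussian bump peaking at t = 0.5); the rest
    are flat at ``base_mean``.  Cells also carry a discretized "age"
    column (latent time binned into 4 stages), emulating the embryonic
    sampling day available for real cells.
    """
    spec.validate()
    shapes = list(shapes)
    if not shapes:
        raise ValueError("shapes must be a non-empty set of trajectory shapes")
    for s in shapes:
        if s not in TRAJECTORY_SHAPES:
            raise ValueError(f"unknown trajectory shape {s!r}")
    if n_dynamic_genes > spec.n_genes:
        raise ValueError("n_dynamic_genes exceeds n_genes")
    rng = np.random.default_rng(spec.seed)

    t = rng.uniform(0.0, 1.0, size=spec.n_cells)
    base = _base_means(spec)
    mu = np.tile(base[:, None], (1, spec.n_cells))
    gene_shape = {}
    for g in range(n_dynamic_genes):
        s = shapes[g % len(shapes)]
        gene_shape[g] = s
        mu[g] = _shape_curve(s, t, base[g], base[g] * spec.marker_fold)

    lib = _libsize_factors(rng, spec.n_cells, spec.libsize_cv)
    counts = _nb_sample(rng, mu * lib[None, :], spec.dispersion)

    genes, cells = _gene_ids(spec.n_genes), _cell_ids(spec.n_cells)
    age = np.digitize(t, [0.25, 0.5, 0.75]) + 11.0  # pseudo E-days 11..14
    meta = pd.DataFrame({"age": age, "latent_time": t}, index=cells)
    matrix = ExpressionMatrix(counts, genes, cells, meta)
    truth = GroundTruth(
        type_of_cell=pd.Series("T0", index=cells),
        latent_time=pd.Series(t, index=cells),
        cycling_flags=pd.Series(False, index=cells),
        libsize_factors=pd.Series(lib, index=cells),
        mean_matrix=pd.DataFrame(
            {"shape": pd.Series({genes[g]: s for g, s in gene_shape.items()})}
        ),
    )
    return matrix, truth


def add_cycle_module(
    matrix: ExpressionMatrix,
    truth: GroundTruth,
    cycle_genes: Iterable[str],
    frac_cycling: float,
    fold: float,
    seed: int = 0,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Plant a correlated cell-cycle module in a random subpopulation.

    A ``frac_cycling`` fraction of cells is flagged as cycling and its
    cycle-gene counts are redrawn from the NB law with the mean
    multiplied by ``fold``; the module is therefore co-activated (and
    hence mutually correlated) across exactly the flagged cells.
    """
    cycle_genes = list(cycle_genes)
    missing = set(cycle_genes) - set(matrix.genes)
    if missing:
        raise ValueError(f"cycle genes not in matrix: {sorted(missing)[:5]}")
    if not (0.0 <= frac_cycling <= 1.0):
        raise ValueError("frac_cycling must lie in [0, 1]")
    if fold < 1.0:
        raise ValueError("fold must be >= 1")
    rng = np.random.default_rng(seed)

    n_cyc = int(round(frac_cycling * matrix.n_cells))
    flagged = np.zeros(matrix.n_cells, dtype=bool)
    flagged[rng.choice(matrix.n_cells, size=n_cyc, replace=False)] = True

    counts = matrix.counts.copy()
    gi = matrix.genes.get_indexer(cycle_genes)
    if n_cyc and fold > 1.0:
        lib = (truth.libsize_factors.to_numpy()
               if truth.libsize_factors is not None else np.ones(matrix.n_cells))
        base = np.maximum(counts[np.ix_(gi, ~flagged)].mean(axis=1), 0.05)
        mu = fold * base[:, None] * lib[flagged][None, :]
        counts[np.ix_(gi, flagged)] = _nb_sample(rng, mu, 0.5)

    out = ExpressionMatrix(counts, matrix.genes, matrix.cells, matrix.cell_meta)
    new_truth = GroundTruth(**{**truth.__dict__})
    new_truth.cycling_flags = pd.Series(flagged, index=matrix.cells)
    return out, new_truth


def mixture_weights_for_pairs(
    n_cells: int, n_types: int, pairs: Sequence[tuple[int, int]],
    alpha: float = 0.5, rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Convex per-cell weights mixing each of the given type pairs.

    Helper for building "in vitro"-like query cells: each cell mixes one
    pair ``(a, b)`` with weight ``w`` on ``a`` drawn Beta(alpha, alpha)
    (or exactly 0.5 when ``rng`` is None).
    """
    w = np.zeros((n_cells, n_types))
    rng_ = rng
    for i in range(n_cells):
        a, b = pairs[i % len(pairs)]
        u = 0.5 if rng_ is None else float(rng_.beta(alpha, alpha))
        w[i, a], w[i, b] = u, 1.0 - u
    return w
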