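"""Cross-species cell-type matching and developmental-timing comparison.

Cell types of two species are compared in the shared feature space of
one-to-one homologous genes, using the per-cluster MAP expression
profiles from the marker model.  A naive transcriptome-wide correlation
is biased toward uniformly high similarity, so the gene panel is first
restricted to homolog pairs with significant, selective variation
across cell types; Pearson correlation over that panel gives the
similarity matrix, and a pair of types corresponds when each is the
other's best match (a mutual row/column maximum).

Developmental timing of a cell type is summarized by its half-sampling
time: a smooth density is fit to the per-cell sampling ages and the
age at which the cumulative area reaches half of the total is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import gaussian_kde


@dataclass
class SimilarityMatrix:
    S: pd.DataFrame  # types of A (rows) x types of B (columns)
    gene_pairs: list  # (gene_a, gene_b) panel used
    undefined: list = field(default_factory=list)  # entries with constant profile


def filter_comparison_genes(
    map_a: pd.DataFrame,
    map_b: pd.DataFrame,
    bin_a: pd.DataFrame,
    bin_b: pd.DataFrame,
    homologs: pd.DataFrame,
    max_sig_types: int = 6,
    max_expr_floor: float = 1.5,
    min_expr_ceiling: float = 0.25,
) -> tuple[list, dict]:
    """Homolog pairs carrying selective cross-cluster signal.

    A pair (gene_a, gene_b) is kept when:
      1. significant (binarized 1) in >= 1 cluster in BOTH species,
      2. significant in fewer than ``max_sig_types`` clusters in at
         least one species,
      3. within at least one species, the MAP expression profile spans
         a real dynamic range: max > ``max_expr_floor`` molecules/cell
         and min < ``min_expr_ceiling``.

    Homolog rows that are not one-to-one are dropped and counted in the
    returned report.
    """
    h = homologs[["gene_a", "gene_b"]].dropna()
    dup = h["gene_a"].duplicated(keep=False) | h["gene_b"].duplicated(keep=False)
    report = {"non_bijective_dropped": int(dup.sum())}
    h = h[~dup]

    kept = []
    for ga, gb in h.itertuples(index=False):
        if ga not in bin_a.index or gb not in bin_b.index:
            continue
        if ga not in map_a.index or gb not in map_b.index:
            continue
        sig_a = int(bin_a.loc[ga].sum())
        sig_b = int(bin_b.loc[gb].sum())
        if sig_a < 1 or sig_b < 1:
            continue
        if not (sig_a < max_sig_types or sig_b < max_sig_types):
            continue
        pa, pb = map_a.loc[ga], map_b.loc[gb]
        range_a = pa.max() > max_expr_floor and pa.min() < min_expr_ceiling
        range_b = pb.max() > max_expr_floor and pb.min() < min_expr_ceiling
        if not (range_a or range_b):
            continue
        kept.append((ga, gb))
    report["kept"] = len(kept)
    return kept, report


def similarity_matrix(
    map_a: pd.DataFrame, map_b: pd.DataFrame, gene_pairs: list
) -> SimilarityMatrix:
    """Pearson correlation between every cluster pair over the panel."""
    if len(gene_pairs) < 10:
        raise ValueError("need at least 10 homolog pairs for a stable similarity")
    genes_a = [p[0] for p in gene_pairs]
    genes_b = [p[1] for p in gene_pairs]
    A = map_a.loc[genes_a].to_numpy(dtype=float)
    B = map_b.loc[genes_b].to_numpy(dtype=float)
    S = pd.DataFrame(index=map_a.columns, columns=map_b.columns, dtype=float)
    undefined = []
    for i, ta in enumerate(map_a.columns):
        for j, tb in enumerate(map_b.columns):
            a, b = A[:, i], B[:, j]
            if a.std() == 0 or b.std() == 0:
                undefined.append((ta, tb))
                continue
            S.loc[ta, tb] = float(np.corrcoef(a, b)[0, 1])
    return SimilarityMatrix(S=S, gene_pairs=list(gene_pairs), undefined=undefined)


def mutual_best_matches(sim: SimilarityMatrix | pd.DataFrame) -> list:
    """(type_a, type_b) pairs that are the maximum of both row and column.

    Ties yield multiple pairs, all reported.
    """
    S = sim.S if isinstance(sim, SimilarityMatrix) else sim
    vals = S.to_numpy(dtype=float)
    pairs = []
    with np.errstate(invalid="ignore"):
        row_max = np.nanmax(vals, axis=1)
        col_max = np.nanmax(vals, axis=0)
    for i, ta in enumerate(S.index):
        for j, tb in enumerate(S.columns):
            v = vals[i, j]
            if np.isnan(v):
                continue
            if v >= row_max[i] and v >= col_max[j]:
                pairs.append((ta, tb))
    return pairs


def half_sampling_time(
    ages, bandwidth: str | float = "scott", ci_bootstrap: int = 0, seed: int = 0
) -> float | tuple[float, tuple[float, float]]:
    """Age at which half of a cluster's cells have been sampled.

    Fits a Gaussian kernel density to the per-cell ages (bandwidth by
    the standard Scott rule unless overridden) and locates the point
    where the cumulative area reaches half of the total, by bisection.
    With ``ci_bootstrap > 0`` a percentile bootstrap CI is attached.
    """
    ages = np.asarray(ages, dtype=float)
    if len(ages) < 5:
        raise ValueError("need at least 5 cells with ages")
    if np.ptp(ages) == 0:
        t_star = float(ages[0])
        return (t_star, (t_star, t_star)) if ci_bootstrap else t_star

    def _half(a: np.ndarray) -> float:
        kde = gaussian_kde(a, bw_method=bandwidth)
        span = 4 * a.std()
        lo, hi = a.min() - span, a.max() + span
        total = kde.integrate_box_1d(lo, hi)
        return brentq(lambda t: kde.integrate_box_1d(lo, t) - total / 2.0, lo, hi)

    t_star = float(_half(ages))
    if not ci_bootstrap:
        return t_star
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(ci_bootstrap):
        resampled = rng.choice(ages, size=len(ages), replace=True)
        if np.ptp(resampled) == 0:
            boots.append(float(resampled[0]))
        else:
            boots.append(float(_half(resampled)))
    lo_ci, hi_ci = np.percentile(boots, [2.5, 97.5])
    return t_star, (float(lo_ci), float(hi_ci))
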