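# cellspin

A tested re-implementation of the computational pipeline used to chart
cell types in developing ventral-midbrain tissue from single-cell UMI
counts: recursive SPIN biclustering (BackSPIN), Bayesian
negative-binomial marker detection and binarization, cross-species
cell-type matching, a learned proliferation index, principal-curve
pseudotime, and prototype-based probabilistic scoring of stem-cell-
derived cells.  A synthetic-data module generates count matrices with
planted ground truth for every structure the pipeline assumes, so the
whole chain is testable without any data download.

It is written for computational biologists who want these methods as an
importable, seeded, reproducible library rather than a collection of
notebooks.

## The methods in brief

**BackSPIN biclustering.**  SPIN permutes a cell-cell correlation
matrix `C` so similar cells sit at nearby positions, by minimizing
`E = Σ_ij D[o(i),o(j)] G_ij` with `D = 1 − C` and a Gaussian
neighborhood weight `G_ij = exp(−(i−j)²/w²)` under a decreasing width
`w`.  The sorted matrix is split at the position `x` maximizing

    f(x) = [ Σ_{i,j≤x, i≠j} C_ij + Σ_{i,j>x, i≠j} C_ij ] / [ x² + (n−x)² ]

and every gene follows the daughter cluster holding its expression
center of mass.  Feature selection (CV excess over an SVR noise model
of log₂CV vs log₂mean) is re-run at every node, excluding genes that
belong to the sibling branch.

**Marker model.**  Per gene, counts are negative binomial with mean
`μ_i = x_i·(β−1) + 0.001` over a baseline predictor (library depth) and
one-hot cluster predictors, overdispersion `rv = (r+1)²−1`, priors
`r ~ HalfCauchy(0,1)`, `β ~ Pareto(1,1.5)`.  A cluster is called
enriched (binarized 1) when `P(β_k > β_baseline) ≥ 0.998`, its median
`β_k−1` is ≥ 35% of the top cluster's, and the top median exceeds 0.4
molecules.

**Cross-species matching.**  One-to-one homologs carrying selective
signal are kept; cell types of two species are matched when their
expression-profile correlation `S_mn` is the maximum of both its row
and its column.  Developmental timing is compared via half-sampling
times (the age where the fitted density's cumulative area reaches 1/2).

**Proliferation index.**  Cell-cycle-annotated genes that are detected
and mutually correlated form a panel; k-means (k=2) separates cycling
from non-cycling cells, and a strongly L1-regularized linear regression
(alpha = 0.01) of that 0/1 label on log-centered panel expression gives
a reusable per-cell score.

**Pseudotime.**  Genes varying with sampling age (NB likelihood-ratio
test, BH FDR < 0.01) define a subspace; a principal curve through the
retained principal components assigns each cell the arc length of its
projection; per-gene SVR profiles over pseudotime (stratified CV,
out-of-fold R²) are clustered by affinity propagation.

**Prototype scoring.**  A multinomial L2-penalized logistic regression
(C = 0.01) on log-transformed max-normalized data learns cell-type
prototypes (possibly merging related clusters); query cells receive
softmax probabilities `p` and a wheel-plot position `x⃗ = Σ p_i û_i`
over the vertices of a regular polygon, with the vertex order chosen to
minimize cells in the central area.  Scrambling gene values within
cells provides the negative control.

## Worked example

`python examples/01_generate_and_cluster.py` generates 500 cells in 5
planted types (20 fold-10 marker genes each), filters, and biclusters:

```
generated 1000 genes x 500 cells, 5 planted types
QC: 500/500 cells kept, 999/1000 genes kept, median 1164 molecules/cell
BackSPIN found 5 clusters; ARI vs planted types = 0.956
cluster sizes: {'C01': 106, 'C02': 102, 'C04': 101, 'C00': 97, 'C03': 94}
```

The adjusted Rand index of 0.956 means the recovered leaf partition
almost exactly reproduces the planted types (1.0 = identical, 0 =
chance); one gene fell below the 4-molecule detection floor.  The other
examples (`examples/02` … `07`) walk through marker binarization,
cross-species matching, the proliferation index, pseudotime, prototype
scoring, and the end-to-end pipeline with manifests.

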