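# Methods

This note documents the models, numerical choices, and synthetic study
conditions behind `cellspin`, in the order the pipeline runs.  Nothing
here states a result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic data

The generators in `cellspin.synth` produce the statistical structure
every downstream stage assumes, with a `GroundTruth` sufficient to
verify any downstream result.

Counts are negative binomial parameterized by mean `μ` and
overdispersion `φ` with `var = μ + φμ²` (gamma–Poisson mixture;
`φ → 0` recovers Poisson).  The marker model downstream uses the
shape/rate form `y ~ NB(μ/rv, 1/rv)` with `var = μ(1+rv)`; the two
agree at a given mean when `rv = φμ`, i.e. the generator's quadratic
mean–variance law corresponds to a per-gene `rv` proportional to
expression level — adequate for the moderate ranges simulated here.

Defaults (chosen once as realistic study conditions, and used by the
tests as-is):

- `base_mean = 0.5` molecules/cell (median), `dispersion φ = 0.5`,
  `libsize_cv = 0.3` — per-cell library factors are log-normal with
  unit mean; strictly positive with a heavy-ish right tail like real
  UMI depth.
- `gene_mean_cv = 2.0`: per-gene base means are log-normal around
  `base_mean`.  Real UMI data spans orders of magnitude in gene mean,
  and the CV-vs-mean noise regression is only identifiable on such a
  continuum; setting this to 0 (supported) produces a single shared
  mean, which some closed-form tests use deliberately.
- Marker panels are contiguous, disjoint gene blocks assigned
  deterministically from the seed, for test readability; a marker's
  mean in its own type is `marker_fold` times its own base.

`make_species_pair` blends log-mean profiles of matched types,
`log m_B = (1−d)·log m_A + d·ε` with `ε` an independent redraw, so
matched types correlate perfectly at divergence `d = 0` and decorrelate
as `d` grows.  `make_trajectory` draws latent times uniform on [0,1]
and lets dynamic genes follow linear up/down ramps or a Gaussian bump
at t = 0.5 between their base mean and `fold ×` it; a discretized age
column (four pseudo-embryonic days) emulates the sampling metadata.
`add_cycle_module` re-draws the cycle genes of a random cell subset at
`fold ×` their background mean, producing a co-activated, mutually
correlated module.

Not emulated: doublets, ambient RNA, batch/litter effects, and
per-gene dispersion variation.  Passing tests therefore demonstrate
method correctness under the assumed generative structure, not
robustness to those artifacts.

## Quality control

Cells are kept when `min ≤ total molecules ≤ max`, both ends inclusive
(the gene rule's explicit "less than" strictness argues the window is
inclusive by contrast); genes with dataset-wide totals strictly below
`min_gene_total = 4` are dropped.  The cell filter runs first, so gene
totals refer to the post-QC dataset.  An optional hook drops cells
whose cluster assignment disagrees between two supplied clusterings
*and* whose depth is below the dataset median; it is off by default
because the comparison protocol it approximates is not fully specified.

## Feature selection

The noise model is a support-vector regression (RBF, `gamma = 0.06`,
otherwise library defaults) of log₂CV on log₂mean over genes with
positive mean; a gene's score is its residual.  The fit is made robust
by one trim-and-refit pass (refit after dropping genes above the 90th
residual percentile): genuinely variable genes occupying an isolated
mean range otherwise anchor the noise floor to themselves and score
zero.  Selection takes the top-n residuals with ties broken by higher
mean then lexicographic gene ID, making it a pure function of the data.

Sibling exclusion before re-clustering: from the genes assigned to the
sibling branch, a core is formed (mean pairwise Pearson correlation on
log1p counts ≥ `core_corr = 0.5`); all genes correlated ≥
`expand_corr = 0.3` with ≥ `core_fraction = 0.5` of the core join the
excluded set.  The thresholds are unquantified upstream; these defaults
are config-exposed.

## SPIN and BackSPIN

SPIN minimizes `Σ_ij D[o(i),o(j)]·G_ij` (`D = 1 − C`, Gaussian
positional weights).  The width schedule starts at `n/2` and is
multiplied by `runs_step = 0.1` after each batch of `runs_iters = 12`
reassignment iterations, ending at width 1.  Reassignment ranks items
by the weighted positional center of their inverted placement-cost
profile, with ties broken by previous position; a candidate order is
accepted only if it lowers the energy, which makes the recorded trace
non-increasing within each width by construction.

The split objective `f(x)` sums off-diagonal correlations inside the
two blocks and divides by `x² + (n−x)²`; `x` is the left-block size,
evaluated exhaustively with ties to the smaller `x`.  An independent
brute-force enumeration backs the implementation in the tests.

Stopping rule: recursion continues only when
`f(x_s) > stop_const × mean off-diagonal correlation` of the node
(`stop_const = 1.1`) **and** `f(x_s) > min_split_score = 0.1`.  The
absolute floor is this package's addition: the ratio alone is
meaningless when a node's background correlation is near zero (pure
noise), where the argmax of `f` is always positive and the pinned rule
would recurse to singleton leaves.  A `raw` mode (`f(x_s) > stop_const`
directly) is exposed for completeness.  Nodes under 4 cells or at
`numLevels = 7` become leaves.  Genes follow the daughter whose sorted
positions contain their center of mass (positions 1..n; boundary to the
left; all-zero genes left; the assignment is scale-invariant per gene).

Distance for cell sorting is `1 − Pearson` on log1p counts over the
node's selected features.  Leaf labels are assigned in leaf order;
within-leaf gene correlation matrices are SPIN-sorted and attached.

The within-species cluster similarity is the Pearson correlation
between cluster columns of the binarized marker matrix, restricted to
genes significant in ≥ 1 cluster and detected at ≥ 1 molecule/cell on
average in ≥ 1 cluster, SPIN-sorted for display.

## Bayesian marker model and binarization

The per-gene model is exactly the density in the README: NB likelihood
in shape/rate form with a single shared overdispersion `r` per gene
(the shared-`rv[1]` behavior of the reference model is reproduced), a
strictly positive baseline predictor (cell total / mean total), and
one-hot cluster predictors; `β ≥ 1` with Pareto(1, 1.5) priors, so
`β−1` is "extra molecules attributable to the cluster".

Sampling runs in the unconstrained space `u = log(β−1)`,
`v = log(r−0.001)` with the exact Jacobian.  The default sampler is an
ensemble MCMC (emcee) with differential-evolution moves — these mix far
better than stretch moves on the anti-correlated (baseline, cell-type)
ridge — initialized at the posterior mode (L-BFGS-B on the constrained
density).  Defaults: 16 walkers, 1200 warmup steps, 800 sampling steps
(12,800 post-warmup draws).  Convergence is flagged by split-R̂ over
walker chains computed on the *constrained* β scale (the unconstrained
scale is a flat ridge for silent genes piled at the bound β = 1) with
limit 1.1; non-converged genes are excluded from binarization.

An independent random-walk Metropolis sampler on the same density is
bundled as the cross-check oracle.  Its proposals are shaped by the
inverse curvature (full numerical Hessian) of the log posterior at the
mode, which lets a scalar-step walk traverse the baseline/cell-type
ridge; a global factor adapts to ~30% acceptance during warmup.

Binarization conditions per cluster: (1) `P(β_k > β_base) ≥ 0.998`
(0.95 in adult-tissue mode); (2) `median(β_k−1) ≥ 0.35 ×
median(β_top−1)`; (3) `median(β_top−1) > 0.4`.  "Median posterior
probability" is read as the median of the posterior distribution, its
only coherent reading.  MAP cluster expression profiles — used for
cross-species work — are `(β_k−1) + mean-baseline_k·(β_base−1)`, the
model's expected molecules for a typical cell of the cluster.

## Cross-species comparison

Homolog pairs must be one-to-one (others are dropped and counted).  A
pair survives the comparison filter when it is significant in ≥ 1
cluster in both species, significant in < 6 clusters in at least one
species, and — within at least one species — spans a real dynamic range
(max > 1.5 and min < 0.25 molecules/cell); the grammatically ambiguous
range clause is pinned to that per-species reading.  Similarity is
Pearson over the filtered panel; entries with a constant profile are
reported missing rather than fabricated.  Mutual best matches are
row-and-column maxima, ties reported in full.  The similarity operation
is scale-agnostic; the acceptance measurements correlate log1p
profiles so each conserved marker carries comparable weight.

Half-sampling times use a Gaussian KDE (Scott bandwidth, overridable)
and solve `CDF(t*) = 1/2` by bisection over the KDE's support, with an
optional percentile bootstrap CI.  Identical ages return that age.

## Proliferation index

Annotation genes with ≥ 10 total molecules enter a pairwise Pearson
correlation (log1p counts); the threshold is the 99th percentile of the
off-diagonal entries (the diagonal is excluded — including n unit
entries would make the cut depend on list size), and genes with ≥ 12
partners above it form the panel.  The percentile rule presumes the
coherent cycle module is a small fraction of the annotation list, as it
is for broad GO-derived lists; the synthetic conditions plant 40 cycle
genes among 400 annotated.  "Log-centered" is log1p then per-gene mean
centering.  K-means (k = 2) labels the higher-panel-expression cluster
cycling, so the final labels do not depend on k-means' arbitrary
indexing; an L1 regression (`alpha = 0.01`, deliberately ~5× stronger
than cross-validation would pick) maps expression to a score, and the
binary call cuts at 0.5 (config-exposed).  Scoring a foreign matrix
reuses the training centering; missing panel genes impute as zero with
a warning.

## Pseudotime

Gene selection: top-5000 noise-model residuals, then a per-gene NB
likelihood-ratio test of categorical age against an intercept-only
null.  With a categorical-only design the NB maximum-likelihood means
are the group sample means for any fixed dispersion, so the fit is
closed-form; the dispersion is profiled out under the alternative
(bounded scalar optimization on log φ) and shared by both models, which
keeps the test calibrated on NB null data.  Benjamini–Hochberg controls
FDR at 0.01; an exclusion set (genes significant in other cell types)
is subtracted.

Expression entering PCA and profile fits is depth-normalized (counts
scaled to the mean library size) before log1p: without this the leading
PC is sampling depth, not maturation.  Components are retained when
their SD exceeds both the fixed 0.25 cut and a parallel-analysis noise
floor (the leading PC SD after independently permuting every gene
column; opt-out via `noise_floor=None`), minimum two components: the
absolute cut is tied to a particular expression scale, while the
permutation floor adapts to any scale.

The principal curve is Hastie–Stuetzle: initialized on PC1, each
iteration lowess-smooths every coordinate against the current arc
length (frac 0.3) and re-projects onto the resulting polyline, until
the mean squared projection displacement falls below 1e-4 or 50
iterations (non-convergence returns the last iterate, flagged).
Pseudotime is arc length from the curve start, oriented so it
correlates positively with sampling age (first PC when ages are
absent).

Profiles: optional imputation replaces a gene's zero counts with an
L1-regression prediction from its 30 most-correlated genes (a documented
stand-in for the published imputation approach; switchable off), then
SVR of normalized expression on pseudotime with `C ∈ {1, 10}`,
`ε ∈ {0.05, 0.2}` chosen by 4-fold CV stratified on pseudotime-quantile
bins; the reported R² is out-of-fold.  Splits and the final fit use a
canonical (pseudotime, cell-ID) ordering so results are invariant to
cell order.  Genes with R² < 0.35 are not significant and carry no
cluster label; the rest are standardized on a 50-point grid and
clustered by affinity propagation (negative squared distance, median
preference), yielding exemplar "prototypical dynamics".

## Prototype scoring

Panel: top-4500 noise-model residuals on reference + outgroup combined;
genes whose outgroup variance is below 10% of their combined variance
are discarded (the unquantified "minimal variability" rule, pinned and
config-exposed); the survivors are halved by best rank under three
specificity heuristics (fold-increase, fold × fraction-positive,
fold × √fraction-positive).  Features are log1p counts max-normalized
per gene; query cells reuse the *training* maxima unclipped.  The
classifier is multinomial logistic regression with L2 penalty,
`C = 0.01` by default; `choose_regularization` reproduces the
plateau rule deterministically as the smallest C within one standard
error of the grid maximum over 35 stratified 85/15 splits.

Wheel plot: vertices of a regular K-gon (first vertex at the top,
clockwise); a cell sits at `Σ p_i û_i`, always inside the unit disk.
Vertex order minimizes the number of cells with `|x⃗| < 0.2` (the
central-area radius, a pinned default): exhaustively over circular
orders for K ≤ 8 (first vertex fixed, reflections halved), by a greedy
maximum-weight Hamiltonian chain on the prototype co-probability matrix
for larger K.  The scrambled control permutes gene values independently
within each cell, preserving each cell's count distribution exactly
while destroying gene identity.

## Pipeline

`run_pipeline` executes qc → feature_selection → backspin →
binarization → optional stages from a flat per-stage config (unknown
keys are errors), with all randomness derived from the master seed via
SHA-256-named substreams and a manifest (stage, input/output SHA-256,
seed, version) written after every stage.  Stage failure raises with
the stage named; completed artifacts remain.

## Problem sizes and limitations

Tests and the acceptance script run at desk scale, chosen to finish in
minutes on one CPU: 500 cells / 1000 genes for biclustering recovery,
200 genes × 150 cells for marker-model recovery (the Bayesian fit is
the dominant cost, ~1.5 s/gene), 50 replicate seeds for cross-species
matching, 2000 cells for prototype training.  Known limitations: the
stopping-rule floor and several unquantified upstream thresholds are
pinned defaults rather than derived quantities; the NB conversion
`rv = φμ` is expression-level dependent; profile R² is bounded above by
the NB noise floor at high dispersion, so strongly overdispersed genes
cannot pass the 0.35 cut even when genuinely dynamic; and the
synthetic conditions omit batch structure entirely.
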