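# Methods

`embrisk` implements a functional single-cell RNA-seq procedure for
assessing the embolic risk of cultured adipose-derived stromal cells
(hADSCs): cells are scored for canonical-pathway activity, clustered in
pathway space, a linear SVM gene panel separating pro-embolic from
non-embolic cells is learned, and the SVM weights are turned into a
per-cell embolic risk score with an ROC-calibrated threshold and a
population-level verdict. This note records the models, the defaults
and why they are what they are, and what the bundled synthetic data can
and cannot show.

## Quality control and normalization

Per cell we compute total UMIs, detected genes and the mitochondrial
read percentage. A cell is excluded iff

* `mito_pct > median + k*MAD`, or
* `n_genes < median - k*MAD`, or
* `total_umi < median - k*MAD`,

with `k = 3` and the MAD left unscaled (no 1.4826 consistency factor;
`scale_mad=True` restores it). The rule is deliberately one-sided in
each metric. When a metric has zero MAD the rule degenerates to an
exact-median cut on the outlying side, with a warning; identical cells
are all kept. Note that for a metric with normal-like tails an
unscaled 3-MAD cutoff sits at about two standard deviations, so it
trims roughly 2% of perfectly healthy cells per rule — low retention on
real data is a property of the rule, not a bug.

Depth normalization is `log(1 + count * scale / cell_total)` with
`scale = 10,000`, recorded in the matrix provenance. Variable genes are
ranked by dispersion (variance/mean of the back-transformed values)
z-scored within 20 equal-frequency mean bins. Optional covariate
regression replaces each gene by its least-squares residual (intercept
always included; all-zero covariates reduce to centering; collinear
designs are rejected by name). PCA runs on per-gene z-scores clipped at
±10, with a deterministic sign convention (the largest-magnitude
loading of each component is made positive).

Cell-cycle phase scoring is not implemented; the covariate interface
accepts any per-cell vector, so a phase score computed elsewhere can be
regressed out, but no phase gene lists ship with the package.

## Pathway activity scores

Three independent per-cell scorers convert expression into a cells ×
pathways matrix; all three share one ranking utility whose tie policy
is a seeded random permutation of gene order.

**Running-sum enrichment (`ssgsea`).** Genes are ranked per cell by
decreasing expression. In-set positions step the running sum up by a
weight proportional to `rank_value**alpha` (rank_value = G for the top
gene down to 1; weights normalized to sum to 1 over the set), out-of-set
positions step down by `1/(G - m)`. The score is the sum over all G
positions of the running difference, computed in closed form as each
gene's weight times the number of positions at or below it. The default
exponent is `alpha = 0.25`; at `alpha = 0` the score is a pure rank
statistic and therefore invariant under any strictly monotone per-cell
transform (for `alpha > 0` invariance still holds because the weights
use rank values, not expression magnitudes). No cross-cell range
normalization is applied by default.

**Recovery-curve AUC (`auc_recovery`).** The area under the gene-set
recovery curve within the top `top_frac` of the ranking, divided by the
maximal achievable area for that set size; scores lie in [0, 1] and
reach 1 exactly when the set fills the top ranks. The package default
is `top_frac = 0.1`. With the compact synthetic gene universes used
here (2,000 genes), a 5% window is only 100 rank positions; the
recovery area of a 20-gene set is then controlled by a handful of
discrete positions, and the resulting lumpy score geometry fragments
graph communities downstream. Ten percent restores a smooth score and
full concordance with the other two scorers; the window is a parameter
and 0.05 can be requested for data with larger universes.

**Module score (`module_score`).** Mean expression of the set genes
minus the mean of expression-matched control genes: genes are cut into
24 equal-frequency bins by population-average expression and 100
controls per set gene are sampled (seeded) from the gene's bin, with
replacement if the bin is smaller. A constant matrix scores exactly 0.
This is the pipeline's default scorer — it is the cheapest of the
three, and it is also the scorer used for the four fibrin-clot pathway
sets that define the pro-embolic state; the other two serve as
cross-checks (the clusterings they induce agree with adjusted Rand
index ≈ 1 on the bundled presets).

`embolic_scores` is the module scorer restricted to exactly the four
coagulation pathways ("common/extrinsic/intrinsic pathway of fibrin
clot formation", "formation of fibrin clot"); missing names are an
error.

## Functional clustering

Cells are embedded by PCA of the (z-scored) pathway-score matrix using
`min(30, n_pathways - 1)` components, connected into a shared-nearest-
neighbor graph (k = 20 neighborhoods including the cell itself, edge
weight = Jaccard overlap, weights below 1/15 pruned), and partitioned
by seeded Louvain modularity optimization (networkx). The pipeline
default resolution is 0.5: on the bundled presets it returns exactly
the planted program counts for all three scorers, while resolution 1.0
over-partitions the lumpier recovery-AUC score geometry. On
structureless data any modularity partition of the single kNN blob is
arbitrary; at resolution ≤ 0.3 the blob stays one community.

Markers come from a cluster-vs-rest Wilcoxon rank-sum test — the
tie-corrected normal approximation with continuity correction, exact
enumeration when both groups have ≤ 8 cells — with natural-log fold
change of mean back-transformed expression (pseudocount 1e-9) and
Benjamini–Hochberg correction across genes within each cluster; rows
are kept at FDR < 0.05 and |logFC| ≥ 0.25.

A cluster is called **pro-embolic** iff the one-sided rank-sum test of
its cells' mean embolic-pathway score against all other cells is
BH-significant at 0.05 *and* its median score exceeds the global
median. The median rule adds direction, making algorithmic what is
otherwise a heatmap judgement. Because the clusters are themselves
built from the same score matrix, this call is descriptive, not an
independent hypothesis test.

## The linear SVM and its solver

The classifier is the standard soft-margin linear SVM. The dual

    min_a 1/2 Σ_ij a_i a_j y_i y_j (x_i·x_j) - Σ_i a_i,
    0 ≤ a_i ≤ C,  Σ_i a_i y_i = 0

is solved by sequential minimal optimization with LIBSVM-style
second-order working-set selection, periodic shrinking of bounded
non-violating points, and warm starts; convergence (KKT violation ≤
`tol`, default 1e-3) is always re-verified on the full set with a
freshly recomputed gradient. The weight vector is `w = Σ a_i y_i x_i`;
the offset `b` is averaged over free support vectors (0 < a < C), which
is numerically stabler than, and at convergence identical to, reading
it off a single free component. Exhausting the iteration budget with
the KKT gap above tolerance raises an error carrying the penalty and
the residual. Prediction is `sign(w·x + b)` with an exact zero mapped
to +1. Features are z-scored with training-set statistics before
fitting, because the squared-weight ranking used by RFE is
scale-sensitive; the scaler is stored in the model.

The solver is validated in the test suite against a brute-force
quadratic-programming oracle (SLSQP on the dual) on random small
instances, and against LIBSVM's solution on a larger one.

**SVM-RFE.** For each penalty in the grid C ∈ {0.2, 0.6, 0.8, 1.0,
1.2, 1.6, 2.0, 2.2, 2.6, 3.0}: fit, rank features by `w_i²`, eliminate
the weakest 10% (at least one), and record the stratified 10-fold CV
accuracy of every nested subset down to a single feature. The selected
panel is the smallest subset attaining the maximal CV accuracy across
the whole grid; ties break to the smaller penalty. The per-penalty
elimination paths are all retained for inspection. One Gram matrix per
penalty is shared across folds and down-dated as features leave, which
is what makes the ~4,000 SVM fits of a full run affordable.

**Final model.** On the selected panel, one SVM per penalty in
C ∈ {0.0001, 0.0005, 0.001, 0.002, 0.004, 0.008, 0.02, 0.05, 0.2, 0.6,
1.2, 1.8, 2.4, 3.0} is trained and scored (accuracy, precision, recall,
F1) on every test set; the final model maximizes mean test accuracy,
ties to the smaller penalty.

## The embolic risk score

For a cell with panel expression `G` (standardized with the training
scaler) the risk score is

    RS = 1 + exp(-Σ_i w_i G_i).

Two properties of this formula are preserved exactly as stated rather
than silently corrected: the sum omits the hyperplane offset `b` (an
`include_offset` flag adds it for sensitivity analysis), and the range
is (1, ∞) — the often-quoted "0 to ∞" is unattainable for `1 + e^-x`.
Because RS is strictly decreasing in the margin, a positive-margin
(pro-embolic) cell lands on the *small* end of the scale; which side of
the RS axis is embolic is therefore resolved empirically: the ROC
direction flag is chosen so that AUC ≥ 0.5 and is reported with the
threshold.

The operating threshold maximizes the Youden index J = sensitivity +
specificity − 1 over all midpoints between consecutive sorted unique RS
values (plus ±∞); ties resolve to the higher-specificity point. The
trapezoidal AUC over this curve equals the Mann–Whitney U statistic
divided by n₊n₋ (asserted to 1e-10 in the tests). Cells exactly at the
threshold are called embolic (conservative).

The population verdict compares the pro-embolic proportion with a
calibration constant of 13.16% of a 1-million-cell dose — an empirical,
animal-model-derived threshold at which infusion causes pulmonary
embolism. It is configurable and is not a property of the classifier;
a proportion exactly at the calibration is a positive (embolic_risk)
verdict.

## The synthetic data generator

No public accession exists for the original sequencing data, so every
stage is exercised on a negative-binomial generator whose structure
mirrors the two-culture-condition design:

* **Baseline.** Per-gene means from Gamma(shape 0.4, scale 1.0);
  NB dispersion θ = 2 (`var = μ + μ²/θ`); per-cell depth = a bounded
  uniform cell-size factor on [0.4, 1.6] times a narrow lognormal
  (σ = 0.1). 2,000 genes.
* **Programs.** Each cell belongs to exactly one of 5–6 latent
  pathway-activation programs (largest-remainder quota, then a seeded
  shuffle — exact counts, so cluster-count checks cannot be flaky).
  Program membership multiplies the program's 80-gene set by a fold
  change of 6. The embolic program's set is split round-robin across
  the four fibrin-clot pathway names; other programs get one synthetic
  pathway set each. Panel genes are excluded from program sets so the
  classifier signal stays orthogonal to the cluster signal.
* **Mitochondria.** 4% of genes, 6× baseline mean, θ = 50, modulated
  per cell by a bounded uniform mito-content factor on [0.5, 1.5].
  The bounded factors are what make the one-sided 3-MAD QC rules
  retain ≥ 99% of healthy cells: a purely normal-tailed metric would
  lose ≈ 2% per rule no matter the parameters, whereas a bounded
  dominant component has no tail to cut.
* **Outliers.** A configurable number of planted QC outliers with 10×
  or 0.05× library size and 10× mitochondrial content.
* **Panel.** The 13 discriminative genes (the twelve published names
  plus the placeholder `KEYGENE13` for the unnamed thirteenth) are
  shifted by `exp(panel_effect)` in pro-embolic cells. Two modes:
  `shared` (default — every panel gene shifted in every +1 cell) and
  `exclusive`, in which each +1 cell switches on exactly one panel
  gene, round-robin, from a silent baseline (mean
  `(base + pseudocount)·e^effect`). Exclusive mode models pro-embolic
  cells that activate different coagulation effectors; it makes every
  panel gene individually necessary, so dropping any one gene costs
  ~1/13 of the positive class and the CV-accuracy path of RFE falls
  off a cliff below the true panel size.

Presets: `mf_default` (3,000 cells, 6 programs, embolic fraction 30%),
`il_default` (2,600 cells, 5 programs, embolic fraction 8%), and
`panel_default` (2,000 cells, 120 genes, two balanced classes,
exclusive panel mode, effect 7.5, panel θ = 20). Identical scenarios
(including the seed) are bit-identical on disk.

**What the generator does not emulate:** doublets, ambient RNA,
batch/plate effects, cell-cycle structure, gene–gene correlation beyond
the program blocks, or read-level noise. Passing tests therefore
demonstrate that the pipeline recovers the structure it assumes — not
that real hADSC data satisfy those assumptions.

## Pipeline, seeding and problem sizes

`run_all` chains QC → normalization → module scoring → pathway-space
PCA/SNN/Louvain → pro-embolic cluster identification → supervised
labels (planted truth, batch membership, or pro-embolic cluster
membership) → a 70/30 stratified split → a univariate candidate filter
(top 60 genes by standardized class-mean difference, which keeps the
RFE search tractable) → SVM-RFE → final-model selection → RS scores →
ROC threshold on the held-out split → per-population verdicts. One
global seed fans out to per-stage seeds through a stable CRC-based
derivation, so output paths never influence numbers and every stage can
be reproduced in isolation.

The scripted acceptance run and the test suite use the presets at their
packaged sizes (≈3,000/2,600/2,000 cells); the end-to-end two-condition
test runs a reduced pair (800 cells, 800 genes, two-penalty RFE grid)
— sizes chosen as the smallest at which every recovered quantity is
stable across seeds.

## Known limitations

* The Louvain resolution (0.5) and SNN k (20) are calibrated on the
  bundled presets; real data will need their own resolution sweep.
* The pro-embolic cluster call reuses the score matrix that defined
  the clusters (inherent double-dipping, as in the original heatmap
  procedure); treat its p-values as ranking scores, not error rates.
* RFE's exact-size panel recovery relies on the exclusive activation
  structure; under a shared panel shift the CV-accuracy path is flat
  near the optimum and the minimal panel is genuinely ambiguous.
* The SMO solver targets dense problems of a few thousand cells; very
  large datasets would need a chunked Gram matrix or a primal solver.
* The 13.16% calibration constant is inherited from an animal model
  and shipped as a configurable number, not re-derived.
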