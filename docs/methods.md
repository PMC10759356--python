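# Methods

This note documents the models, numerical choices and limitations behind
each pipeline stage, and what the synthetic-data generator does and does not
emulate.

## Synthetic single-cell data

Counts are negative binomial with gene-wise means
`mu(g, c) = L_c · p_k(g)`, where `p_k` is the relative expression profile of
cell `c`'s cluster `k` and `L_c` the cell's expected library size. The
baseline profile is log-normal(0, 1) across genes; cluster `k` multiplies
its planted marker genes by `2^de_effect`; profiles are renormalized to sum
to one, so the realized fold change is slightly below the nominal effect
(the renormalization spreads the added mass over all genes). Library sizes
are `mean_library_size · LogNormal(0, libsize_sigma)` — defaults 5,000 and
0.35, typical of droplet data. The dispersion parameter (default 2.0, with
variance `mu + mu²/θ`) gives the strong overdispersion of UMI counts.

Structure planted for specific stages:

- **Mitochondrial block** — the first `mito_fraction` of genes carry `MT-`
  prefixes, so QC and covariate regression have a real mitochondrial
  fraction to work with.
- **Hormone gene pair** — two dedicated genes whose per-cluster regime
  cycles through both-high / A-only / B-only / both-low / neither
  (multipliers 8 / 1 / 0.05), exercising the co-expression quadrant
  analysis.
- **Aggressive subpopulation** — a fraction of cells in *every* sample
  (default 2%) whose proliferation-program genes (default 25, disjoint from
  markers and hormones) are up-shifted by `2^aggressive_effect`. This
  mirrors a rare cross-sample proliferative tumor-cell cluster and is the
  training signal of the classifier. Aggressive status is an overlay on the
  base cluster, recorded in the ground truth.
- **Lineage bias** — with `lineage_bias > 0` each sample draws
  preferentially from a designated dominant cluster (round-robin), giving
  pseudo-bulk profiles genuine sample-level lineage structure.

Samples are split half normal / half tumor as annotation metadata. Bulk
cohorts are convex mixtures of cluster centroids in log-normalized space —
carcinoma-like samples get weight 0.40 on the aggressive centroid versus
0.05 for the rest, matching a cohort of 13 samples with 3 carcinomas —
multiplied by gene-wise LogNormal(0, noise_sigma) noise, with a fraction of
entries masked missing and optionally a fraction of genes dropped
("not measured on the platform"). Reference atlases keep a fraction of
genes, re-case symbols mouse-style, distort each kept gene by a log-normal
scale factor and sample Poisson counts around each centroid; with
`count_sampling` off, cells are deterministic expected-count copies of the
centroid — the exactly noiseless limit in which mapping must be perfect.

**What the generator does not emulate**: gene–gene correlation beyond the
cluster/program structure, doublets, ambient RNA, batch effects, zero
inflation beyond the NB, and realistic gene-length or GC biases. Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under a faithful null/effect model, not robustness to every real
artifact.

## QC and normalization

Four cell filters (UMI range, detected-gene range, mitochondrial fraction,
dissociation-signature fraction) run before the gene filter (detected in
≥ 3 cells). Defaults — UMIs 500–60,000, genes 200–8,000, mito ≤ 0.2,
dissociation ≤ 0.05 — are package choices (configurable); for cross-species
reference data the conventional genes ≥ 200 / mito ≤ 0.5 apply. Filters are
computed once on the input matrix in the stated order; a second application
is a no-op on realistic data, though a gene removal can in principle drag a
borderline cell below a threshold.

Normalization is `ln(count / cell_total × 10,000 + 1)`. Natural log is the
single supported base and is recorded on the data type.

HVG selection is vst-style: per-gene raw-count mean and variance (n−1
denominator throughout the package), a local-regression trend of log₁₀
variance on log₁₀ mean (lowess, span 0.3), counts standardized by the
trend-predicted standard deviation, clipped symmetrically at √n_cells, and
scored by the variance of the clipped values. Ties rank by gene id.
Because the score depends only on per-gene marginals it is exactly
invariant to cell order.

Scaling regresses each gene on the covariates (total UMIs, mitochondrial
fraction, with intercept) by OLS and standardizes the residuals; constant
genes become zero rows with a log message rather than an error.

## Marker statistics

The exact small-sample path computes the full permutation null of the rank
sum by dynamic programming over doubled midranks (doubling makes midranks
integers), then two-sided p = P(|W − E| ≥ |w − E|); the null is symmetric
about E, so this equals the usual doubled tail. The DP covers any group
sizes with n·m ≤ 200, including tied data for which the classic
no-ties recursion is unavailable. The large-sample path is the normal
approximation with midrank tie correction and 0.5 continuity correction.
Completely constant data gives p = 1.

Adjustment defaults to Benjamini–Hochberg, applied across the full table of
tested (cluster, gene) rows; Bonferroni is available behind a config enum
since the convention differs between toolkits. Fold changes are log₂ of
de-logged group means with pseudo-count 1. The detection prefilter
(expressed in ≥ 10% of either group, |log₂FC| ≥ 0.1) mirrors common
practice and can be disabled for calibration studies. Filtering thresholds
are strict inequalities, so a gene at exactly the threshold is excluded.

## Signatures and quadrants

Module scores bin all genes into 24 equal-frequency bins by mean expression
(ties broken by gene id) and draw 100 control genes per set gene with
replacement from the gene's bin, excluding set genes; a bin containing only
set genes borrows from the nearest non-degenerate bin. Scores are exactly
reproducible under a seed. Cell-cycle phase is G1 iff both S and G2M scores
are ≤ 0, else the arg-max phase.

Ternary scores divide three non-negative mean-expression signatures by
their sum; all-zero cells map to (1/3, 1/3, 1/3). The third coordinate is
stored as the floating-point complement of the first two, which makes the
row sum exactly 1.0 in double precision (any sub-ulp deficit is absorbed
into the middle coordinate).

The quadrant analysis calls a gene "expressed" at value > 0 and "high" at
value ≥ the per-gene upper quartile among expressing cells by default —
a scale-free cutoff, since no universal numeric threshold for "high" hormone
expression exists; both cutoffs are arguments.

## Mapping and pseudo-bulk

Cross-species harmonization matches uppercased symbols unless an explicit
one-to-one ortholog table is given, and requires ≥ 50 shared genes.
Correlations use the full shared gene space by default. Zero-variance cells
or centroids get r = 0 (logged); ties in the arg-max resolve to the
lexicographically smallest cluster label.

PCA is an SVD of the centered (and optionally unit-variance) matrix with a
deterministic sign convention — each component's largest-magnitude loading
is positive — so embeddings are exactly reproducible. `n_pcs` must not
exceed min(observations − 1, features); pipeline callers cap it (a
13-sample pseudo-bulk cohort uses 12 PCs). The dendrogram takes cluster
means in PC space of the scaled (TF-restricted) matrix, Euclidean
distances, and complete linkage by default (average and Ward exposed);
output serializes to Newick.

## Classifier transfer

Gene selection applies the marker filter (log₂FC > 0.75, adjusted
P < 0.05, positive only) and keeps genes detected in the bulk cohort,
recording the count at every stage. The selected set is stored in
lexicographic order and every feature matrix follows it, so results are
independent of marker-table row order.

Bulk harmonization imputes missing entries gene-wise (each missing value is
the average of the k = 10 nearest gene rows by Euclidean distance over
commonly observed samples) and quantile-normalizes across samples — both on
the **full** cohort, not the selected submatrix: quantile normalization
aligns whole-sample distributions, and running it on only the selected
genes would cancel exactly the coordinated elevation of those genes that
distinguishes aggressive samples. Tied ranks receive the mean of the
corresponding reference quantiles. The selected-gene submatrix is then
z-scored per gene, as is the single-cell side.

The ensemble trains unpruned CART trees with √p candidate features per
split, each on a stratified bootstrap of 1,500 aggressive and 500
non-aggressive cells drawn with replacement — with a rare aggressive class
this deliberately oversamples it near-exhaustively, which is the point of
the balancing. Defaults are 4,000 trees; recovery experiments and the
acceptance script use 500, which is already vote-saturated at these problem
sizes. A sample's aggressiveness probability is the fraction of trees
voting aggressive; prediction refuses feature matrices whose column order
differs from the model's.

## Problem sizes and determinism

Recovery experiments run at 2,000 genes × 3,000 cells (five clusters, 2%
aggressive cells), null calibration at 2,000 × 1,000, mapping at 1,000 ×
1,500 with 100 atlas cells per cluster, and the classifier transfer on a
13-sample bulk cohort over 20 seeds — sizes at which every planted effect
is comfortably identifiable while the full suite and the acceptance script
each complete in a few minutes. All randomness flows through
`numpy.random.default_rng` seeds; the pipeline derives per-stage seeds by
hashing stage names against one global seed, so stages re-run in isolation
reproduce their in-pipeline outputs byte for byte.

## Known limitations

- Exact rank-sum p-values are limited to n·m ≤ 200; beyond that the normal
  approximation is used even when slightly conservative.
- QC idempotence is empirical, not structural (see above).
- The KNN imputer recovers masked entries exactly only when near-duplicate
  gene rows exist (neighbor-mean semantics); on generic low-rank data it is
  approximate.
- Graph clustering, batch integration, embedding visualizations, enrichment
  analysis and survival analysis are intentionally out of scope; cluster
  labels are inputs.
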