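# Methods

## Problem setting

Given matched expression profiles of three RNA classes — protein-coding
mRNA, long noncoding RNA (lncRNA) and microRNA (miRNA) — over the same
samples, the goal is a genome-wide undirected network whose edges mean
"these two RNAs' expression levels are strongly associated after
accounting for the rest of the transcriptome", and, from it, the
heterogeneous 3-cliques (one RNA of each class, pairwise adjacent) that
serve as candidate cross-regulation units. The data regime is
p ≫ n: tens of thousands of RNA features against a few hundred samples.

## Preprocessing

Expression values arrive on an RPKM-like nonnegative scale containing
exact zeros. Zeros forbid a log transform, so each zero is replaced by
the **minimum nonzero value of its own sample (column)** — a per-sample
detection floor that leaves every observed value untouched and preserves
each column's minimum-nonzero statistic. Values are then log-transformed
(base 2 by default; the base only rescales the features and is
configurable) and the three class matrices are stacked into one combined
matrix over a canonical, lexicographically sorted sample order, which
makes the result invariant to the column order of the inputs. miRNA rows
can be pulled out of a noncoding compendium by case-insensitive
gene-symbol prefix (defaults `hsa-mir`, `hsa-let`, `mir`, `let-7`,
covering human miRNA nomenclature; configurable because annotation
sources differ). Genes with zero variance after the transform cannot be
standardized and are excluded from the regressions with a warning.

## Per-target sparse regression

Each RNA in turn is the response y (its log expression across samples,
centered); all other RNAs are candidate predictors (centered and scaled
to unit variance — marginal correlations and t-statistics are otherwise
scale-dependent; refit coefficients are reported back on the original
scale). The selection objective is l0-penalized least squares,
argmin_β ‖y − Xβ‖² + λ₀‖β‖₀, approached streamwise:

1. Candidates are visited in a seeded random permutation (a total,
   reproducible order also serves as the floating-point tie-break).
2. For candidate x_j, the t-statistic of x_j against the current residual
   is computed on the full data, then divided by √ρ_j. The
   **variance-inflation ratio** ρ_j ∈ (0, 1] is the residual variance of
   x_j after least-squares projection onto the current support, divided
   by its variance, both estimated on a fixed **presample** of
   m = min(200, n) rows; this corrects the optimism of the marginal
   statistic at O(m·k) cost per candidate instead of refitting on all
   rows. ρ = 1 for an empty support, and ρ is clamped to [1e-6, 1] so
   that exact collinearity cannot produce an infinite corrected
   statistic. If the presample is too small to fit the projection
   (m ≤ k + 1) the correction falls back to ρ = 1 with a warning.
3. The corrected statistic's two-sided normal p-value enters an
   **alpha-investing** test: wealth starts at w0 = 0.05, the level at
   step i is αᵢ = w/(2i), an admission adds Δw = 0.05 to the wealth and a
   rejection subtracts αᵢ/(1 − αᵢ) (wealth floored at 0, after which no
   further admissions occur). This sequential scheme bounds expected
   false selections over the stream and is the operational form of the
   nominal penalty weight λ₀, which is retained only for objective
   reporting.
4. After each pass the support is refit by OLS and any member whose refit
   t-statistic p-value exceeds the level that admitted it is pruned,
   worst violator first ("adding or removing one variable at a time").
   Passes repeat until nothing changes or `max_passes` (default 2) is
   reached. Admission also stops once the support reaches n − 2, where
   further coefficients are unidentifiable.

The final model is the OLS refit on the selected support; its goodness of
fit is the adjusted coefficient of determination
adj R² = 1 − (1 − R²)(n − 1)/(n − k − 1), which penalizes model size and
is comparable across supports of different k.

Defaults (presample 200, w0 = Δw = 0.05, two passes, seeded random
stream) follow the published convention for streamwise VIF selection; all
are exposed in `VifParams` / the estimator constructor. Centering absorbs
the intercept, so whether models "include" one is moot; the intercept is
reconstructed for prediction on the original scale.

## Network integration

One model is fit per RNA (31,623 models of 31,622 features each at the
genome scale the package is sized for; task enumeration is lazy, so the
manifest is cheap to describe and the dry-run mode prints the counts
without fitting). A model is retained only if adj R² **strictly
exceeds** the cutoff (default 0.8; "surpasses" read literally), and each
retained (target, regulator) pair contributes an undirected edge: the
regressions detect association, not direction, so arcs of either
direction collapse onto one edge, annotated with the maximum adj R² and
both discovery records for provenance. Vertices exist only while they
touch an edge, so the network's vertex counts are below the raw gene
counts. Each task derives its own seed from the root seed and the target
id (BLAKE2 hash), making the edge-set union independent of task execution
order and safe to parallelize; raising the cutoff can only remove edges.

## Triplet detection and screening

Triangles are listed edge-centrically: for every edge (u, v), each common
neighbor w of u and v with w greater than both (in the vertex order)
closes exactly one triangle once. This is exact for 3-cliques and linear
in the triangle count — no maximal-clique machinery, whose output would
anyway have to be re-filtered to size 3. A triangle is kept only when its
three vertex types are exactly {mRNA, lncRNA, miRNA}; slots are assigned
by type, making the (mrna, lncrna, mirna) representation canonical and
duplicate-free. Screening keeps triplets whose mRNA symbol belongs to a
supplied gene set (case-insensitive; GMT symbols are uppercased on load).
When a GMT file holds several sets, the screen uses the one named on the
command line, or their union behind an explicit flag — the scientific
use case screens against a single disease pathway.

## Synthetic data

The generator emulates the target data regime: positive RPKM-like values
(`rpkm_scale · 2^logexpr`), a tunable fraction of exact zeros, background
genes whose log expression is independent standard normal, and planted
triplets whose three members share a latent factor z per sample:
log expression = loading · z + N(0, noise_sd). Two planted members
therefore correlate at loading²/(loading² + noise_sd²) (≈ 0.99 at the
defaults loading 1.0, noise 0.1), so each pairwise regression attains a
high adjusted R² and the three pairwise edges of every planted triplet
are recoverable. A shared factor, rather than a causal chain, is the
right generative picture because the method's edges are
correlation-symmetric.

Defaults are a desk-scale cohort: 300 samples, 50/50/20 genes, 5 planted
triplets, 2% zeros. Zeros are planted only in background genes by
default so recovery tests isolate the network stage from the imputation
step (a flag allows zeros in planted genes for integration tests). What
the generator does **not** emulate: heavy-tailed RPKM marginals,
library-size and batch effects, gene–gene correlation beyond the planted
factors, and genome-scale dimensionality. Passing tests therefore
demonstrate correctness of the machinery and recoverability of strong
planted structure, not performance on real tumor cohorts.

## Numerical and design choices

- OLS refits use `numpy.linalg.lstsq` (SVD-based); refit covariance uses
  the pseudoinverse, so near-collinear supports degrade gracefully.
- Candidate p-values use the normal tail (the corrected statistic is an
  approximation anyway); refit prune p-values use the exact t tail with
  n − k − 1 degrees of freedom.
- Serialized numbers use `repr` round-trip precision and all writers emit
  canonical orderings, so every artifact is byte-stable and
  read∘write is the identity; the expression writer records the log-scale
  state in a `#scale=log` header line.
- A constant response yields the null model with R² defined as 0.
- Mean degree of the empty graph is defined as 0.

## Problem sizes used in the shipped checks

The test suite and the acceptance script size their simulations for a
single CPU: support-recovery problems at n = 200, p = 50 (with an
exhaustive-pair oracle) and p = 12 (full best-subset agreement), the
independent-noise null at 30 genes × 100 samples × 20 seeds, and the
end-to-end recovery design at 300 samples, 50/50/20 genes, 5 planted
triplets × 10 seeds. Genome-scale structure (31,623 tasks × 31,622
predictors) is exercised through enumeration only; fitting all
genome-scale models is cluster-scale work that users can shard by target
id, since tasks are independent and per-task seeded.

## Known limitations

- Edges are conditional-association claims under a linear model; they do
  not establish regulation or its direction.
- The adjusted-R² cutoff of 0.8 is a stringent, data-regime-dependent
  choice; on noisier cohorts it may leave the network nearly empty.
- Alpha-investing parameters trade recall for false selections; the
  defaults aim at sparse, high-confidence supports.
- The miRNA symbol-prefix selector is only as good as the annotation's
  naming discipline.
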