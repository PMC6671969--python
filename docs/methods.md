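# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices and the known limitations of the
package. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Mixed-model association

For one mutant line and one brain parameter the model is

    y_ij = β₀ + β₁·g_ij + u_j + ε_ij,   u_j ~ N(0, σ_b²),  ε_ij ~ N(0, σ_e²)

over the line's replicates plus the shared wild-type pool, with one
random intercept per necropsy-date batch j and the genotype indicator
g. The fit profiles the variance ratio λ = σ_b²/σ_e²: for
block-diagonal V = I + λZZ′, the GLS coefficients, the V-weighted
residual sum of squares and log|V| are closed-form functions of
per-batch sufficient statistics, so a likelihood evaluation costs
O(#batches) and whole screens vectorise across lines and a λ grid
(grid: 0 plus 49 log-spaced points in [1e-4, 1e4], then golden-section
refinement in log λ). This is what makes 100-permutation re-runs of a
500-line × 48-parameter screen affordable on one CPU. The same ML
optimum is recovered by `statsmodels.MixedLM`; the test suite uses that
as an independent oracle rather than as the implementation.

Inference on β₁ is a likelihood-ratio test of the genotype model
against the intercept-only model (both ML). The statistic is referred
to an F scale,

    F = (n − 2)·(exp(LRT/n) − 1)  ~  F(1, n − 2),

rather than to χ²(1). The two are asymptotically equivalent, but the χ²
tail is visibly anticonservative at screen-typical n (~100–150
observations per fit): the adaptive BH threshold in a screen sits at
p ≈ 5·10⁻⁴, exactly where the inflation matters for the realised
false-discovery proportion. The F form is also exact in the
zero-batch-variance limit: when the ML variance-ratio estimates of both
models hit the λ = 0 boundary, F is literally the squared pooled
two-sample t statistic, so the mixed model degrades gracefully into
Student's t. Singular/boundary fits are therefore not dropped — they
*are* the OLS solution, flagged via `LmmFit.boundary`. A Wald z test at
the fitted λ is available (`p_wald`) but not the default.

Lines kept on genetic backgrounds other than the main inbred pool are
routed to a plain equal-variance two-sample t-test against the wild
types of their own background (`method="ttest"`).

Per-line summaries are computed from raw animal-level values:
percent change = 100·(mean_mut − mean_wt)/mean_wt and
z = (mean_mut − mean_wt)/sd_wt, with the matched wild-type SD (not
SEM — the published choice is not stated; SD is the direct reading of
"deviation from the average of matched controls"). Severity is the
band of the largest-magnitude significant percent change, half-open on
the left: mild [0, 10), moderate [10, 20), severe [20, 40), very severe
[40, ∞). Direction is decrease/increase when all significant changes
share a sign, bidirectional otherwise; an exactly zero change cannot be
significant and is rejected, while a zero *percent change* with nonzero
fitted effect is counted by the sign of the effect.

**BH family.** The default family is all testable (line, parameter)
pairs of a screen (optionally within a user-supplied subproject
grouping); a per-parameter family is available. The published analysis
reports a single adjusted p per gene × parameter and genome-wide FDR
lists, which the global family matches most directly.

**Permutation FDR.** The calibration re-runs the entire caller on data
whose line labels are shuffled across mutant animals (wild-type pool
fixed), n_perm = 100 times, and compares the observed number of
BH-significant lines with the permutation mean ± SD. Within
`permutation_fdr` both the observed and the permuted screens use the
grid-only (unrefined) λ optimisation so the comparison is internally
consistent; standalone calls refine by default (the difference is in
the 4th decimal of p).

## Synthetic screens

The generator is the package's test bed; its defaults are the study
conditions every calibration figure refers to.

- Measurement model: `wt_mean · (1 + effect) · exp(batch + noise)` with
  parameter-specific log-normal noise, SD chosen so the multiplicative
  CV equals `wt_cv` (default 0.05 — the screen reports little
  inter-individual variation in most regions; the true per-parameter
  CVs are not published, so this is a configurable convention, not a
  calibration). Measurements are areas/lengths and stay strictly
  positive.
- Batch structure: wild types are spread round-robin over necropsy-date
  batches; a line's replicates share one batch (the shared-control
  design). Batch effects are drawn per (batch, parameter) — log-scale
  SD `batch_sd_frac`, default 0.02 — because processing drift hits
  each measurement differently; a single per-batch draw would correlate
  all of a line's tests through one random number.
- Optional per-animal common size factor (`animal_sd_frac`, default 0)
  induces the positive inter-parameter correlation of real brains
  (structures scale together); it is off by default so the baseline
  model has independent parameters given batch, and switched on where
  correlated panels are the point (e.g. imputation demonstrations,
  structural correlations).
- Planted effects: `fraction_nap` of lines receive 1–3 affected
  parameters; magnitudes are drawn from the four severity bands with
  configurable weights, and each line draws a direction class with the
  screen's observed proportions (46% decrease, 38% increase, 16%
  bidirectional). Negative effects are capped at −75% so areas stay
  positive; very-severe magnitudes at +150%.
- Catalogue: 118 parameters by default (39 + 39 on the two analysed
  coronal sections, 10 caudal, 30 sagittal; the published per-section
  counts are not mutually consistent, so only the total is matched),
  six categories, with `total_brain_area` always present so normalised
  structural correlations are defined.
- Companion generators produce planted-partition gene networks
  (log-normal CDS lengths, weighted-degree connectivity), constraint
  annotations whose scores shift by `assoc_strength` SDs for
  phenotype-carrying genes (in each metric's constrained direction:
  pLI/s_het/HIS up, dN/dS/RVIS down), and gene sets with controlled
  overlap with the planted genes.

What the generator does **not** emulate: left/right asymmetry, cellular
ectopia, image-level artifacts, realistic missingness mechanisms other
than MCAR, and kinship between lines. Passing tests therefore
demonstrate the statistics, not robustness to those features of real
histology data.

## Imputation

`fit_mvn_em` fits a multivariate normal to standardised,
genotype-adjusted residuals by EM over the missing entries (E-step:
conditional means plus conditional covariance accumulation per
missingness pattern; M-step: moment updates; stop when the
observed-data log-likelihood gains < `tol`, ridge on the diagonal for
conditioning). `impute_missing` fills each gap with its conditional
mean given the row's observed cells; observed cells are never touched
and an imputation mask is emitted.

Genotype adjustment uses empirical-Bayes shrinkage: a line's center per
parameter is `wt_mean + w·(line_mean − wt_mean)` with
`w = τ²/(τ² + σ²/n_line)`, τ² the method-of-moments between-line
variance. Lines with genuine effects keep their deviation (τ²
dominates); in a null screen the noisy 3-replicate means shrink to the
wild-type mean. Without shrinkage, a filled replicate equal to its
line's raw mean acts like a duplicated observation and produces
spurious NAP calls on null data.

This imputer is a deliberately simple, documented stand-in for the
Bayesian multiple-phenotype mixed model used in the published analysis:
the role of imputation here is to complete matrices for downstream
full-matrix analyses while respecting inter-parameter covariance, and
that contract — not the original tool's internals — is what is
implemented and tested. Point estimates are the default (the published
choice between point estimates and posterior draws is not stated);
`draw=True` samples from the conditional distribution instead.

**Known limitation.** Deterministic conditional-mean fills overstate
the effective sample size of a 3-replicate line wherever a replicate
was missing, so the raw type-I error of the mixed model re-run on
imputed null data runs above nominal (the suite measures ≈ 0.07–0.09
at the 0.05 level under 10% MCAR, and keeps a deliberately failing test
documenting it). False NAP calls remain under control — they stay
within 2 SD of the 100-permutation null computed on the same imputed
table — and conditional draws restore marginal variance but not the
center-estimation correlation. Users re-running variance-sensitive
tests on imputed data should rely on the permutation calibration, as
the published analysis did.

## Phenotypic similarity

Profiles binarise associations at BH-p ≤ 0.05 (cutoff inclusive;
not-testable associations score 0, absence). For genes i, j and
feature k with abnormality frequency f_k over the gene universe in the
matrix,

    S(i,j)_k = 1 − f_k²   if k is abnormal in both genes, else 0,

and the pair's score is the mean of S(i,j)_k over all features pooled
across the requested sections (default: the two analysed coronal
sections pooled into one mean — the index runs over features directly;
a mean-of-section-means mode is not provided because no result depends
on it). Genes without defects have similarity 0 to everything by
construction. The convergence test compares a module's mean pairwise
similarity against random same-size subsets of the matrix's genes
(right tail, plain fraction; `(r+1)/(n+1)` smoothing optional).
Tail counts use a 1e-9 relative tolerance so statistics that tie the
observed value up to summation order count as ties.

## Networks

Co-expression: genes with expression < 1 in > 95% of samples are
dropped, as are constant genes; edges carry |Pearson r|, keeping the
top 1% by default (configurable). Interconnectedness of a gene set is
the plain sum of internal edge weights (weighted, as "sum of links"
does not specify binary; a binary count is one
`weight=1` preprocessing away). The permutation test draws 1000 sets
matched on a 5 × 5 cross of quantile bins of log-CDS × weighted degree
(bin counts are a package choice; sparse strata borrow nearest
neighbours, logged) and reports the fraction of sets *strictly* more
interconnected than the observed one. Louvain module detection runs
networkx's implementation 10 times with derived seeds at resolution 1
and keeps the best-modularity partition; `modularity` exposes the
weighted Newman quantity with resolution scaling. On graphs of ≤ 8
nodes the restarted Louvain matches exhaustive maximisation over all
set partitions in the suite's randomised fixtures.

## Enrichment and gene properties

Fisher tests are right-tailed hypergeometric via `scipy.stats.
fisher_exact`, cross-checked against full enumeration of tables in the
suite. Mann–Whitney comparisons use exact enumeration when
n_a·n_b ≤ 400 and the data are tie-free, and the tie-corrected normal
approximation otherwise. Extreme deciles take ⌊frac·n⌋ genes per tail
by max |z| with stable gene-id tie-breaking (a 960-gene screen yields
exactly 96 per tail). Constraint metrics keep their field conventions:
higher pLI/s_het/HIS and lower dN/dS/RVIS mean more constrained, and
one-sided tests default to the corresponding tail. The permuted-set
comparison contrasts the target's median score with medians of random
same-size draws. Gene-set panels are BH-adjusted within panel.

## Reproducibility and problem sizes

One global seed fans out to per-stage child seeds by SHA-256 hashing of
`"{seed}:{stage}"` (kept < 2³¹), so every stage is independently
reproducible and two runs of the same config produce byte-identical
outputs. All file formats are plain text (TSV with `NA` missing
markers, GMT, edge-list TSV, JSON).

The suite and the acceptance script run desk-scale versions of the
screen: type-I calibration on a 500-line × 48-parameter all-null
cohort (24 000 fits), the 100-permutation NAP-null comparison on a
150-line × 12-parameter cohort (the permutation stage multiplies cost
a hundredfold), FDR/sensitivity on ten 100-line × 48-parameter screens
with 10% planted severe lines, and permutation tests at their published
counts (1000 network/convergence permutations, 100 FDR permutations).
The published screen's headline numbers (198 NAP genes, category
percentages, per-gene effect sizes) derive from 6214 real animals and
are not reproducible from synthetic data; what the package demonstrates
is that the machinery is calibrated, powerful and exact where exactness
is claimed.
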