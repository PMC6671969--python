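# napmap

Statistical machinery for large-scale mouse neuroanatomical phenotyping
screens, as a tested, reusable Python library.

In such a screen, each mutant line (typically 3 biological replicates)
is measured against a large shared wild-type pool on ~118 brain
morphometric parameters — areas and lengths on stereotaxically defined
coronal and sagittal sections, grouped into six anatomical categories.
`napmap` implements the analysis stack end to end:

- **Association**: per (line, parameter) linear mixed model
  `y = β₀ + β₁·genotype + u_batch + ε` with a random intercept per
  necropsy date, fitted by profile maximum likelihood and tested with a
  likelihood-ratio statistic on an F(1, n−2) scale (exactly the pooled
  Student t-test when the batch variance vanishes). Lines on other
  genetic backgrounds are analysed separately with a two-sample t-test.
- **Multiplicity and FDR**: Benjamini–Hochberg adjustment across all
  testable (line, parameter) pairs; a gene is a *NAP* (NeuroAnatomical
  Phenotype) gene when any parameter has BH-p < 0.1. FDR control is
  verified empirically by re-running the whole caller on 100
  genotype-label permutations.
- **Calls**: severity bands on the largest significant |percent change|
  — mild [0, 10), moderate [10, 20), severe [20, 40), very severe
  [40, ∞) — direction classes (decrease / increase / bidirectional) and
  affected anatomical categories.
- **Imputation**: a multivariate-normal EM imputer (conditional-mean
  fills on empirically-shrunk genotype-adjusted residuals) completes
  gappy matrices for full-matrix downstream analyses.
- **Phenotypic similarity**: a simplified Goodall3 index over binarised
  abnormality profiles — a defect in feature k shared by two genes
  scores 1 − f_k², where f_k is the defect's frequency, so rare shared
  defects weigh most — plus a module phenotypic-convergence permutation
  test.
- **Gene networks**: co-expression construction (expression-level
  filter, Pearson edges), interconnectedness (sum of internal edge
  weights) tested against 1000 random gene sets matched for CDS length
  and connectivity, and Louvain module detection at resolution 1.
- **Enrichment and gene properties**: right-tailed Fisher exact tests,
  right-tailed Mann–Whitney comparisons of constraint metrics (dN/dS,
  s_het, RVIS, pLI, HIS) between extreme-phenotype deciles, and OLS
  regression of abnormality strength (max |z|) on constraint.
- **Synthetic screens**: a generator producing cohorts, networks,
  annotations and gene sets with known ground truth — the substrate for
  every test in the suite.

## Worked example

```bash
python examples/01_simulate_and_call.py
```

simulates a 60-line screen (20% of lines carry planted severe effects),
runs the caller and prints:

```
cohort: 260 animals x 24 parameters, 12 lines with planted effects
NAP lines called at BH<0.1: 13 (12 of them planted)
line_id    severity direction                    categories_affected
  L0001      severe  decrease                  brain_size;ventricles
  L0002      severe  decrease   brain_size;cerebellum_pons;subcortex
  L0003      severe  increase                     commissures;cortex
  ...
```

All 12 planted lines are recovered; `severity` is the band of the
largest significant percent change versus wild type, and `direction`
says whether the affected structures shrank, grew, or both. The other
scripts in `examples/` walk through imputation, Goodall3 similarity,
network interconnectedness/modules, enrichment, and the one-command
pipeline (`napmap run`, also available as a CLI with `simulate`,
`impute`, `call`, `similarity`, `converge`, `nettest`, `modules`,
`enrich` subcommands).

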