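# Methods

This note documents the models, estimators and numerical choices behind
`ferrostrat`, and what the bundled synthetic cohort does and does not
establish about real data.

## The stratification model

The package operates on a bulk RNA-seq cohort of Philadelphia-negative
B-ALL patients summarized as an FPKM matrix (genes × samples), with
companion tables of targeted-panel mutations, overall survival, and
CIBERSORT-style immune-cell fractions (consumed as input; deconvolution is
out of scope). The central object is a 24-gene ferroptosis panel
(ACSL4 … TFRC). Risk stratification is unsupervised:

1. each panel gene is min–max scaled to [0, 1] across samples (a constant
   gene maps to zeros, not NaN, so the downstream PCA stays defined);
2. samples are projected onto the top two principal components of the
   scaled panel (component signs fixed so the largest-magnitude loading is
   positive, making projections reproducible across linear-algebra
   backends);
3. K-means (k-means++ seeding, 10 restarts, tol 1e-6, ≤300 Lloyd
   iterations, seeded) partitions the 2-D projection. By default
   clustering happens in the projection, matching the stated order
   "standardize, then reduce, then cluster"; callers who prefer the full
   24-D space can simply pass the scaled matrix to `kmeans_fit`;
4. k is chosen by the elbow rule, operationalized as the argmax of the
   discrete second difference of the best-of-restarts inertia curve. The
   curve is anchored at k = 1 (total SSE about the grand mean) so an elbow
   at the lower end of the range is detectable. When the maximal second
   difference is below 5% of the total inertia drop the routine flags "no
   pronounced elbow" rather than inventing structure;
5. with k = 3, clusters are named High/Middle/Low risk by death proportion
   (descending), ties broken by the median follow-up of the deceased
   (dying sooner = higher risk).

### Clustering evaluation

ARI, AMI (arithmetic-mean normalizer, hypergeometric expected MI),
V-measure (β = 1), Fowlkes–Mallows, Silhouette and Calinski–Harabasz are
implemented from their contingency-table / dispersion definitions;
scikit-learn's versions serve as an independent cross-check in the test
suite, never as the implementation. External metrics need a reference
partition, and no ground truth exists for a real cohort, so
`evaluate_clustering` defaults to a *stability* reference: agreement
between the full-data labeling and re-clusterings of seeded 80%
subsamples. High stability scores mean the partition is reproducible under
perturbation — not that it is biologically correct. `reference_mode=
"truth"` (synthetic cohorts) and `"survival_labels"` are available when a
reference exists.

## Co-mutation networks

Two genes mutated in the same patient form an edge. `unique_pairs` counts
distinct pairs per group (the edges of a network figure); `instances`
counts every within-sample pair, Σᵢ C(mᵢ, 2). Both are divided by the
group's sample count to give a per-sample burden comparable across groups
of different sizes; summaries round half-up to two decimals (1.625 → 1.63),
matching how such figures are conventionally printed. The phrase "edges
per mutation" sometimes attached to this quantity is a misnomer — the
arithmetic divides by samples, and this package names it accordingly.
Mutated genes are annotated Fe-driver / Fe-suppressor / Fe-marker by
membership in the bundled role lists with precedence driver > suppressor >
marker; genes in none are Fe-negative. Driver burden between groups is
compared with Welch's unequal-variance t-test (safer than the pooled form
when group sizes differ; a pooled flag is not offered because the Welch
test dominates at these sizes). Gene symbols are never silently corrected:
a dubious symbol such as "PTEN11" stays as written, and callers can supply
an alias map at read time if they decide it means PTPN11.

## Expression scores

All log-based scores use log10(FPKM + pc) with pc = 1 by default. The
pseudocount is a package addition: summing log10 of raw FPKM is undefined
at zero, and +1 keeps every score finite and monotone. Setting pc = 0
recovers the raw-log arithmetic on strictly positive matrices.

* **Cytolytic** — mean over GZMA, GZMB, GZMH, GZMK, GZMM and PRF1. The
  five granzymes are configurable because granzyme panels vary between
  reports.
* **Inflammatory / IFN-γ / expanded-immune** — `signature_score(mean_log)`
  over editable GMT lists shipped with the package; the checkpoint-response
  lists are the 6- and 18-gene panels standard in the PD-1 blockade
  literature.
* **HLA summary** — mean log expression of HLA-A/B/C.
* **Microenvironment stand-in** — `mean_rank_z`: per-gene within-cohort
  rank z-scores averaged over the signature. This is a generic rank-based
  signature score, *not* ESTIMATE; it is exposed for exploratory contrasts
  only and labeled accordingly.
* **Sorafenib sensitivity** — log10(FLT3) − Σ log10(g) over MAPK1, MAPK3,
  GADD45G, MCL1, PINK1. Drug-associated genes are classified up / down /
  ns by two Welch tests (High vs Low, Middle vs Low, two-sided, α = 0.05,
  both comparisons required to agree). Concordance with cell-line potency
  is Spearman's ρ between score and log IC50; negative ρ is concordant.

Gene–immune relationships use Pearson correlation over shared samples
(≥ 3 required); cell types constant across the cohort (e.g. a population
undetected in every sample) are reported as missing columns, not dropped
silently.

## Differential expression

A deliberate stand-in for count-model DE: Welch t (or Wilcoxon) on
log2(FPKM + 1), fold change as the difference of group means on that
scale, Benjamini–Hochberg FDR across all tested genes. The choice is
recorded in the output metadata so results are never mistaken for a
negative-binomial fit; with only an FPKM matrix deposited, a count model
is not honestly fittable. Genes with zero variance in both groups get
P = 1 when means agree (and P = 0 in the vanishing-variance, distinct-means
corner). DEG thresholds are strict inequalities (|log2FC| > 1, FDR < 0.05
by default). Ferroptosis enrichment counts DEGs per role set, multi-role
genes counted once under the driver > suppressor > marker precedence
(`count_in_each` disables the precedence).

## Survival modeling

Covariates enter Cox models as z-scored log10(FPKM + 1); the L1 penalty
requires commensurate scales, and the transform (means, SDs) is frozen on
the development cohort and reapplied verbatim to validation samples.

* **Partial likelihood** — Efron tie handling throughout (follow-up at
  months resolution ties often). The implementation is fully vectorized
  over event times via suffix cumulative sums and tie-block corrections.
* **Newton–Raphson** — convergence on the score norm (tol 1e-8), ≤ 50
  iterations, step-halving on any likelihood decrease. Fits that hit a
  singular Hessian or exhaust iterations are flagged, and the univariate
  screen excludes them with a warning. The screen retains genes with Wald
  P < 0.1 and warns below 10 events.
* **LASSO** — objective −pl(β)/n + λ‖β‖₁, minimized by an outer quadratic
  approximation with inner cyclic coordinate descent (soft-thresholding),
  warm-started along a 100-point log-spaced path from λ_max (the smallest
  penalty with the all-zero optimum) down to 0.01 λ_max, with
  step-halving on the exact penalized objective. λ is selected by 5-fold
  event-stratified cross-validation of the Verweij–van Houwelingen partial
  likelihood deviance. Two selection rules are exposed: `"min"` (default;
  deviance-minimizing, prediction-optimal) and `"1se"` (largest λ within
  one SE of the minimum). The rules answer different questions: λ_min
  predictably carries a few small-coefficient extras, so when the question
  is *which genes belong in the model* the 1-SE rule is the appropriate
  estimator, and the package's support-recovery properties are stated and
  tested under it. Both λ values are reported on every fit.
* **Split** — 70/30, event-stratified, seeded; a part with zero events is
  an error because nothing downstream is estimable there.
* **Evaluation** — Kaplan–Meier curves and the log-rank test via
  lifelines; time-dependent AUC via scikit-survival's IPCW
  cumulative/dynamic estimator (the same estimator family as the R
  timeROC default); horizons with no prior events report NaN rather than
  raising. Risk is dichotomized at the development-cohort median for KM
  (configurable by passing any strata). Calibration bins samples by
  score quantiles and compares the mean model-predicted survival
  (Breslow baseline, S(t|x) = exp(−H₀(t)·e^score)) with the within-bin
  KM estimate; tied scores may collapse bins, and an all-equal score
  vector degenerates to one bin whose prediction is the overall
  exp(−Nelson–Aalen) level.

## The synthetic cohort

`simulate_cohort` emulates the *statistical structure* of an 80-patient
cohort in three latent risk groups (25/39/16 by default), not any real
patient data:

* **Expression** — per gene, log10-FPKM ~ Normal(group mean, σ = 0.3),
  exponentiated. The 24 panel genes split into three blocks of eight;
  block *b* is shifted up by `frg_shift` (default 1.0 log10) in group *b*,
  the simplest geometry that makes min–max + PCA + K-means separable with
  three distinct centroids. Background genes (400 by default) share one
  global mean. A small dictionary of named genes (`extra_group_shifts`)
  plants the patterns the scoring stages analyze: FLT3 up in High/Middle
  and the five negatively-signed Sorafenib genes mildly up in Low;
  granzymes/PRF1/HLA and an inflammatory program up in Low;
  checkpoint-response signature genes deliberately unshifted (the
  no-difference pattern).
* **Counts** — library sizes ~ U{1.5e7, 2.5e7}, transcript lengths ~
  U{500, 5000}; fragment counts are the rounded inversion of the FPKM
  formula, and the cohort's expression matrix is recomputed *from those
  integer counts*, so counts → FPKM reproduces it exactly.
* **Survival** — Weibull (shape 1.2) with multiplicative group hazards
  4:2:1 and the baseline anchored so the Middle group's median OS is 24
  months; censoring is independent uniform administrative, with the
  horizon solved numerically so the expected censored fraction equals
  `censoring_rate` (0.3 default). Times are rounded to 0.1 months, which
  deliberately produces ties to exercise the Efron machinery.
* **Mutations** — per-sample burden ~ Poisson(rate_g) with rates
  (3.5, 2.0, 1.8), giving expected per-sample pair counts near the
  observed group burdens; driver content ~ Binomial(m, p_g) with p =
  (0.6, 0.4, 0.2), drawn without replacement from driver and background
  pools so (sample, gene) pairs are unique and the per-group driver
  fraction converges to p.
* **Immune fractions** — Dirichlet per group over the 22 LM22 cell types
  with concentrations skewed toward B-lineage expansion in High/Middle and
  a myeloid-rich profile in Low; "Dendritic cells resting" has
  concentration 0 everywhere (a cell type undetected in all samples, which
  exercises the constant-column handling). Two samples receive a failing
  deconvolution P-value, reproducing the 80 → 78 quality-gate attrition.
* **Seeding** — one RNG stream per modality, spawned from the master seed:
  a fixed seed gives byte-identical cohorts, and changing one modality's
  parameters does not perturb the draws of the others.

### What the synthetic cohort does not show

The generator has no gene–gene co-expression beyond the block structure,
no copy-number or fusion events, no batch effects, and the immune
fractions are exact simplex draws rather than deconvolution estimates with
their correlated errors. Passing tests therefore demonstrate that the
*procedures* are implemented correctly and recover planted structure under
clean conditions; they do not certify performance on real cohorts, and the
published cohort-specific quantities (the 8-gene model's AUCs of
0.716/0.924, specific DEG lists, specific correlation coefficients) depend
on undeposited clinical data and are outside what any reimplementation can
verify.

## Problem sizes used in checks

The automated checks run clustering recovery on 20 cohorts of n = 80,
univariate Cox recovery on 50 replicates of n = 500 with ~30% censoring,
LASSO support recovery on 10 replicates of the 2-true/6-null design at
n = 300, and score-ordering on 20 cohorts; these sizes give the binomial
pass-criteria comfortable margins while keeping a full run in the
low minutes on one CPU.

## Known limitations

* The DE stage is not a count model and will not reproduce edgeR gene
  lists even given identical data.
* The rank-based microenvironment score is not ESTIMATE and its values are
  not comparable to ESTIMATE scores.
* The bundled role and signature GMTs are small curated stand-ins
  (filenames say so); analyses of real cohorts should substitute the
  current full databases.
* Whether clustering in the 2-D projection or in the 24-D scaled space is
  preferable is cohort-dependent; both are one call away, and the default
  is the projection.
* The elbow rule is a heuristic; the six-metric report exists precisely so
  a k choice can be defended on more than the inertia curve.
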