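# Methods

This document defines the statistical methods implemented in `corrbreak`
and records the deliberate design choices in the numerics. Everything here
runs at desk scale (hundreds of individuals, hundreds of markers) on a
single CPU.

## 1. Synthetic study generator (`simdata`)

A founder population is simulated at scaffold-structured SNP panels
(default 60 scaffolds × 6 SNPs, 10 kb each) with founder allele frequencies
drawn uniformly from the configured MAF range. Distance-dependent LD is
created mechanistically: 30 generations of finite-population random mating
with Poisson-distributed crossovers placed uniformly within each scaffold.

Four traits (BR9, ST9 on a 1–9 ordinal scale; DBH, WD continuous) are
driven by sparse QTL effects. The adverse DBH–WD correlation comes from two
sources with separate knobs: pleiotropic QTLs with antagonistic effects on
three designated scaffolds, and linked QTL pairs in repulsion. Genetic and
residual variances are solved analytically from the heritability and
genetic-correlation targets before any noise is drawn; nothing is rescaled
post hoc, so realized parameters vary around their targets exactly as they
would in a real study of this size.

Cohorts mirror a two-strategy breeding program:

* **POP1GF** — offspring of growth-and-form–selected parents.
* **POP1HD** — offspring of tandem-selected parents (growth first, then
  wood density), put through extra intermating generations with a
  recombination-rate multiplier. These are the labelled *breakers*.
* **POP2GF** — an independent factorial-mated prediction cohort with no
  breaker ancestry.

Tandem selection (`tandem_select`) is the literal two-stage truncation:
keep the top *n₁* on the growth index, then the top *n₂* of those on the
density index; it raises an error when *n₂* > *n₁*. Selection pushes the
antagonistic pleiotropic loci toward intermediate frequencies (elevated
local heterozygosity) while directional selection plus drift depresses the
breakers' genome-wide heterozygosity — the signature the downstream
analysis looks for. Clonal replication (copies per clone across sites,
replicates and sets/blocks) provides the design structure the mixed model
needs.

## 2. Genotype I/O and QC (`genio`)

Dosage tables are TSV with individuals in rows and markers in columns;
entries are expected in [0, 2] with blanks/`NA` as missing. VCF ingest
(optional `cyvcf2` dependency) keeps biallelic SNPs only and counts skipped
records. QC applies a **strict** MAF filter (a marker is retained only if
MAF > threshold, so a marker at exactly the threshold is dropped) followed
by per-marker mean imputation; the imputed-cell mask is retained so that
heterozygosity calculations can exclude imputed calls.

## 3. Relationship matrices and heterozygosity (`kinship`)

* **A** — the numerator relationship matrix from the tabular method on a
  chronologically sorted pedigree; pedigree cycles raise an error.
* **G** — VanRaden method 1, `G = WW' / (2 Σ p(1−p))` with `W` the
  frequency-centred dosage matrix. Monomorphic markers and missing values
  must be removed first (the function refuses them rather than silently
  degrading). For downstream inversion G is blended with identity at
  weight 0.99.
* **IBS** — mean over hard-called markers of `1 − |gᵢ − gⱼ| / 2`, which
  lives in [0, 1] with self-similarity 1.
* **Observed heterozygosity (Ho)** — the per-individual fraction of
  heterozygous calls among its non-imputed markers. The cohort contrast
  (`het_resample_test`) resamples equal-sized subsets of both cohorts many
  times and runs a t-test on the replicate means. The replicate means are
  not independent draws (the same individuals recur across replicates), so
  the test is anti-conservative; it is implemented this way deliberately,
  as a descriptive resampling contrast, and the caveat is noted here and in
  the API docs. Interpret the t statistic as an effect-size summary, not a
  calibrated p-value.
* **PCA** — eigen-decomposition of the chosen relationship matrix; used
  for cohort-structure visualization.

## 4. Linkage disequilibrium (`ldtools`)

* **Composite r²** — squared Pearson correlation of dosages, the standard
  genotype-level composite LD measure that requires no phasing.
* **Relatedness-corrected r²** — the generalized-least-squares form
  `r²_V = (x' V⁻¹ y)² / ((x' V⁻¹ x)(y' V⁻¹ y))` on centred dosages with
  `V` a (blended) relationship matrix. Although often written with an
  unsquared `r̂_V` notation, the ratio itself is the squared quantity, and
  that is what is returned. With `V = I` it reduces exactly to the
  composite r² — this identity is a tested invariant. Family structure
  inflates composite r² between unlinked loci; the corrected form removes
  that inflation, so corrected significant fractions should not exceed
  uncorrected ones.
* **Hill–Weir decay** — the expected-r² curve for sample size *n* as a
  function of the recombination-scaled distance `C = β·d`, including the
  finite-sample terms; its large-distance asymptote is `1/n`, and at
  `C = 0, n = 100` it evaluates to 0.4620. `fit_hill_weir` estimates the
  per-bp β by multi-start nonlinear least squares (starts spanning
  10⁻⁵–10⁻²) and `decay_distance` reports where the fitted curve crosses a
  threshold (r² = 0.2 by default), returning `None` when the curve never
  reaches it.
* **Jennrich test** — the χ² test for equality of two correlation matrices
  with unequal sample sizes; requires at least 3 markers, and the statistic
  is floored at 0 against round-off. `compare_populations` runs it per
  scaffold in both uncorrected and corrected modes, restricted to markers
  usable in both cohorts, and reports significant fractions plus failure
  counts.

## 5. Multivariate mixed model (`mtmm`)

The model for the stacked trait-major data vector is

```
y = X b + Σ_k Z_k u_k + e,   u_k ~ N(0, Σ_k ⊗ K_k),   e ~ N(0, R₀ ⊗ I)
```

with one unstructured t×t covariance Σ_k per random term (additive with a
pedigree or genomic K, plus design terms such as set/block with K = I) and
an unstructured residual R₀. Phenotypes are standardized within site
before fitting.

**REML.** The solver works on the mixed-model equations rather than the
dense n·t × n·t covariance; a unit test verifies the MME-based −2·log-
likelihood against the textbook dense form `log|V| + log|X'V⁻¹X| + y'Py`
to 10⁻⁶. Optimization is expectation–maximization (EM) warm-up followed by
average-information (AI) updates with a ridge and step-halving, falling
back to an EM step whenever the AI step fails to improve the likelihood.
Monotonicity of EM steps is asserted (with numerical slack) as an internal
correctness check.

Three numerical design points deserve explanation:

* **PSD flooring.** Updated covariance components are projected onto the
  positive-semidefinite cone with a consistent relative/absolute
  eigenvalue floor. This matters because boundary solutions are *routine*
  here, not exceptional: a design term with fewer levels than traits (for
  example 3 replicates and 4 traits) has a structurally rank-deficient Σ
  at any optimum.
* **Over-relaxed EM.** On such boundary ridges plain EM crawls
  geometrically and AI steps are perpetually rejected. When the AI step
  fails, the solver therefore also tries longer steps along the EM
  direction (step multipliers 16, 8, 4, 2) and keeps the first that beats
  the plain EM step. This is guarded — a candidate is only accepted on an
  actual likelihood improvement — so monotonicity is preserved.
* **Stopping rule.** Convergence is declared after 5 consecutive
  iterations (patience) without a likelihood improvement exceeding
  `max(tol, 10⁻⁷·|ℓ|)`, and the best-likelihood state seen is returned.
  The default iteration cap is 500: near-boundary fits have been observed
  to need ~220 iterations before the patience rule fires, and at roughly
  10 ms per iteration at desk scale a generous cap is the right trade-off.
  Exceeding the cap raises `ConvergenceError` carrying the likelihood
  trace.

**Derived quantities.** Heritability is reported as
`h² = σ²_a / (σ²_a + σ²_e)` per trait — non-additive and design variances
are deliberately excluded from the denominator even though the model
contains them, matching common breeding-program reporting; this is a
documented convention, not an oversight. Genetic correlations are
`r_g = σ_a(x,y) / √(σ²_a(x) σ²_a(y))`, reported as NaN when an additive
variance is numerically zero. Standard errors come from the delta method
on the inverse average-information matrix (NaN when the AI matrix is
unavailable). EBVs are the additive BLUPs from the final solve.

## 6. G-matrix comparison (`gcompare`)

* **Krzanowski subspace similarity** compares the leading
  `k = ⌊t/2⌋ − 1` eigenvectors of two genetic covariance matrices (k must
  be ≥ 1, so t ≥ 4); it is 1 for identical subspaces and 0 for orthogonal
  ones.
* **Random skewers** applies many random unit selection gradients to both
  matrices and summarizes the distribution of response-vector
  correlations. With t = 4 each correlation is computed from 4-length
  vectors, a very small sample for a Pearson correlation; the mean over
  many skewers is the meaningful summary, individual correlations are
  noisy by construction.
* **Selection-response decomposition (SRD)** reports per-trait agreement
  scores and their variances across skewers, flagging which traits drive
  any divergence; traits with zero response get NaN rather than a
  fabricated score.

## 7. Breaker prediction (`breakerpred`)

Breaker status is modelled by logistic GBLUP: a logit-link GLMM with an
animal effect `u ~ N(0, σ²_u G)`, fitted by penalized quasi-likelihood
(iteratively reweighted least squares on the working response). Scores for
unobserved individuals use the conditional mean
`u_new = G_{new,train} G_{train,train}⁻¹ û` and the inverse-logit link
(the inverse logit is the assumed back-transformation).

**Cross-validation.** Leave-one-individual-out and leave-one-family-out
schemes refit the random effects per fold. Held-out folds are scored with
the **full-data intercept** rather than the fold's own: the fold intercept
is a deterministic function of the held-out labels (leave-one-out mean
leakage), which under a label-permutation null anti-correlates scores with
labels and drives AUC toward 0. Using the full-data intercept — a single
scalar shared by every fold, shifting all scores monotonically — removes
the leakage without touching the per-fold genetic effects, and restores
AUC ≈ 0.5 under permuted labels.

**Metrics.** AUC is the exact Mann–Whitney statistic with midranks for
ties. Classification of new individuals flags scores **strictly above** the
chosen percentile (default 95th) of the training-score distribution.

## 8. Pipeline (`pipeline`)

`run(PipelineConfig)` executes: simulate → QC → cohort assembly →
relationship matrices and PCA → heterozygosity contrasts (genome-wide and
inside LD-significant scaffolds) → LD decay + Jennrich comparison →
per-cohort REML and genetic parameters (skippable) → G-matrix comparison →
breaker prediction with LOO validation → `summary.json` and a
human-readable `report.md` (plus optional PNG plots). Cohort genomic
matrices are built after re-filtering monomorphic markers *within* the
cohort, since a marker polymorphic overall can be fixed in a subset. All
randomness flows from two seeds recorded in the summary: the simulation
seed and an analysis seed.

## Limitations

* The resampling heterozygosity t-test treats replicate means as
  independent (see §3); use it descriptively.
* Delta-method SEs for r_g are first-order and can be optimistic near
  |r_g| = 1 or near-zero additive variances.
* Hill–Weir fitting assumes a single genome-wide β; per-scaffold
  heterogeneity is averaged over.
* PQL is known to bias variance components for binary traits with small
  cluster sizes; the classifier is used for ranking (AUC), where this
  matters little.
* Desk-scale defaults (hundreds of individuals/markers) are not tuned for
  genome-scale data; the dense linear algebra scales cubically.
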