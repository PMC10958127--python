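# Methods

`lsca` implements a cell-type-abundance route to prognosis in acute myeloid
leukemia (AML): instead of scoring patients on the expression of individual
genes, it estimates the composition of each patient's bulk transcriptome in
terms of nine flow-sorted hematopoietic populations and models overall
survival on those composition fractions. This note records the models, the
numerical choices, and what the synthetic benchmarks do and do not show.

## 1. The nine-population reference and signature matrix

The reference vocabulary is nine sorted populations spanning the normal and
leukemic hematopoietic hierarchy: AML blasts, common myeloid progenitors
(CMP), granulocyte–monocyte progenitors (GMP), megakaryocyte–erythrocyte
progenitors (MEP), hematopoietic stem cells (HSC), multipotent progenitors
(MPP), leukemic progenitor cells (LPC), leukemic stem cells (LSC), and
CD45RA+ Lin−CD34+CD38−CD90− cells from healthy donors (RApos).

Marker genes are nominated per population by one-vs-rest differential
expression on log2 profiles. The test is the empirical-Bayes moderated t:
gene-wise pooled variances s²_g (d_g residual df) are shrunk toward a prior
(d₀, s₀²) fitted by moment-matching the marginal distribution of log s²_g
(digamma/trigamma moments; trigamma inverted by Newton iteration), giving
posterior variances (d₀s₀² + d_g s²_g)/(d₀ + d_g) and t statistics with
d₀ + d_g degrees of freedom. An ordinary two-sample t is available for
cross-checks; the moderated version is validated against the limma
implementation in the test suite.

Selection thresholds: log2 fold change ≥ 1 and Benjamini–Hochberg adjusted
p ≤ 0.05, with per-type overrides for sparse populations
(LSC 0.1, RApos 0.1, MPP 0.2 in `PUBLISHED_ADJP_OVERRIDES`); genes are ranked
by descending fold change (ties: ascending adjusted p, then gene id) and
capped at a per-type top-N (N ∈ {25, 50, 100, 150}; 50 is the working
default downstream). The signature matrix stores per-type **median linear
expression** of the selected markers — fold changes are computed in log
space (the microarray convention) while mixing is linear, so the two scales
are never conflated. Genes selected for more than one population are
recorded; they may be kept (default) or dropped (`shared_policy`).

## 2. Deconvolution

Bulk expression is modeled as a non-negative mixture of the signature
columns, `b ≈ S f`, solved per sample on the signature/bulk gene
intersection in linear scale (log2 input is exponentiated with a warning):

* **NNLS** — `min ‖S f − b‖₂, f ≥ 0` (Lawson–Hanson via SciPy), then
  normalized to the simplex. Transparent, exactly invertible on noiseless
  full-rank mixtures; the baseline of the benchmark.
* **ν-SVR** — the support-vector formulation used by CIBERSORT-style
  tools: the signature (globally) and each mixture vector are z-scored, a
  linear-kernel ν-SVR (C = 1) is fitted for ν ∈ {0.25, 0.5, 0.75}, the ν
  with the lowest reconstruction RMSE wins, negative weights are clipped
  and the remainder renormalized. No quantile normalization, no batch
  correction, no absolute mode.

Recovery is evaluated as the per-population Pearson correlation between
true and inferred fractions across a pseudo-bulk cohort (zero-variance
columns report a missing correlation, never 0), plus per-sample residual
RMSE.

## 3. The prognostic score

Given a fraction matrix F (samples × populations) and overall survival
(time, event), the score weights come from L1-penalized Cox regression:

    minimize −(1/n)·pll(β) + λ‖β‖₁,

with the Breslow partial likelihood, solved by outer
iteratively-reweighted least squares around the current linear predictor
and inner cyclic coordinate descent with soft-thresholding (exact zeros).
Implementation details chosen to mirror the glmnet family, the toolchain
this procedure is normally run with:

* λ grid: 100 log-spaced points from λ_max = max_j |(1/n) x_jᵀ u(0)| down
  to 10⁻⁴·λ_max (10⁻²·λ_max when p ≥ n);
* path truncation: the sequence stops once the explained fraction of the
  null deviance improves by less than 10⁻⁵ (absolute increment) or
  exceeds 0.999 — verified to reproduce glmnet's sequence lengths;
* cross-validation: 10-fold, criterion = held-out partial-likelihood
  deviance in the Verweij–Van Houwelingen form
  −2·(ll_all(β₋k) − ll₋k(β₋k)), candidate λs restricted to the truncated
  full-data path, λ_min = argmin; folds are re-randomized with at least
  one event per fold (bounded retries);
* the reported coefficient vector at λ_min is the warm-started path
  solution (a cold restart can flip borderline zeros);
* convergence: inner sweeps stop at max coefficient change < 10⁻⁷; the
  outer loop at < 10⁻⁵ (or an objective stall). Fraction covariates share
  the [0, 1] scale and enter unstandardized by default. A numba-compiled
  path kernel and a pure-NumPy reference implementation coexist; tests
  assert they agree, and fixed-λ solutions match R glmnet to ~10⁻³.

Because the fractions are compositional (rows sum to 1), the partial
likelihood is invariant to adding a constant to all coefficients; the L1
penalty resolves this by picking the minimum-‖·‖₁ representative, which is
also why exact zeros are meaningful here.

**Stability selection.** A single CV-selected lasso fit is unstable at
p = 9 with correlated compositional covariates, so the fit is repeated
(default 100 rounds), each round on a bootstrap resample of the patients
with fresh folds. Populations whose coefficient is exactly zero in
strictly more than `zero_limit` rounds (default 5 of 100, i.e. a 5%
rejection fraction) are discarded; each retained population's final weight
is the mean of its per-round coefficients, zeros included (an option
averages non-zero rounds only). Bootstrap resampling, not fold
re-randomization alone, is essential: with the data fixed, the rounds are
nearly perfectly correlated and zero counts collapse to 0 or n_iter,
defeating the filter. When the procedure is run at reduced round counts
(e.g. 25 in the test suite), `zero_limit` should be scaled proportionally
(drop at ≥ 2 zeros of 25) to preserve the operating point.

The packaged published model carries the five-population weight vector

    score = −2.15·F_GMP − 1.64·F_CMP + 0.37·F_RApos + 0.49·F_MEP + 4.52·F_MPP

and scoring is the plain dot product of weights with a patient's fraction
vector. Cohorts are split into high/low groups at the median score
(composite scores) or the mean (single-population abundances, whose median
is often 0).

## 4. Survival validation

Standard estimators, delegated to lifelines / scikit-survival behind the
package's containers: Kaplan–Meier product-limit curves per group; the
two-group log-rank χ² test; multivariate Cox proportional hazards with
Efron tie handling, Wald 95% CIs (exp(β ± 1.96·se)) and Wald p per
covariate, categoricals expanded against declared reference levels
(sex = Female, cytogenetic risk = Favorable); and cumulative/dynamic
time-dependent AUC with inverse-probability-of-censoring weights from the
KM estimate of the censoring distribution (with no censoring this reduces
to the Mann–Whitney statistic; horizons with no cases or no controls
report NaN). Two scores are compared per horizon by a paired patient
bootstrap of the AUC difference with an add-one two-sided p — an
approximation to the analytic comparison tests, documented as such.
Cytogenetic-risk labels are harmonized on input
("FavorableOrIntermediate" → Favorable, "IntermediateOrAdverse" →
Intermediate, "Adverse" → Poor).

## 5. Gene-set enrichment

Single-sample enrichment follows the GSVA construction: per gene, a
Gaussian kernel CDF across samples (bandwidth = sd/4; Poisson kernel
available for counts) expresses each sample's relative expression; per
sample, genes are ranked by that statistic (ties broken by stable gene
order) and a KS-like random walk over the ranked list — inside-set steps
weighted by |p/2 − rank|^τ (τ = 1), outside-set steps 1/(p − |set|) —
yields the ES as max-positive + max-negative deviation (`max_diff`,
default) or the single largest deviation (`max_dev`). Sets with no gene in
the matrix are skipped and reported, not scored. The implementation is
checked against a literal hand-executed walk and against the gseapy
implementation. Note the ES is invariant to per-gene positive affine
transforms (the bandwidth scales out) but not to arbitrary monotone
transforms, which reorder the kernel statistics across genes.

Downstream: PAM (k-medoids, BUILD + best-improvement SWAP, Euclidean
distance on ES profiles, deterministic with index tie-breaks) clusters
samples; Fisher's exact test (two-sided, probability-mass convention;
sample odds ratio with symbolic inf/NaN for empty cells) measures
concordance between score groups and clusters; Pearson correlation
matrices over gene sets + scores carry BH-adjusted p-values across the
upper triangle; and per-set high-vs-low group contrasts reuse the
moderated t with sets as rows. The group contrast is reported as a
**difference of mean ES** (`es_diff`): ES values are signed, so a literal
fold-change ratio is undefined — heatmap-style "log2 fold change" labels
elsewhere correspond to this difference.

## 6. Synthetic data

The generator produces every input with known truth, as the study
conditions the tests assume:

* **Reference profiles**: log2 scale; per-gene baselines N(5, 1) shared
  across populations (heterogeneous constitutive expression — with a
  constant baseline the signature becomes structurally rank-deficient
  under the SVR route's z-scoring + intercept); each population's disjoint
  block of 50 markers elevated by +2 log2 units; 4 replicates per
  population with N(0, 0.25²) noise.
* **Fractions**: i.i.d. Dirichlet(α = 1) rows (uniform on the simplex),
  α configurable.
* **Pseudo-bulk**: per-population linear-scale medians mixed by the
  fraction matrix (bulk = M·Fᵀ); mixing is linear because proportions are
  only additive in linear expression units.
* **Survival**: exponential proportional hazards with
  η = Σ β_c F_c and rate exp(η)/baseline_scale (baseline_scale = 1000
  time units ≈ days); censoring uniform on [0, c] with c solved by
  bisection on the realized sample so the censored share matches the
  target (default 30%, a typical AML-cohort order).
* **Gene sets**: disjoint sets drawn from non-marker genes; group-wise
  signal planted as a ±δ log2 shift in one sample group.

Every generator is a pure function of (design, seed); cohort stages derive
seeds from one master seed by fixed offsets.

What this emulates — and does not. The synthetic cohorts have exactly the
generative structure the methods assume: mixtures are exact linear
combinations of the reference medians, survival follows proportional
hazards in the true fractions, and planted markers are disjoint. Real
cohorts violate all of these (probe effects, batch structure, cell types
outside the reference, non-PH hazards, microenvironment signal), so
passing benchmarks demonstrates correctness of the implementations and
identifiability under the stated model, not clinical performance.

## 7. Problem sizes used by the test and acceptance runs

Defaults were scaled for single-CPU runs: reference designs of 600–1000
genes with 30–50 markers per population, 100-sample pseudo-bulk cohorts,
n = 400 survival cohorts, stability selection at 25 rounds with the
proportionally scaled zero limit (full-scale defaults: 100 rounds,
limit 5), 2000-replicate calibration nulls, and 200–1000-draw bootstraps.
The end-to-end smoke test runs the entire chain from one seed in a few
minutes.

## 8. Known limitations

* The ν-SVR route reproduces the published algorithmic recipe, not any
  specific web-tool build; equivalence is asserted at the level of the
  recovery benchmark.
* `compare_auc` is a bootstrap approximation, not the analytic
  iid-decomposition test.
* The stability-selection filter's behavior depends on the bootstrap
  operating point; at reduced round counts the proportional zero-limit
  scaling above is the supported configuration.
* No probe-level microarray structure, batch effects, or lymphoid
  populations are simulated; gene identifiers are matched verbatim
  (case-sensitive after whitespace trimming) with no alias resolution.
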