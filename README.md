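# lsca — cell-type-abundance prognostic scoring for AML

Prognostic models for acute myeloid leukemia (AML) usually score patients
on the expression of a handful of genes. `lsca` implements the
composition-based alternative: estimate how much of each patient's bulk
transcriptome comes from nine flow-sorted hematopoietic populations
(AML blasts, CMP, GMP, MEP, HSC, MPP, LPC, LSC, and CD45RA+ cells), then
model overall survival directly on those population fractions. It is aimed
at computational hematology groups who want the whole chain — signature
construction, deconvolution, penalized survival modelling, validation,
enrichment — as a tested, scriptable package rather than a pile of web
tools.

The pipeline:

1. **Signature** (`lsca.signature`) — one-vs-rest empirical-Bayes moderated-t
   differential expression on sorted reference profiles (log2FC ≥ 1,
   BH-adjusted p thresholds with per-type overrides, top-N cap) → a
   marker-genes × 9-populations matrix of median linear expression.
2. **Deconvolution** (`lsca.deconv`) — per-sample mixture regression of bulk
   expression on the signature: non-negative least squares, and
   CIBERSORT-style linear ν-SVR (ν ∈ {0.25, 0.5, 0.75} chosen by
   reconstruction RMSE, negatives clipped, simplex-normalized).
3. **Score model** (`lsca.model`) — L1-penalized Cox regression of survival
   on the fractions (Breslow partial likelihood, coordinate descent with
   exact zeros, glmnet-style λ path + 10-fold CV), wrapped in stability
   selection: 100 bootstrap rounds, populations zeroed in more than 5
   rounds are dropped, retained coefficients are averaged. The resulting
   score is a sparse linear functional of the fraction vector:

       score = Σ_c β_c · F_c

   The packaged published model (`lsca.published_model()`) carries

       score = −2.15·F_GMP − 1.64·F_CMP + 0.37·F_RApos + 0.49·F_MEP + 4.52·F_MPP

4. **Survival validation** (`lsca.surveval`) — Kaplan–Meier curves,
   two-group log-rank, multivariate Cox (hazard ratios with Wald 95% CIs),
   IPCW time-dependent AUC, and a paired-bootstrap AUC comparison.
5. **Enrichment** (`lsca.enrich`) — GSVA-style single-sample enrichment of
   LSC-program gene sets (Gaussian kernel CDF + weighted KS random walk),
   PAM clustering of enrichment profiles, Fisher's exact concordance with
   score groups, correlation matrices, and moderated-t group contrasts.
6. **Synthetic data** (`lsca.synth`) — generates every input with known
   ground truth (reference profiles with planted markers, Dirichlet
   fractions, pseudo-bulk mixtures, proportional-hazards survival, planted
   gene-set signal), so the whole chain is testable without any cohort
   download.

See `docs/methods.md` for the models, parameter meanings and defaults,
numerical choices, and what the synthetic benchmarks do and do not show.

## Worked example

Simulate a 200-patient cohort whose survival is driven by the published
coefficients, rebuild a signature from sorted profiles, deconvolve, train
a scaled-down stability selection (25 bootstrap rounds, zero-limit scaled
to 1), and validate the score:

```python
import numpy as np
import lsca

design = lsca.SyntheticDesign(n_genes=1000, markers_per_type=50,
                              n_mixtures=200, seed=42)
cohort = lsca.simulate_cohort(design, censor_rate=0.3)

sig = lsca.build_signature(cohort.profiles, cohort.labels,
                           adjp_overrides=lsca.PUBLISHED_ADJP_OVERRIDES, top_n=50)
fractions, _ = lsca.deconvolve_svr(sig, cohort.bulk)

result = lsca.StabilityLassoCox(fractions, cohort.survival,
                                n_iter=25, zero_limit=1).fit(seed=42)
print(result.summary().round(2))

scores = lsca.compute_score(result, fractions)
grouped = lsca.split_by_threshold(scores, method="median")
chi2, p = lsca.logrank_test(cohort.survival, grouped["group"])
print(f"log-rank chi2 = {chi2:.2f}, p = {p:.2e}")
```

Output:

```
           coefficient  zero_count  retained  coef_sd
cell_type
AML_blast          NaN          11     False     0.69
CMP                NaN          16     False     0.69
GMP                NaN           8     False     0.80
HSC                NaN          13     False     0.57
LPC                NaN          12     False     0.39
LSC                NaN          16     False     0.60
MEP                NaN           8     False     0.75
MPP               2.86           0      True     1.04
RApos              NaN           7     False     1.07
log-rank chi2 = 14.84, p = 1.17e-04
```

Reading it: deconvolution recovers the generating fractions essentially
exactly on this noiseless benchmark (per-population Pearson r = 1.00, from
`lsca.evaluate_fraction_recovery`), and stability selection retains MPP —
the population with the largest generating weight (+4.52) — with a mean
coefficient of +2.86 and no zero rounds, while the weaker effects are not
separable at n = 200 and are filtered out. The median split of the
resulting score separates survival (log-rank p ≈ 1.2×10⁻⁴), and the
time-dependent AUC at the 25/50/75% follow-up quantiles is 0.59/0.67/0.67.

The same chain is scriptable from the shell via the `lsca` command
(`lsca simulate cohort`, `lsca signature build`, `lsca deconv run`,
`lsca model train/score`, `lsca validate`, `lsca enrich`).

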