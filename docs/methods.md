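# Methods

`mpscore` implements a molecular prognostic score (mPS) system for bulk tumor
expression cohorts with overall-survival follow-up, together with the full
construction pipeline that produces such a system and the survival analyses
used to evaluate it. This note records the models, the defaults and the
numerical choices, and what the synthetic-data tests do and do not establish.

## The score

A panel is a list of genes, each with a favorable expression state and a
positive weight. For a sample *s* and panel gene *g*,

    GeneScore_g(s) = 1  if expression_g(s) is in gene g's favorable state
                     0  otherwise
    mPS(s) = Σ_g GeneScore_g(s) · weight_g

The expression state is dichotomized at the gene's median expression in the
reference cohort; samples exactly at the median fall in the low state. The
favorable state of a gene is the side of the median associated with lower
hazard: genes whose median-split hazard ratio (high vs low expression) is
below 1 are favorable when high (`score_high = 1`), genes with HR > 1 are
favorable when low (`score_low = 1`); HR exactly 1 is tie-broken to
`score_low = 1` and logged. Under this convention a **higher mPS predicts
longer survival**, consistent with the published multivariate hazard ratio of
0.46 for high- vs low-scoring patients on the bundled 21-gene ccRCC panel.
(The inverse orientation — scoring the unfavorable state — appears in some
descriptions of this family of scores but contradicts that hazard ratio; the
orientation here is a single documented constant.)

The bundled ccRCC panel (`mpscore/data/panel_ccrcc21.tsv`, loaded by
`load_published_panel()`) carries 21 genes with weights between 3.009 and
4.217 and a total weight of 74.616. Its published strata are

    low: mPS < 22      median: 22 ≤ mPS < 30      high: mPS ≥ 30

with a two-group variant (split at 22) for small cohorts. Bins are half-open
`[lower, upper)` and the top bin is closed above by +∞. These thresholds are
constants of that panel's weight scale; a freshly trained panel has an
arbitrary scale, so for new panels the package derives thresholds from score
quantiles (`StratificationScheme.from_quantiles`, pipeline syntax
`--strata q:0.33,0.66`). When scoring a new cohort the median cutoffs are by
default recomputed within that cohort; a `MedianReference` carries
construction-cohort cutoffs across cohorts when fixed cutoffs are wanted.
Missing panel genes are an error in strict mode; in permissive mode a missing
gene is imputed as at-the-median (low state) and more than 20% missing is an
error in any mode.

## Panel construction

1. **Survival screen.** For every gene, tumor samples are split at the
   cohort-median expression (ties to the low group). The two groups are
   compared with a log-rank test, and the hazard ratio with Wald CI comes
   from a Cox proportional-hazards fit of the binary indicator. Genes pass
   at unadjusted log-rank p < α (default 0.05); genes whose split leaves a
   group with fewer than two samples are flagged and never scored. The
   screen uses raw p-values (multiplicity control is applied only in the DE
   arm, matching how the candidate funnel is usually reported).
2. **Differential expression.** Tumor vs normal means on the log2 input
   scale give the fold change; inference uses an empirical-Bayes moderated
   t-statistic: per-gene pooled variances are shrunk toward a prior
   estimated across genes by the method of moments on log variances
   (trigamma matching, the same estimator limma uses — the test suite checks
   agreement with Bioconductor limma to numerical precision). P-values are
   Benjamini-Hochberg adjusted; a gene passes at adj. p < 0.05 **and**
   |log2FC| > 2 (strict inequality, as published).
3. **Candidates** are the intersection of the two hit lists, ordered by
   survival p-value.
4. **Random-forest selection.** Candidate Gene-Scores (the binarized,
   direction-oriented values — "expression status", not continuous
   expression) are features; the label is vital status at 3 years (alive = 0,
   deceased = 1; samples censored before 3 years have unknown status and are
   excluded). Defaults follow the published settings: 500 trees, maximum
   depth 10, stratified 10-fold cross-validation; the importance of a gene is
   the unnormalized mean decrease in node impurity averaged over trees and
   over the forests trained on each fold's training split. The published
   importance cutoff (0.5) is specific to the impurity scale of the original
   software and is not portable across implementations, so the pipeline
   defaults to top-k selection with k = 21 (the published panel size); a raw
   cutoff mode remains available.
5. **Neural-network weights.** A fixed feed-forward net — inputs (one per
   selected gene) → 4 ReLU → 2 ReLU → 2 softmax outputs (alive, deceased;
   output 2 is the death probability) — is trained full-batch with Adam
   (learning rate 0.001, exactly 1000 epochs, cross-entropy loss E, the
   per-epoch trace is recorded and must stay finite). The network is a small
   NumPy implementation so that the architecture, epoch count and raw weight
   matrices are exactly specified and deterministic given the seed.
   Each gene's weight is a norm of its outgoing first-layer weight row;
   the default reduction is the L1 norm (L2 and plain sum are available and
   recorded in the provenance file). A published single positive scalar per
   gene is compatible with several reductions of a genes × 4 matrix; L1 is
   the simplest positive one. Genes with an all-zero row are flagged and
   excluded from the panel. Retraining is not expected to reproduce the
   published numeric weights — those depend on the original cohort and an
   unstated seed — only the construction procedure.

## Survival evaluation

Model fitting is delegated to lifelines; ties use the Efron approximation
(lifelines' default). Covariates enter as fixed dichotomies (grade 3&4 vs
1&2, stage III&IV vs I&II, T3&4 vs T1&2, N1 vs N0, M1 vs M0, low vs normal
hemoglobin, elevated vs normal platelets, low vs normal calcium, older vs
younger, male vs female); the missing-information levels (NX, MX, unknown)
are deleted listwise per model and the used sample count is reported. The
mPS enters the Cox models as the high-vs-low dichotomy (any stratum above
"low"); a continuous option exists for the C-index. The evaluation stage
runs univariate Cox models for every covariate and carries those with
p < 0.05 into one multivariate model.

Harrell's C-index is computed over comparable pairs with prediction ties
counted 1/2; the caller must declare whether a higher score means higher
risk or longer survival. C ≥ 0.70 (the conventional "good fit" remark) is
logged, never used as a gate.

The nomogram maps each multivariate coefficient to a 0–100 point scale:
points_i ∝ |β_i| × (observed range of x_i), with the largest span normalized
to 100. Total points map affinely back to the linear predictor, and survival
at 3 and 5 years is S₀(t)^exp(lp) with the Breslow baseline at the all-zero
covariate vector, so the points → lp → S(t) round trip reproduces the Cox
model's own predictions to numerical precision (tested at 1e-6). Calibration
bins samples by predicted survival (tertiles by default), compares the
within-bin Kaplan-Meier estimate at the horizon with the mean prediction,
and with n_boot > 0 subtracts per-bin bootstrap optimism (refit on the
resample, evaluate apparent-minus-test error; 200 seeded resamples by
default; n_boot = 0 gives the apparent curve). Horizons beyond the last
observed time are an error.

### Per-gene survival statistics

The genome-wide screen fits one binary Cox model and one log-rank test per
gene across thousands of genes and many simulation replicates, so these two
statistics are implemented directly (`_coxfast`): a Newton solve of the
single-parameter partial likelihood with Efron tie handling and step halving
(|β| > 15 is flagged as separation), and the standard hypergeometric-variance
log-rank test. Both agree with lifelines to ~1e-5 in the test suite, with
and without ties; lifelines remains the fitter for everything multivariate.

## Synthetic cohorts

The generator emulates the structure the pipeline consumes, not RNA-seq
marginals: per-gene Gaussian log2 expression (sd `noise_sd`, default 1.0),
an additive `planted_log2fc` shift (default 2.5) in tumors for DE genes,
dichotomized clinical covariates as independent Bernoullis with realistic
prevalences (a configurable fraction masked to NX/MX/unknown), Weibull
baseline survival (scale 2400 days, shape 1.1 — median OS of several years
at the reference cohort's scale) under proportional hazards, and independent
exponential censoring whose rate is solved numerically so the expected
censored fraction hits `censor_rate` (default 0.68, matching a two-thirds-
alive registry cohort; the realized fraction is within ±0.05 at n ≥ 500).

Prognostic structure: each tumor carries `n_risk_programs` independent
latent risk states (Bernoulli 1/2); every planted prognostic gene reports
one program bimodally with a 6·noise_sd separation between modes, so the
gene's median split recovers its program's state essentially perfectly, and
the hazard includes `planted_log_hr` once per high-risk program. The risk
load is centered (minus half the program count) so that a median-risk
patient follows the baseline Weibull and the 3-year vital-status labels stay
realistically balanced; shifting the linear predictor by a constant leaves
every hazard ratio intact. With the
default single program, each planted gene's *marginal* median-split hazard
ratio equals exp(planted_log_hr) exactly — there are no other hazard terms
to attenuate it — which makes parameter recovery a clean test (the
alternative, independent per-gene hazard contributions, would attenuate
every marginal HR through Cox non-collapsibility and leave nothing exactly
recoverable). With several programs the summed risk is graded, which is the
configuration the end-to-end pipeline demonstration uses (5 programs) so
that a continuous score has ranking power; in that regime per-gene marginal
HRs are deliberately not asserted. Clinical covariate effects default to
zero; coverage tests plant explicit `covariate_betas` in cohorts without
prognostic genes so the fitted model is correctly specified.

Because planted genes are near-noiseless reporters of their program, power
and recovery results on synthetic data are upper bounds: real signatures
face correlated noise, batch effects, normalization artifacts and
continuous (not near-binary) effect gradients, none of which the generator
models. Passing tests establish the correctness of the machinery, not the
real-data performance of any panel.

## Problem sizes, seeds, determinism

All randomness flows through explicit integer seeds; the pipeline expands
its single seed into per-stage seeds via `SeedSequence([seed, stage_index])`
and rerunning a configuration reproduces byte-identical outputs (manifests
record the seed, a config hash and stage record counts). The bundled
verification workloads use sizes chosen to exercise the asymptotics the
checks rely on while staying desk-scale: 2000 null genes at n = 600 for
screen calibration, 50 replicates for hazard-ratio recovery, 200 replicates
for Wald-CI coverage, n = 2000 for calibration, and a 400-tumor / 300-gene
construction cohort with a 300-tumor held-out cohort for the end-to-end run.

## Known limitations

- The published 21-gene weights are shipped as data, not re-derived; the
  original discovery cohorts are not bundled or downloaded.
- The DE module assumes log-scale input (the package never normalizes) and
  two-group comparison only; no count models.
- The survival screen's HR is a single-cohort estimate; no meta-analytic
  "integration" across cohorts is implemented.
- No time-dependent effects, competing risks, or comparisons against other
  published signatures.
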