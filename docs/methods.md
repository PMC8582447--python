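# Methods

## Model

The endpoint is any-grade radiation-induced optic neuropathy (RION), a
binary outcome. Its probability is modeled as a logistic function of a
linear predictor over clinical and dosimetric covariates,

    NTCP = 1 / (1 + exp(-(b0 + b1*x1 + ... + bn*xn))),

i.e. a binomial GLM with logit link. No other link or family is supported.
Dose-volume metrics (D_min, D_mean, D_max, D_1%, D_99% over the optic
apparatus — chiasm plus both optic nerves) enter as precomputed scalars in
Gy_RBE; the package does not touch treatment plans or DVHs.

## Pipeline and its rationale

RION is rare (a few percent), so a cohort of a few hundred patients holds
only on the order of ten events. Every stage of the pipeline exists to keep
a ~15-covariate search honest at that event count:

1. **Univariable screen.** Continuous covariates: single-covariate logistic
   fit, Wald p-value on the slope (the conventional default; the
   alternative likelihood-ratio test is not implemented). Categorical
   covariates: Pearson chi-square on the 2x2 table without continuity
   correction. The surgery count is additionally screened as the
   dichotomizations >1, >2, >3, >4 because its effect is concentrated in
   the small heavily-operated subgroup. Complete-case filtering is applied
   per variable. No multiplicity correction is applied at this stage.
2. **Collinearity elimination.** Pairs with |Spearman| > 0.8 (mid-ranks,
   average ranks for ties; binary variables through their 0/1 ranks) are
   resolved greedily in descending pair-correlation order; the member with
   the lower |Spearman| to the event indicator is dropped. A tie drops the
   variable later in the declared order — an arbitrary but deterministic
   rule, logged when exercised. The nine-variable preset
   `POST_FILTER_NINE` (age, hypertension, tumor involvement, sex, surgery
   count, GTV volume, prescription dose, mean and maximum optic dose) ships
   as the reference post-filter configuration.
3. **Bootstrap-LASSO ranking.** 1000 resamples with replacement; on each,
   an L1-penalized logistic fit at the smallest penalty (on a 100-point log
   path from lambda_max down to 1e-3*lambda_max) admitting at most
   `max_k = 4` nonzero slopes, the penalty recomputed per resample.
   Resamples with fewer than two events (or two non-events) are skipped and
   counted, never redrawn — redrawing would bias the bootstrap
   distribution. "Selected" means a standardized-scale slope above 1e-8
   (coordinate descent produces exact zeros; the epsilon guards float
   noise). The default 0.40 frequency cutoff for the "top" list is a
   reverse-engineered convention, overridable. Note an intrinsic property
   of the minimal-penalty/max-k rule: it sits just above the entry point of
   the (k+1)-th covariate, so ~k slopes are active in nearly every
   resample. Frequencies therefore sum to ~k, and because resampling one
   dataset preserves its chance in-sample correlations, even a pure-noise
   covariate that happens to correlate with the outcome in that dataset can
   hold a high frequency. Only the frequency *ranking* and the aggregate
   noise level are meaningful, not individual noise frequencies.
4. **Candidate comparison.** All non-empty subsets (max size 4) of the top
   list are fitted *unpenalized* inside leave-one-out, 5-fold and 10-fold
   cross-validation, each scheme repeated 10 times with a fresh shuffle.
   AUC-ROC (Mann–Whitney form, ties half-weight) and cross-entropy
   (-lnL/n) are computed on the pooled out-of-fold probabilities of each
   repetition; the ranking key is the unweighted mean AUC over all
   scheme x repetition runs — the most literal reading of "mean across all
   cross-validation runs", documented as a convention. LOO folds do not
   depend on the shuffle, so LOO repetitions are identical and are computed
   once. Folds whose training complement is single-class are merged into a
   neighbor and logged (inevitable at ~4% prevalence with 5 folds). AIC
   (2k-2lnL), BIC (k ln n - 2lnL; k counts the offset) and the
   Hosmer–Lemeshow statistic come from the full-data fit. Ties in mean AUC
   go to the smaller model, then lower cross-entropy.
5. **Final fit.** The reported coefficients are the coordinate-wise median
   of 100 penalized fits, each using a fresh 10-fold shuffle to pick the
   penalty minimizing mean out-of-fold deviance on a 100-point path; the
   median removes the dependence on any single fold assignment.
   Per-coefficient 90% confidence intervals are percentile intervals (not
   BCa — the minimal reading of a bootstrap-distribution interval) over
   1000 unpenalized refits on resamples; degenerate or non-converged
   resamples are skipped and counted, and more than 50% degeneracy aborts
   with diagnostics.
6. **Evaluation.** Apparent AUC with a percentile bootstrap CI that
   resamples records while holding the model fixed (an apparent-performance
   interval; a refitting bootstrap is intentionally out of scope).
   Calibration: records binned by predicted-risk quantiles (5 bins below 30
   events, else 10), each bin reporting mean predicted probability,
   observed event fraction and an exact (Clopper–Pearson) binomial 90%
   interval; the calibration slope is the unweighted least-squares line
   through the bin points.
7. **Stratification.** Patients with NTCP at or above the threshold
   (default 6%) are high-risk; the inclusive boundary errs toward
   sensitivity. The default sweep grid runs 1%–20% in 0.5% steps.

## Fitting algorithms and numerics

- **Maximum likelihood:** iteratively reweighted least squares;
  convergence when the relative log-likelihood change is below 1e-9 within
  100 iterations; IRLS weights floored at 1e-6. Quasi-separation — any
  |coefficient| exceeding 15 — sets `converged=False` instead of raising,
  so bootstrap loops survive degenerate resamples (with ~10 events in a few
  hundred records, occasional separation is expected). Standard errors come
  from the observed information matrix; Wald p-values per coefficient.
- **L1-penalized likelihood:** glmnet-style cyclic coordinate descent on
  the IRLS quadratic approximation of (1/n)*negative log-likelihood +
  lambda*sum|slopes|; the offset is never penalized. Continuous covariates
  are standardized to zero mean / unit variance internally so the penalty
  treats doses (tens of Gy) and binary flags comparably; binary 0/1 columns
  are left unscaled; reported coefficients are back-transformed.
  lambda_max = max_j |x_j'(y - ybar)|/n makes all slopes exactly zero (a
  tiny relative margin in the soft threshold keeps this exact at
  lambda == lambda_max despite float rounding). Warm starts are used along
  paths.
- **Cross-entropy** clips probabilities to [1e-12, 1-1e-12]; the bound is
  far below any reported digit.
- **Hosmer–Lemeshow:** 10 risk-decile bins by default (the test's canonical
  form), statistic sum (O-E)^2/(E(1-E/m)), reference chi-square with
  bins-2 degrees of freedom; zero-variance bins are skipped with a warning
  and the degrees of freedom reduced. The bins-2 reference assumes
  *estimated* probabilities; with the true generating probabilities plugged
  in, the statistic is approximately chi-square with `bins` degrees of
  freedom instead, so calibration-level simulations in the test suite fit
  the (correctly specified) model first.
- **Wilcoxon rank-sum:** exact enumeration when both groups have at most 10
  observations and no cross-group ties, otherwise normal approximation with
  tie correction. **Fisher exact:** hypergeometric two-sided form for 2x2;
  complete enumeration of fixed-margin tables for small r x c cross-tabs.

## Synthetic cohort generator

The generator emulates a two-institution skull-base cohort: n = 289 split
143/146 between a pencil-beam-scanning proton center ("PSI") and a
passive-scattering/mixed-modality center ("CPO"); all chordomas at the
former (101/143), the latter all-chondrosarcoma; age truncated-normal
(mean 44, sd 13) on [18, 80]; hypertension Bernoulli(0.19) with 16/289
missing at random; tumor involvement 112/286 with 3/289 missing; 152/289
female; surgery counts truncated-geometric on 1..8 with mean 1.6; GTV
log-normal (median 27.2 cc) truncated to [0.2, 130]; maximum optic dose
truncated-normal centred at 59.6 Gy_RBE on [45, 76]; prescription dose by
tumor type (chordoma ~74 on [68, 76], chondrosarcoma ~70 on [67, 76]).
Spread parameters that no summary table pins down were fixed once at
realistic values: dose sd 7 (optic maximum) and 2 (prescription), GTV
log-sd 0.9, minimum-dose log-normal (median 2, log-sd 1.2, capped at 80% of
the maximum), follow-up log-normal (median 73.8 months, log-sd 0.5) on
[5, 197], photon share U(0.2, 0.5) of prescription for mixed regimens.
Interior dose metrics are three sorted uniform draws between minimum and
maximum, which enforces D_min <= D_99 <= D_mean <= D_1 <= D_max by
construction.

Covariates are mutually independent apart from the two design couplings
(tumor type given institution; prescription given tumor type). An optional
logistic age–hypertension link exists for stress tests and is off by
default. Missingness is completely at random, consistent with downstream
complete-case analysis. Outcomes are Bernoulli draws at each record's NTCP
under the configured ground truth (default: offset -5.07, age 0.031/year,
hypertension 1.21 — a ~3-4% event rate); case grades follow the 3:1:3:5
distribution over CTCAE grades 1–4. One master seed spawns independent
substreams for covariates and outcomes.

**What passing tests do and do not show.** The generator reproduces
marginal distributions and the logistic outcome mechanism; it does not
reproduce real covariate correlation structure (beyond the two couplings),
institutional dose-planning idiosyncrasies, follow-up censoring dynamics,
or per-structure dose distributions. Pipeline properties demonstrated on
it (parameter recovery, selection behavior, CV ranking consistency,
interval coverage) validate the *machinery*, not the clinical
transportability of any particular fitted model.

## Problem sizes used in the test suite

Simulation-based checks are scaled to desk size: parameter recovery uses
one cohort of 20 000; selection-frequency behavior 20 runs of 200
resamples at n = 1000; CV ranking consistency 20 runs at n = 2000;
interval coverage 200 replications (n = 2000, 200 bootstrap draws each);
calibration level 1000 simulations at n = 1000. These sizes give
comfortable Monte-Carlo resolution for the asserted tolerances.

## Known limitations

- Binomial-logit only; no elastic-net mixing, no nested CV for the penalty
  inside candidate comparison, no optimism-corrected (refitting) bootstrap
  validation, no external-validation harness.
- The LASSO penalty grid is log-spaced with fixed ratio 1e-3; pathological
  designs could require a wider grid.
- The r x c Fisher enumeration is exponential and restricted to small
  tables (total count <= 400).
- Percentile intervals at ~10 events are noisy; the >50% degeneracy guard
  reports, but cannot repair, cohorts too small to resample.
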