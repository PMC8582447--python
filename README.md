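# rionntcp

Normal tissue complication probability (NTCP) modeling of
**radiation-induced optic neuropathy (RION)** for skull-base radiotherapy
cohorts. RION is a rare (few-percent) but severe late toxicity of high-dose
treatment near the optic apparatus; with only a handful of events per
cohort, naive model fitting is fragile. This package implements a complete,
resampling-hardened model-development pipeline for clinical physicists and
outcome modelers:

1. **Cohort I/O & screening** — validated patient tables (clinical
   covariates plus scalar dose-volume metrics over the optic apparatus, in
   Gy_RBE), inter-institution comparison (Wilcoxon rank-sum / Fisher exact),
   complete-case filtering, univariable association screening and
   Spearman-based collinearity elimination (|SRCC| > 0.8).
2. **Bootstrap-LASSO variable ranking** — L1-penalized logistic fits on
   bootstrap resamples, penalty chosen per resample as the smallest value
   admitting at most four covariates; variables ranked by selection
   frequency.
3. **Cross-validated model comparison** — all candidate subsets of the
   top-ranked variables compared by out-of-fold AUC-ROC (leave-one-out,
   5-fold and 10-fold, each repeated 10 times), alongside AIC, BIC,
   cross-entropy and the Hosmer–Lemeshow statistic.
4. **Final model** — median coefficients over 100 penalized refits with
   deviance-minimizing cross-validated penalty; 90% percentile bootstrap
   confidence intervals from unpenalized refits; ROC and calibration-curve
   evaluation.
5. **Risk stratification** — low/high-risk segmentation at an NTCP
   threshold (default 6%) and operating-point sweeps.

The model is a logistic dose–response in the covariates $x_i$:

$$\mathrm{NTCP} = \frac{1}{1 + e^{-\beta x}}, \qquad
\beta x = \beta_0 + \beta_1 x_1 + \cdots + \beta_n x_n .$$

Because clinical RION cohorts are not generally shareable, the package
includes a first-class **synthetic cohort generator** whose covariate
margins emulate a realistic two-institution chordoma/chondrosarcoma cohort
(n = 289) and whose outcomes are drawn from the logistic mechanism with
configurable ground-truth coefficients — by default
$\beta_0 = -5.07$, $\beta_{\mathrm{Age}} = 0.031$ per year,
$\beta_{\mathrm{HBP}} = 1.21$ for arterial hypertension. Every downstream
stage is tested against this generator.

## Worked example

```python
import numpy as np
from rionntcp import (SimulationConfig, generate_cohort, covariate_frame,
                      fit_logistic, stratify)

# simulate a cohort under the default ground truth and refit it
cfg = SimulationConfig(n=20000, seed=1, hbp_missing_rate=0.0)
cohort = generate_cohort(cfg)
frame = covariate_frame(cohort)
model = fit_logistic(frame[["age", "hypertension"]].to_numpy(),
                     frame["rion"].to_numpy(), ["age", "hypertension"])
print("events:", int(frame["rion"].sum()))
for name, b, se in zip(["offset", "age", "hypertension"],
                       model.beta, model.standard_errors):
    print(f"beta_{name:14s} {b:8.3f} +- {se:.3f}")

s = stratify(model, cohort, threshold=0.06)
print(f"high-risk: {s.proportion_high:.1%}  "
      f"sensitivity {s.sensitivity:.0%}  specificity {s.specificity:.0%}")
```

prints (seed 1):

```
events: 720
beta_offset           -4.900 +- 0.159
beta_age               0.027 +- 0.003
beta_hypertension      1.226 +- 0.078
high-risk: 14.9%  sensitivity 37%  specificity 86%
```

The refitted coefficients recover the generating values (−5.07, 0.031,
1.21) to within sampling error at ~700 events. At the 6% NTCP threshold
roughly one patient in seven of this synthetic cohort is flagged high-risk;
the split is a property of the configured covariate margins and ground
truth, so it is reported, not asserted.

A command-line front end mirrors the pipeline stages:

```bash
rion simulate --n 289 --seed 7 --out cohort.csv
rion screen cohort.csv
rion select cohort.csv --n-bootstrap 200
rion fit cohort.csv --variables age,hypertension --out final.json
rion stratify cohort.csv final.json --threshold 0.06
```

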