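# ovresponse

Predicting the number of metaphase-II (MII) oocytes retrieved after
controlled ovarian stimulation, from clinical covariates and engineered
genetic features.

## The problem

Ovarian stimulation before IVF yields anywhere from zero to dozens of
mature oocytes, and both poor response and hyper-response carry clinical
risk. The standard predictors are hormonal and sonographic —
anti-Müllerian hormone (AMH), the antral follicle count (AFC), age,
previous stimulation outcomes — but germline variation in
reproduction-related genes (*FSHR*, *LHCGR*, *ESR1/2*, *GDF9*, *PRLR*,
*FSHB*, ...) also modulates the response. Single variants rarely help a
predictive model; this package implements a pipeline that discovers
**multi-variant genetic features** and adds them to a gradient-boosted
count model:

1. **Screening** — per-variant Kolmogorov–Smirnov and Mann–Whitney U
   tests of the MII distribution split by carrier status, plus
   shadow-feature (Boruta) importance rankings with random-forest and
   GBM/SHAP engines, merged by mean rank into a top-20 pool.
2. **Count feature via correspondence analysis** — CA of the variant ×
   MII-group contingency table (five groups: ≤2, (2,4], (4,7], (7,11],
   >11 oocytes); the k variants nearest the high-yield group form
   IV-CA = Σ 1[variant is alternative].
3. **Standardized count feature via a self-organizing map** — a 6×6
   hexagonal SOM (Gaussian neighborhood, σ = 1.5, lr = 0.7, Manhattan
   distance) over genotype vectors; variants over-represented in
   enriched nodes enter an exhaustive subset search scored by
   cross-validated RMSE; the winner is frozen as a z-score,
   (SOMv − E[SOMv]) / σ(SOMv).
4. **Binary reduced haplotypes** — two-locus EM estimates of D′/r²,
   haplotype blocks by confidence intervals, the four-gamete rule and
   the solid spine of LD; candidate block haplotypes screened by their
   effect on model RMSE; blocks reduced (UMAP → K-means → decision
   tree) to the root-to-leaf path variants, giving a feature that is 1
   iff every path variant matches its baseline allele.
5. **Model** — LightGBM gradient-boosted trees (100 trees, five leaves,
   max depth 16, l2 loss), five-fold cross-validation grouped by
   patient, RMSE/MAE/MAPE on pooled out-of-fold predictions, greedy
   forward selection of clinical features, an exhaustive 2ⁿ−1 search
   over genetic-feature combinations, and exact TreeSHAP explanations
   (global importance and additive per-patient decompositions).

Because no clinical-genetic cohort of this kind is public, the package
ships a first-class **synthetic cohort generator** that reproduces the
study population's structure: realistic clinical marginals (log-normal
AMH truncated at the 15 ng/mL exclusion bound, AFC correlated with AMH),
a 122-variant panel with published allele frequencies, founder-haplotype
LD blocks, structurally missing previous-stimulation data, and a
negative-binomial MII outcome with planted clinical and genetic effects
whose ground truth is returned for recovery testing.

## Worked example

`python examples/06_predictive_model.py` runs the whole pipeline on a
synthetic 264-patient cohort (515 stimulation processes) and prints:

```
trivial baseline RMSE: 4.70 oocytes
selected clinical features: ['amh', 'afc_day1', 'pcos']
clinical model:         RMSE 3.84, MAE 2.89
best genetic combination (7 tried): ['IV-SOM']
clinical-genetic model: RMSE 3.80, MAE 2.87
RMSE reduction from genetics: 0.046 oocytes

global importance (mean |SHAP|, oocytes):
  amh          1.740
  afc_day1     0.889
  IV-SOM       0.313
  pcos         0.025

patient S0000-1: predicted 4.29 MII oocytes (base 6.15)
  amh          -0.80
  afc_day1     -0.75
  IV-SOM       -0.31
  pcos         -0.01
cumulative genetic impact: -0.31 oocytes
```

Reading this: the trivial model (always predict the cohort mean) errs by
4.70 oocytes RMSE; the selected clinical covariates cut that to 3.84;
adding the best genetic-feature combination (here the SOM-derived
standardized count) cuts it further. AMH dominates the global SHAP
ranking, AFC is second, and the genetic feature ranks third. For the
example patient, a low AMH and AFC pull the prediction from the base
value of 6.15 down to 4.29 oocytes, of which −0.31 is attributable to
her genotype — the decomposition is exactly additive.

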