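# Methods

This note documents the models, algorithms and design choices behind
`ovresponse`, in the order the pipeline runs them, together with the
assumptions of the synthetic cohort generator and the package's known
limitations.

## The prediction problem

The outcome is the number of metaphase-II (MII) oocytes retrieved after
one controlled ovarian stimulation ("process"). A patient can contribute
more than one process, and a second stimulation carries the first's
oocyte counts as covariates. Inputs are a clinical record per process
(age, BMI, AMH, FSH, LH, E2, day-1 antral follicle count ≤ 10 mm, PCOS
flag, previous-stimulation counts where they exist) and a genotype
matrix over a panel of reproduction-gene variants. Genotypes are stored
as dosages {0, 1, 2} but every feature-engineering stage collapses them
to *alt-presence* (carries at least one alternative allele): the
feature definitions are inherently binary per variant, and the data do
not support zygosity effects at these sample sizes.

Records with AMH above 15 ng/mL or missing are excluded at load time
(implausible/undetected assay values). MII groups are the five bins
[0,2], (2,4], (4,7], (7,11], (11,∞). The lowest bin is closed at 2:
this is the only closure of the published-style group labels that is
jointly exhaustive over the nonnegative integers.

## Synthetic cohort generator

The generator is first-class code: every downstream stage is validated
on cohorts it produces, with the planted ground truth returned for
recovery checks.

* **Clinical marginals.** Ages are a discretized truncated normal
  (34.55 ± 4.20 y, clipped to 18–46). AMH is log-normal
  (μ = 0.83, σ = 0.88 on the log scale) with a mild negative age trend
  (−0.03/y on log AMH, giving r(age, AMH) ≈ −0.14) and truncation at
  the 15 ng/mL exclusion bound, so the exclusion filter is exercised.
  AFC is negative-binomial with mean 6 + 2.2·AMH (the two ovarian
  reserve markers co-vary, discordant in a minority of patients). FSH,
  LH, E2, BMI, stimulation days and gonadotropin dose are truncated
  normals at the study group's means/SDs. PCOS prevalence is 8%.
* **Genotypes.** The default panel carries 22 named variants with their
  published alternative-allele frequencies (three frequencies for
  SOM-screen variants are not published and were invented at plausible
  values — marked in `panel.py`) plus 100 independent null variants so
  that screening specificity is measurable. Three LD blocks (FSHR ×2,
  PRLR ×8, GDF9 ×4 variants) are induced by founder-haplotype pools:
  each founder draws one shared latent uniform, and each site copies it
  with probability `target_dprime` (default 0.95) or draws fresh;
  individuals sample two founders per block. This yields exact
  haplotypes (so block-detection tests have a known answer), pairwise
  |D′| rising to 1 as `target_dprime` → 1, and marginal frequencies
  matching the configuration up to founder-pool sampling error
  (pool size 200 ⇒ SD ≈ √(f(1−f)/200)).
* **Outcome.** MII counts are negative binomial — an overdispersed
  count, the natural family here — with log-mean
  β₀ + β_AMH·log(1+AMH) + β_AFC·(AFC − 13.41) + β_age·(age − 34.55) +
  Σ β_g·g. Defaults (β₀ = 0.94, β_AMH = 0.45, β_AFC = 0.02,
  β_age = −0.01, dispersion θ = 6) were fixed once to reproduce the
  study group's outcome scale: mean ≈ 5.9, SD ≈ 5, r(AMH, MII) ≈ 0.55.
  Two genetic effects are planted by default: a count feature over the
  three CA-identified variants (β = 0.07) and a protective
  all-reference PRLR haplotype (β = 0.15).
* **Missingness.** First stimulations have no previous-stimulation
  fields (≈51% of processes under the default two-process probability);
  10% of AFC values and 2% of genotypes are missing at random. Nothing
  is imputed: the boosted trees route missing values natively, except
  that SOM training (only) imputes missing alt-presence to 0.

What the generator does **not** emulate: population stratification,
assay batch effects, recombination within blocks, dose–response of the
stimulation protocol, and correlation between genetic features and
clinical covariates. Passing recovery tests therefore demonstrates that
the pipeline finds the kinds of structure it claims to find — not that
it would perform identically on real clinical data.

## Screening

Per variant, carriers vs non-carriers of the alternative allele are
compared on MII counts with the two-sample Kolmogorov–Smirnov test and
the Mann–Whitney U test at α = 0.05, with no multiplicity correction
(matching the original screening design; a corrected variant is a
one-line change). The Mann–Whitney null is exact for tie-free groups of
≤ 8, otherwise normal with tie correction. A direction (higher/lower)
is assigned only when both tests reject; monomorphic or undersized
splits are flagged untestable rather than raised.

The shadow-feature ranking (Boruta) appends a column-permuted copy of
every feature each iteration, draws a fresh 70/30 train/test split, and
scores features with one of two engines: a random forest evaluated by
*held-out* permutation importance, or LightGBM evaluated by held-out
mean |SHAP|; both engines subsample features (fraction 0.5) so
iterations are genuine replicates. A feature scores a "hit" when it
beats the best shadow. Decisions use a Bonferroni-corrected two-sided
binomial test on hit counts at α = 0.05; features in the tentative
middle ground are conservatively rejected. Two choices here deserve
explanation: in-sample importance makes the luckiest spuriously
correlated noise feature beat freshly permuted shadows in a majority of
iterations — a persistent, not random, advantage — which destroys
specificity; held-out scoring with randomized engines and the corrected
binomial restore it (measured: 0/20 all-noise runs confirm anything,
while strongly planted features are confirmed at rank 1). Defaults are
100 iterations; the orchestrated pipeline and tests run 8–30 iterations
as a deliberate scale choice — decisions stabilize quickly at these
panel sizes.

Rankings from the three runs (RF on variants, GBM-SHAP on variants, RF
on variants + AMH as a helper covariate) are combined by mean rank,
ties broken by mean score then variant id, and the top 20 variants
proceed.

## Correspondence analysis feature (IV-CA)

The contingency table counts alt-carriers of each candidate variant
within each MII group (missing genotypes uncounted). CA is the SVD of
the standardized residuals of the correspondence matrix; rows and
columns are both reported in principal coordinates (a symmetric map).
Total inertia equals Pearson χ²/n exactly — this identity is the test
oracle. The k = 3 variants nearest the ">11" group's point in the
first two dimensions (Euclidean distance, ties by variant id) form the
count feature. Caveat, documented rather than hidden: in a symmetric
map, row-to-column distances are not χ² distances; the proximity rule
is a heuristic of the original design, and reflection/rotation of the
axes does not change the selection.

## Self-organizing map feature (IV-SOM)

A 6×6 SOM with hexagonal topology (odd-r offset → axial coordinates;
neighborhood distance is the standard hex distance), Gaussian
neighborhood with σ = 1.5, learning rate 0.7, Manhattan metric for
best-matching-unit search, online updates, and linear decay of both σ
and the learning rate over the iteration budget (the decay schedule is
an implementation default — the original tooling does not report one).
The default budget is 100,000 iterations; the pipeline uses 20,000 (QE
stabilizes well before that at these input sizes). Quantization error
is the mean BMU distance.

A node is *enriched* for an MII group when its within-node share is at
least 2× the population share and the node holds ≥ 10 observations
(both configurable; the original "over-represented" is not quantified).
Per enriched node the 10 variants with the largest difference between
node and population alternative-allele frequency are characteristic.
The union over the extreme groups (≤2, >11), capped at 10 candidates by
absolute frequency difference, enters an exhaustive subset search
(≤ 2¹⁰ − 1 = 1,023 evaluations; candidate counts above 15 are refused):
each subset's standardized carrier count is added to the clinical model
and scored by fixed-fold CV RMSE; ties prefer smaller subsets. The
winning feature's standardization constants (mean, population SD) are
frozen from the defining cohort and reused verbatim on new data.

## Haplotype features

Two-locus haplotype frequencies come from the standard EM over the
double-heterozygote ambiguity (tolerance 1e-6, ≤ 1,000 iterations);
D = p_AB − p_A·p_B, D′ = |D|/D_max, r² = D²/(p_A p_a p_B p_b). With no
double heterozygotes the EM equals direct gamete counting — the test
oracle. |D′| is invariant to allele relabeling.

Blocks are detected per chromosome after a MAF ≥ 0.05 filter, with
Haploview-style defaults throughout (only the algorithm names are
published; thresholds are the classical ones, all configurable):

* **Four-gamete rule** — a pair shows recombination when all four EM
  haplotype frequencies are ≥ 0.01; blocks are maximal contiguous runs
  with no recombinant internal pair (equal to brute-force interval
  search, verified on ≤ 12-variant toys).
* **Confidence intervals (Gabriel-style)** — the |D′| CI per pair comes
  from a likelihood grid with margins fixed at their MLEs (90%
  equal-tail interval of the normalized likelihood); a pair is strong
  LD when CI ∈ [0.70, ·] × [0.98, ·], recombination evidence when the
  upper bound < 0.90; spans are accepted longest-first when ≥ 95% of
  informative pairs are strong.
* **Solid spine of LD** — maximal runs whose first and last variants
  have |D′| ≥ 0.80 with every variant between them and with each other.

Per-block haplotype spectra use exhaustive multi-locus EM up to 12
variants and partition–ligation (top-20 side haplotypes) beyond. Every
block haplotype with frequency ≥ 0.05 becomes a candidate binary
feature — a process carries it iff its alt-presence vector over the
block equals the haplotype's pattern, the unphased analogue of
haplotype carriage that matches the reduced-haplotype semantics below —
and candidates are ranked by the fixed-fold CV RMSE of the clinical
model plus that feature.

Winning blocks are *reduced*: alt-presence vectors are embedded in 2-D
with UMAP (Hamming metric, 15 neighbors, min_dist 0.1, fixed seed),
clustered by K-means with k ∈ 2..10 chosen by silhouette, and a
decision tree grown to purity predicts cluster labels from the
variants. The root-to-leaf path to the leaf capturing the most members
of the largest cluster defines the reduced haplotype: each path
variant's required state is the branch taken (0 = reference). The
binary feature is 1 iff every path variant matches; a missing path
genotype yields a missing value (visible to the learner) rather than 0.
Degenerate blocks (identical rows) fall back to the full block with
modal states. The whole reduction is deterministic under a fixed seed.

## Model, selection, explanation

The learner is LightGBM GBDT with the study configuration — 100 trees,
5 leaves, max depth 16, l2 loss — plus a 0.1 learning rate (not
specified originally; surfaced in `ModelConfig`). Validation is 5-fold
CV *grouped by patient* (a patient's processes never straddle folds;
asserted on every run), with the fold assignment derived from the seed
by dealing shuffled patients round-robin. RMSE, MAE and MAPE are
computed on pooled out-of-fold predictions (single numbers, stabler
than per-fold averages); MAPE excludes zero-outcome rows (a relative
error is undefined there) and reports how many were excluded. The
trivial benchmark predicts the cohort mean; its RMSE is the outcome SD.

Clinical forward selection visits candidates in descending |Pearson r|
with the outcome and keeps a candidate iff retraining on identical
folds strictly lowers CV RMSE; an empty selection is a valid outcome.
The genetic combination search retrains the clinical + subset model for
every non-empty subset of the genetic features (2ⁿ − 1 models, n ≤ 7,
identical folds), ties toward smaller subsets. Clinical-only and
clinical-genetic metrics are always compared on the same folds.

Explanations are LightGBM's built-in exact TreeSHAP
(`pred_contrib=True`): additive by construction (base value + per-
feature contributions = prediction; asserted at 1e-6 on every
explanation), equal to brute-force Shapley values over all coalitions
on balanced product-distributed toys (tested), with global importance
as mean |contribution|. The per-patient *cumulative genetic impact* is
the sum of the genetic features' contributions, in oocytes.

## Numerical and scale choices

* Sizes in tests and the acceptance script — cohorts of ~500 processes
  for pipeline runs, ~2,000 for recovery studies, 8–30 Boruta
  iterations, 4,000–20,000 SOM iterations — are the package's chosen
  desk-scale settings; all are configurable upward.
* The planted-signal recovery studies use genetic effects of
  β = 0.15 (count) / 0.30 (haplotype) on the log-mean — roughly one
  oocyte across the feature range. This is a power consideration: a
  recovery property is only informative when the planted effect is
  above the detection floor at the study's sample size; the generator's
  milder defaults (0.07/0.15) sit near that floor by design, as weak
  effects are the realistic regime.
* Ties everywhere (rank combination, subset search, proximity
  selection) break deterministically: score, then size, then
  lexicographic id.
* All stage seeds derive from one master seed recorded in the pipeline
  report; every stochastic routine is reproducible bit-for-bit under a
  fixed seed.

## Limitations

* Carrier semantics for candidate haplotypes are evaluated on unphased
  alt-presence patterns, not phased chromosomes; a heterozygous carrier
  of a reference-pattern haplotype does not count as a carrier under
  the all-reference rule. This matches the binary feature definitions
  but differs from population-genetic haplotype frequency.
* The CA proximity rule inherits the symmetric-map caveat above.
* The Boruta engines' held-out scoring cannot distinguish a genuinely
  predictive variant from one spuriously correlated across the whole
  dataset; only larger cohorts fix that.
* MAPE is fragile at low counts and is reported for completeness, not
  used for selection.
* No hyperparameter optimization, alternative learners, or endpoints
  beyond the MII count (live birth, pregnancy) are in scope; nor is
  variant calling, phasing from reads, or AMH assay harmonization.
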