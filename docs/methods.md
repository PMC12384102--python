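# Methods

This note documents the models, their assumptions, the tunable parameters,
and the design choices made where the design was genuinely open. Nothing
here states an empirical result that the test suite or the acceptance
script does not itself compute.

## Synthetic data model

The generators in `mitocausal.synth` define the study conditions for every
downstream stage and record their ground truth.

**Expression cohorts** (`gen_expression`). Values are Gaussian on a
log-like scale: gene baselines μ_g ~ N(7, 1), within-gene SD 1. Genes are
partitioned into pathways; genes of affected pathways receive, in cases
only, a mean shift (SD units; default study condition 0.8) and a variance
inflation factor (default 1.5). Batch membership is randomized against the
label and batches receive centered additive offsets. Missingness is MCAR;
outliers replace values with the gene baseline ± 6 SD. The generator does
*not* emulate count-based RNA-seq noise, probe effects, gene–gene
correlation beyond the pathway structure, or confounded batches — so green
tests show the pipeline recovers localized mean/variance signal under
clean Gaussian noise, not that it handles every pathology of real arrays.

**GWAS summary-statistic pairs** (`gen_two_sample_gwas`). SNP–exposure
effects γ_j come from a configurable distribution (default N(0.1, 0.02));
standard errors follow the standardized-trait approximation
se = 1/√(2·MAF·(1−MAF)·n), which makes instrument strength (F ≈ (γ/se)²)
analytically predictable. The outcome effect is Γ_j = θ·γ_j + α_j with
pleiotropy α_j ~ N(α, σ_α²) on an `frac_invalid` subset. Case-control
outcomes use the same SE form on the log-odds scale with the effective-n
correction 4·n·φ(1−φ). Default sample sizes are 100,000 per study, giving
eQTL-scale instruments (z ≈ 20) that comfortably clear the p < 1e-8 and
F ≥ 10 filters. LD is not simulated here (instruments are independent);
the clumping path is exercised with explicit r² lookups.

**Colocalization regions** (`gen_region_pair`). LD is simulated at the
z-score level: Σ_ij = ρ^|i−j| (AR(1)), z ~ MVN(LD-propagated causal
signal, Σ). This is deliberate — individual-level genotypes are out of
scope — and is sufficient to produce the single-causal-variant geometry
the posterior computation assumes. Default region: 300 SNPs over 200 kb,
ρ = 0.5, causal |z| = 8.

**Trait panels and drug tables** emulate a PheWAS catalog (per-trait
per-SNP β/se/p with designated true associations) and a drug–target
bipartite schema (unique (drug, gene) pairs, a configurable fraction of
multi-target drugs).

## Expression preprocessing

Fixed order: median imputation → 1st/99th-percentile winsorization →
batch adjustment → variance filter (threshold 0.01, population variance).
Standardization is *not* part of this chain: it is fit on CV training
folds only and applied to validation folds, preventing leakage that the
source protocol leaves unstated. Percentiles use linear interpolation
between order statistics; winsorization is exactly idempotent when the
percentile position lands on an order statistic (e.g. 101 or 201 values)
and approximately so otherwise. The variance filter runs after
imputation/capping because the variance of the imputed data is what the
models see.

Batch adjustment is a label-protected location/scale method, not
empirical-Bayes ComBat: per gene, the label effect is estimated by OLS and
set aside; batch means and SDs of the label-adjusted residuals are
equalized to the pooled *within-batch* scale; the label effect is added
back. There is no shrinkage across genes. A batch design confounded 1:1
with the label is rejected as inestimable. Whether disease status belongs
in the batch model was an open choice; protecting it was chosen because
the alternative silently removes signal in unbalanced designs.

Distribution contrasts use Welch's t (central tendency) and the
median-centered Brown–Forsythe variant of Levene's test (variance),
pooled over the gene set and per gene, with significance stars at
0.05/0.01/0.001/0.0001.

## Pathway scoring and gene ranking

Per pathway, each model of the zoo (logistic regression, linear and RBF
SVM, random forest, gradient boosting, k-NN, Gaussian naive Bayes, MLP —
a dependency-light registry that is pluggable by name) is evaluated under
stratified k-fold CV (default 10) with an inner 3-fold grid search on the
training fold maximizing ROC-AUC; nesting avoids hyperparameter selection
leakage. The Pathway Score averages each of the five metrics across the
zoo before taking the five-metric mean; a best-model-only aggregation is
available. Top-half selection uses score ≥ median with median ties
included; model-selection ties break by registry order.

Importances come from a final fit on the full standardized pathway matrix:
native impurity importances for tree models, |coefficients| for linear
models, and a seeded permutation importance (mean ROC-AUC drop over 20
shuffles per gene, negatives clipped) otherwise. The permutation routine
is implemented in-package so that any object with a prediction function
qualifies, not only scikit-learn estimators. Normalization divides by the
vector maximum — min-subtraction would zero the least important gene of an
all-positive tree-importance vector. Total Importance sums the normalized
importances over selected pathways and, by default, over all models
(`all_models`); with M models and P selected pathways it is bounded by
M·P. Whether the source protocol summed over all models or only each
pathway's best is not stated; `all_models` is the default because it
matches the magnitude of published Total Importance values, and
`best_model` is available.

## Two-sample MR

Instrument pipeline: p < 1e-8 (as stated by the source protocol, stricter
than the genome-wide 5e-8; configurable) → greedy clumping (sweep by
ascending p; drop a SNP if any kept SNP on the same chromosome within
10,000 kb has r² ≥ 0.001; missing LD entries are treated as independent
and logged) → F ≥ 10 with the single-instrument approximation F = (β/se)².

Harmonization aligns the outcome to the exposure's effect allele: swapped
alleles flip β and EAF; strand complements are resolved; palindromic SNPs
are dropped under `drop_all`, or under `infer` kept only when both EAFs
lie outside |EAF−0.5| ≤ 0.08 and oriented so the frequencies agree.
Harmonization is an involution: re-orienting the outcome input arbitrarily
leaves the harmonized pair unchanged.

Estimators (all on Wald ratios β_out/β_exp with first-order delta SEs):

* **IVW** — closed form Σwβxβy/Σwβx², w = 1/se_y²; multiplicative
  random-effects SE inflation √max(1, Q/df), never narrower than the
  fixed-effect SE. One instrument degrades to a labeled Wald ratio.
* **MR-Egger** — WLS with intercept after orienting exposure betas
  positive; SEs inflated by √max(1, σ̂²); t reference with n−2 df. The
  intercept is the directional-pleiotropy test.
* **Weighted median** — cumulative-weight interpolation at 50% with
  inverse-variance weights; SE by seeded parametric bootstrap (default
  1,000 draws resampling both betas from their SEs).
* **Simple/weighted mode** — mode of the Gaussian-kernel density of the
  ratios; bandwidth = factor × 0.9·min(sd, normalized MAD)·n^(−1/5)
  (modified Silverman, factor 1 by default); bootstrap SE.
* **Cochran's Q** — Σw_j(ratio_j − θ)², χ²_{n−1}.
* **PRESSO-style outlier test** — observed weighted RSS of outcome betas
  around leave-one-out IVW predictions, compared to a parametric null
  (default 1,000 simulations resampling outcome betas from their SEs);
  per-SNP outlier p-values Bonferroni-corrected; corrected IVW refit
  excluding flagged SNPs.

Multiple testing across an exposure panel: BH-FDR at 0.05 by default,
Bonferroni optional.

## Colocalization

Per SNP, the Wakefield log-ABF: with r = W²/(se² + W²) and z = β/se,
log ABF = ½log(1−r) + z²r/2. Prior effect SD W = 0.15 for quantitative
traits, 0.2 on the log-odds scale for case-control. Hypothesis evidence is
accumulated in log space (log-sum-exp): H1 = p1·ΣABF1, H2 = p2·ΣABF2,
H3 = p1p2·Σ_{j≠k}ABF1_jABF2_k (computed as the log-difference of the full
product and the diagonal), H4 = p12·Σ_jABF1_jABF2_j, H0 = 1, then
normalized. Priors default to the canonical p1 = p2 = 1e-4, p12 = 1e-5.
When only p-values are available, |z| recovered from p suffices because z
enters squared. Per-SNP PP.H4 is the posterior over causal SNPs
conditional on H4.

The adaptive window evaluates half-windows 10/50/100/200 kb in increasing
order around the anchor, stops expanding after the first count exceeding
the 500-SNP target (that candidate stays eligible), and picks the
evaluated count closest to 500, ties to the smaller window (regional
specificity against long-range LD). The stop-then-choose-closest rule is
this package's reconciliation of an iteration rule and a halting rule that
can conflict when the first window already overshoots.

The high (> 0.8) / suggestive (> 0.6) flags follow the top per-SNP PP.H4
score, matching the stated decision rule even though that score is
conditional on H4; the regional PP.H0–H4 are always reported alongside and
should be read together — an H3-like region can flag "high" while its
regional PP.H4 is near zero.

## PheWAS and bidirectional MR

SNPs with per-SNP PP.H4 strictly above 0.8 are screened against a trait
panel (an on-disk TSV, never a remote catalog) with per-SNP BH-FDR across
traits at q = 0.05; the multiple-testing procedure was unstated in the
source protocol and BH per SNP is the implemented choice (Bonferroni
optional). Bidirectional MR runs the full battery in each direction with
direction-appropriate instrument selection; SNPs already serving as
forward instruments are excluded from the reverse candidate pool, because
a strong trait instrument can reach genome-wide significance for the
disease through the causal path itself, and instrument-set disjointness is
asserted per run. The p < 0.05 retention applies only to the summary
table; full results are always kept. A caution flag marks any direction
resting on fewer than 10 instruments.

## Drug ranking

Genes passing the configured filter (default: the MR-significant set)
carry their per-disease importance into the drug–target join; a drug's
combined importance is the sum of its (disease, gene) contributions, kept
at full precision and rounded only for display. Inhibitory annotations are
carried as metadata, not scoring inputs. Ranking is by descending combined
importance with lexicographic drug-id ties; `multi_target_only` restricts
to drugs with surviving targets in ≥ 2 diseases.

## Numerical and reproducibility choices

* Every stochastic stage takes an explicit seed; the pipeline derives
  per-stage substreams via CRC-tagged `SeedSequence`, so reruns are
  byte-identical and stages are independently reproducible.
* Posterior sums use log-sum-exp throughout; simulated p-values are floored
  at 1e-300; invalid p-values in coloc inputs are replaced by representable
  bounds before use.
* Percentile convention, variance ddof (population, matching the usual
  feature-scaling/VarianceThreshold conventions), and all tie-breaks are
  fixed and documented above.
* Degenerate inputs fail loudly: all-missing genes, zero-SD genes at
  standardization, confounded batch designs, single-class CV folds, empty
  instrument sets, and regions without shared SNPs raise typed errors.

## Problem sizes

The shipped defaults are desk-scale by design: 120-sample cohorts with 80
genes in 8 pathways, 30-instrument MR panels at n = 100,000 per study, and
300-SNP colocalization regions. Simulation-based checks use 100–1,000
replicates depending on the statistic (type-I error 1,000; coverage,
pleiotropy power/calibration and estimator-robustness 200; coloc recovery
100; end-to-end recovery 50). These sizes give binomial margins well
inside the asserted bounds while keeping any run reproducible on a laptop.

## Known limitations

* No empirical-Bayes shrinkage in batch adjustment; with very few samples
  per batch the scale estimates are noisy.
* Single-causal-variant colocalization only; no SuSiE-style multi-signal
  decomposition, no conditional analysis, no reference-panel LD.
* MR assumes summary statistics on a common scale; no Steiger filtering,
  multivariable MR, or individual-level analysis.
* The model zoo omits gradient-boosting variants with heavy dependencies
  (registry is pluggable); SHAP-based attribution is replaced by seeded
  permutation importance.
* Synthetic trait panels and drug tables are schema-faithful toys; no
  ontology mapping or live catalog queries.
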