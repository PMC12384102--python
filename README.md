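# mitocausal

An offline, fully seeded pipeline linking pathway-structured gene-expression
classification to causal genetics for neurodegenerative disease studies
(AD, ALS, MS, PD): per-pathway machine-learning scoring of case/control
expression cohorts, two-sample Mendelian randomization (MR) from summary
statistics, Bayesian colocalization with adaptive genomic windows, PheWAS
screening with bidirectional MR, and multi-target drug-importance ranking.
Synthetic-data generators with recorded ground truth stand in for the
GEO/OpenGWAS/HCDT inputs, so every stage is testable end to end without
network access.

It is written for biostatisticians and computational geneticists who want
the whole chain — expression evidence, causal evidence, shared-variant
evidence, drug mapping — in one reproducible toolbox.

## The models at the core

**Two-stage pathway/gene ranking.** For each pathway, classifiers are
evaluated by stratified 10-fold CV (standardization fit per training fold);
the composite *Pathway Score* is the mean of the five across-model mean
metrics (Accuracy, ROC-AUC, F1, Precision, Recall). Pathways in the top
half are selected, and each gene's *Total Importance* is the sum of its
max-normalized per-model importances over the selected pathways.

**Two-sample MR.** Instruments satisfy p < 1e-8, pairwise r² < 0.001 within
a 10,000 kb clumping window, and F = (β/se)² ≥ 10. After allele
harmonization (palindromic SNPs frequency-corrected outside the
|EAF−0.5| ≤ 0.08 ambiguity zone, or dropped), the battery reports the IVW
estimate θ̂ = Σwβxβy / Σwβx² (w = 1/se_y², multiplicative random-effects
SE), MR-Egger slope and intercept, the weighted median, simple/weighted
modes, Cochran's Q, and a PRESSO-style outlier test with a parametric null.

**Colocalization.** Per SNP and trait, the Wakefield log-ABF
½·log(1−r) + z²r/2 with r = W²/(se²+W²); hypothesis sums H0–H4 over causal
configurations with priors p1 = p2 = 1e-4, p12 = 1e-5. The analysis window
expands over candidates 10/50/100/200 kb, halting after the first count
above 500 SNPs and keeping the evaluated window closest to 500.

**Drug ranking.** Genes passing the MR filter are joined to a drug–target
table; a drug's *combined importance* is the sum of its per-disease gene
importances, e.g. a drug targeting ETFB (27.5 in ALS) and EPHX2 (15.1 in
MS) scores 42.6.

## Worked example

```python
from mitocausal.io import PipelineConfig
from mitocausal.pipeline import run_all

out = run_all(PipelineConfig(seed=7, out_dir="results/demo",
                             model_set=["logistic_regression"]))
print((out / "summary.json").read_text())
```

On the default synthetic cohort (120 samples, 8 ten-gene pathways, 3
pathways carrying a 0.8-SD case shift) this prints, deterministically for
seed 7:

```json
{
 "ml":     {"n_pathways_scored": 8, "n_pathways_selected": 4, "top_gene": "G0005"},
 "mr":     {"n_genes": 6, "significant_genes": ["G0005", "G0028", "G0017", "G0009", "G0016"]},
 "coloc":  {"n_regions": 5, "high": ["G0005", "G0028", "G0017", "G0009", "G0016"]},
 "phewas": {"n_coloc_snps": 1, "n_hits": 1},
 "drugs":  {"n_drugs_ranked": 15}
}
```

(abridged: the file also lists the low-variance filter report and the true
multi-target drug set recorded by the generator)

Reading: all selected pathways and every MR-significant gene come from the
injected affected set; their simulated eQTL/disease region pairs colocalize
("high" = top per-SNP PP.H4 > 0.8); the colocalized SNP's injected trait
association is recovered by the PheWAS screen; and the drug stage ranks 15
compounds by combined importance. The numbered scripts under `analysis/`
run the same stages step by step with narrated output and write their
tables under `results/analysis/`.

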