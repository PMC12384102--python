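"""Generate every synthetic input for the study and write it to disk.

A case/control expression cohort (8 mitochondrial-style pathways of 10
genes, 3 pathways carrying a 0.8-SD mean shift and 1.5x case-variance
inflation, 2 batches, 2% missingness, 1% outliers), eQTL/disease GWAS
pairs for causal and null genes, colocalization regions under H0/H3/H4,
a 40-trait PheWAS panel with one injected association, and a drug-target
table. Ground truth is saved alongside for the recovery checks in the
later steps.
"""

import json
from pathlib import Path

from mitocausal.io import (
    write_drug_table,
    write_expression_tsv,
    write_gmt,
    write_sumstats_tsv,
    write_trait_panel,
)
from mitocausal.pipeline import default_expression_config
from mitocausal.synth import (
    MRSimConfig,
    RegionSimConfig,
    gen_drug_table,
    gen_expression,
    gen_region_pair,
    gen_trait_panel,
    gen_two_sample_gwas,
)

SEED = 20260929
OUT = Path("results/analysis/inputs")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    em, pmap, truth = gen_expression(default_expression_config(SEED))
    write_expression_tsv(em, OUT / "expression.tsv")
    write_gmt(pmap, OUT / "pathways.gmt")
    (OUT / "truth_expression.json").write_text(
        json.dumps(truth.params, default=str, indent=1))
    print(f"expression cohort: {em.n_samples} samples x {em.n_genes} genes, "
          f"{len(truth['affected_genes'])} genes in affected pathways")

    # causal (theta=0.1) and null eQTL/disease pairs for the MR step
    for name, theta in [("causal", 0.1), ("null", 0.0)]:
        exp, out, _ = gen_two_sample_gwas(
            MRSimConfig(n_snps=30, theta=theta, seed=SEED + hashstr(name)))
        write_sumstats_tsv(exp, OUT / f"eqtl_{name}.tsv")
        write_sumstats_tsv(out, OUT / f"gwas_{name}.tsv")
    print("two-sample GWAS pairs written (theta = 0.1 and 0)")

    for hypo, idx2 in [("H0", 150), ("H3", 225), ("H4", 150)]:
        region, _ = gen_region_pair(RegionSimConfig(
            n_snps=300, hypothesis=hypo, causal_index_1=150,
            causal_index_2=idx2, seed=SEED + hashstr(hypo)))
        write_sumstats_tsv(region.trait1, OUT / f"region_{hypo}_eqtl.tsv")
        write_sumstats_tsv(region.trait2, OUT / f"region_{hypo}_gwas.tsv")
        (OUT / f"region_{hypo}_anchor.txt").write_text(region.anchor_snp)
    print("colocalization regions written for H0, H3, H4")

    panel, panel_truth = gen_trait_panel(
        n_traits=40, n_snps=5, effects=[(0, 0, 8.0)], seed=SEED + 5)
    write_trait_panel(panel, OUT / "trait_panel.tsv")
    print(f"trait panel: 40 traits x 5 SNPs, injected hit "
          f"{panel_truth['effects'][0][:2]}")

    table, drug_truth = gen_drug_table(
        [f"G{i + 1:04d}" for i in range(10)], drugs_per_gene=3,
        multi_target_fraction=0.3, seed=SEED + 6)
    write_drug_table(table, OUT / "drug_table.tsv")
    print(f"drug table: {len(table)} interactions, "
          f"{len(drug_truth['multi_target_drugs'])} multi-target drugs")


def hashstr(s: str) -> int:
    import zlib
    return zlib.crc32(s.encode()) % 10_000


if __name__ == "__main__":
    main()
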