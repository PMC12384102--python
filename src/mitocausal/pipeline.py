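"""End-to-end synthetic study: expression ML -> MR -> coloc -> PheWAS -> drugs.

``run_all`` drives every stage on generated inputs with controllable ground
truth, writing each intermediate artifact, a provenance log (seeds,
thresholds, versions) and a summary report into a run directory. The stage
order mirrors the analysis workflow: pathway-structured classification
ranks genes, MR tests their causal effect on the disease, colocalization
checks for shared variants, PheWAS plus bidirectional MR probe flagged SNPs
against a trait panel, and the drug stage aggregates multi-target combined
importances.
"""

from __future__ import annotations

import json
import sys
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import TruthRecord
from .coloc import ColocConfig, run_coloc
from .drugs import map_genes_to_drugs, rank_drugs
from .expression import filter_pathways, preprocess
from .io import (
    PipelineConfig,
    write_drug_table,
    write_expression_tsv,
    write_gmt,
    write_sumstats_tsv,
    write_trait_panel,
)
from .mr import MRConfig, adjust_exposures, run_mr
from .pathway_ml import CVConfig, score_pathways, select_top_pathways, total_importance
from .phewas import bidirectional_mr, phewas_scan, select_coloc_snps
from .synth import (
    ExprSimConfig,
    MRSimConfig,
    RegionSimConfig,
    gen_drug_table,
    gen_expression,
    gen_region_pair,
    gen_trait_panel,
    gen_two_sample_gwas,
)

__all__ = ["run_all", "default_expression_config"]

N_MR_GENES = 6  # top-ranked genes carried into the MR stage


def default_expression_config(seed: int) -> ExprSimConfig:
    """The default synthetic cohort: 8 ten-gene pathways, 3 affected."""
    return ExprSimConfig(
        n_cases=60, n_controls=60, n_genes=80,
        pathway_sizes=[10] * 8,
        affected_pathways={"PW001", "PW002", "PW003"},
        mean_shift=0.8, var_inflation=1.5,
        n_batches=2, batch_shift=0.5,
        missing_rate=0.02, outlier_rate=0.01,
        seed=seed,
    )


def _seed_for(base: int, stage: str) -> int:
    tag = zlib.crc32(stage.encode()) % (2**31)
    return int(np.random.SeedSequence([base, tag]).generate_state(1)[0] % (2**31))


def run_all(config: PipelineConfig | None = None) -> Path:
    """Execute the configured stages; returns the run directory."""
    cfg = config or PipelineConfig()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.seed)
    summary: dict = {}
    provenance = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "seed": seed,
        "thresholds": {
            "mr_p_threshold": cfg.mr_p_threshold, "mr_r2_max": cfg.mr_r2_max,
            "mr_window_kb": cfg.mr_window_kb, "mr_f_min": cfg.mr_f_min,
            "variance_threshold": cfg.variance_threshold,
            "min_pathway_genes": cfg.min_pathway_genes,
            "coloc_half_windows_kb": cfg.coloc_half_windows_kb,
            "coloc_snp_target": cfg.coloc_snp_target,
            "coloc_priors": cfg.coloc_priors,
            "snp_pp_h4_high": cfg.snp_pp_h4_high,
            "fdr_q": cfg.fdr_q,
        },
    }

    def fail(stage: str, exc: Exception):
        raise RuntimeError(
            f"pipeline stage {stage!r} failed ({exc}); partial outputs in {out}"
        ) from exc

    # --- stage 1: simulate + preprocess + pathway ML -----------------------
    expr_cfg = default_expression_config(_seed_for(seed, "expression"))
    em, pmap, expr_truth = gen_expression(expr_cfg)
    write_expression_tsv(em, out / "expression.tsv")
    write_gmt(pmap, out / "pathways.gmt")
    (out / "truth_expression.json").write_text(
        json.dumps(expr_truth.params, default=str, indent=1))

    ranking = None
    mr_sig_genes: list = []
    causal_genes: set = set(expr_truth["affected_genes"][:N_MR_GENES])
    if cfg.run_ml:
        try:
            prepped, removed = preprocess(em, cfg.variance_threshold)
            pmap_f = filter_pathways(pmap, prepped, cfg.min_pathway_genes)
            cv = CVConfig(n_folds=cfg.cv_folds, seed=_seed_for(seed, "cv"),
                          model_set=list(cfg.model_set))
            scorecard = score_pathways(prepped, pmap_f, cv)
            selected = select_top_pathways(scorecard)
            ranking = total_importance(scorecard, selected, pmap_f)
            scorecard.table.to_csv(out / "pathway_scores.tsv", sep="\t")
            ranking.table.to_csv(out / "gene_ranking.tsv", sep="\t")
            summary["ml"] = {
                "n_pathways_scored": len(scorecard.table),
                "n_pathways_selected": len(selected),
                "removed_low_variance": removed,
                "top_gene": ranking.table.index[0],
            }
        except Exception as exc:  # noqa: BLE001
            fail("ml", exc)

    # --- stage 2: MR over the top-ranked genes -----------------------------
    mr_cfg = MRConfig(p_threshold=cfg.mr_p_threshold, r2_max=cfg.mr_r2_max,
                      window_kb=cfg.mr_window_kb, f_min=cfg.mr_f_min,
                      seed=_seed_for(seed, "mr"))
    mr_rows = []
    if cfg.run_mr:
        try:
            genes = (list(ranking.table.index[:N_MR_GENES]) if ranking is not None
                     else sorted(causal_genes))
            for gi, gene in enumerate(genes):
                theta = 0.1 if gene in set(expr_truth["affected_genes"]) else 0.0
                exp_s, out_s, _ = gen_two_sample_gwas(MRSimConfig(
                    n_snps=30, theta=theta, seed=_seed_for(seed, f"mr_{gene}")))
                write_sumstats_tsv(exp_s, out / f"eqtl_{gene}.tsv")
                res = run_mr(exp_s, out_s, None, mr_cfg)
                e = res.estimate("IVW")
                mr_rows.append({
                    "gene": gene, "beta": e["beta"], "se": e["se"], "p": e["p"],
                    "OR": e["OR"], "OR_lo": e["OR_lo"], "OR_hi": e["OR_hi"],
                    "n_snps": e["n_snps"], "q_p": res.q_p,
                    "presso_global_p": res.presso_global_p,
                })
            mr_table = pd.DataFrame(mr_rows).set_index("gene")
            adj = adjust_exposures(mr_table["p"], method="fdr_bh", alpha=cfg.fdr_q)
            mr_table["p_adj"] = adj["p_adj"]
            mr_table["significant"] = adj["significant"]
            mr_sig_genes = list(mr_table.index[mr_table["significant"]])
            mr_table.to_csv(out / "mr_results.tsv", sep="\t")
            summary["mr"] = {"n_genes": len(mr_table),
                             "significant_genes": mr_sig_genes}
        except Exception as exc:  # noqa: BLE001
            fail("mr", exc)

    # --- stage 3: colocalization around MR-significant genes ---------------
    coloc_reports = {}
    if cfg.run_coloc:
        try:
            p1, p2, p12 = cfg.coloc_priors
            ccfg = ColocConfig(half_windows_kb=tuple(cfg.coloc_half_windows_kb),
                               snp_target=cfg.coloc_snp_target,
                               p1=p1, p2=p2, p12=p12)
            rows = []
            for gene in (mr_sig_genes or sorted(causal_genes)):
                hypo = "H4" if gene in set(expr_truth["affected_genes"]) else "H0"
                region, _ = gen_region_pair(RegionSimConfig(
                    n_snps=300, hypothesis=hypo,
                    causal_index_1=150, causal_index_2=150,
                    seed=_seed_for(seed, f"coloc_{gene}")))
                post = run_coloc(region.anchor_snp, region.trait1, region.trait2,
                                 ccfg)
                coloc_reports[gene] = post
                rows.append({"gene": gene, "window_kb": post.window_kb,
                             "n_snps": post.n_snps, **post.pp.to_dict(),
                             "top_snp": post.top_snp,
                             "top_snp_pp_h4": float(post.snp_pp_h4.max()),
                             "flag": post.flag})
            pd.DataFrame(rows).to_csv(out / "coloc_results.tsv", sep="\t",
                                      index=False)
            summary["coloc"] = {
                "n_regions": len(rows),
                "high": [r["gene"] for r in rows if r["flag"] == "high"],
            }
        except Exception as exc:  # noqa: BLE001
            fail("coloc", exc)

    # --- stage 4: PheWAS + bidirectional MR --------------------------------
    if cfg.run_phewas:
        try:
            snps = select_coloc_snps(coloc_reports)
            panel_snp_names = list(snps["SNP"]) if len(snps) else ["rs00151"]
            panel, _ = gen_trait_panel(
                n_traits=40, n_snps=len(panel_snp_names),
                effects=[(0, 0, 8.0)], seed=_seed_for(seed, "panel"))
            panel["SNP"] = np.tile(panel_snp_names, 40)
            write_trait_panel(panel, out / "trait_panel.tsv")
            hits = phewas_scan(panel_snp_names, panel, cfg.fdr_q)
            hits.to_csv(out / "phewas_hits.tsv", sep="\t", index=False)
            bidir_summary = pd.DataFrame()
            if len(hits):
                t_exp, d_out, _ = gen_two_sample_gwas(MRSimConfig(
                    n_snps=30, theta=0.1, seed=_seed_for(seed, "bidir_f")))
                d_exp, t_out, _ = gen_two_sample_gwas(MRSimConfig(
                    n_snps=30, theta=0.0, seed=_seed_for(seed, "bidir_r")))
                d_exp["SNP"] = "x" + d_exp["SNP"]
                t_out["SNP"] = "x" + t_out["SNP"]
                trait_stats = pd.concat([t_exp, t_out], ignore_index=True)
                disease_stats = pd.concat([d_out, d_exp], ignore_index=True)
                bidir = bidirectional_mr(trait_stats, disease_stats, None, mr_cfg)
                bidir_summary = bidir.summary
            bidir_summary.to_csv(out / "bidirectional_mr.tsv", sep="\t",
                                 index=False)
            summary["phewas"] = {"n_coloc_snps": len(panel_snp_names),
                                 "n_hits": len(hits)}
        except Exception as exc:  # noqa: BLE001
            fail("phewas", exc)

    # --- stage 5: drug ranking ---------------------------------------------
    if cfg.run_drugs:
        try:
            genes_for_drugs = mr_sig_genes or sorted(causal_genes)
            table, drug_truth = gen_drug_table(
                genes_for_drugs, drugs_per_gene=3, multi_target_fraction=0.3,
                seed=_seed_for(seed, "drugs"))
            write_drug_table(table, out / "drug_table.tsv")
            importances = (ranking.table["total_importance"]
                           if ranking is not None
                           else pd.Series(1.0, index=genes_for_drugs))
            dr = map_genes_to_drugs(
                {"disease": importances},
                table, gene_filter={"disease": genes_for_drugs})
            report = rank_drugs(dr)
            report.to_csv(out / "drug_ranking.tsv", sep="\t", index=False)
            summary["drugs"] = {
                "n_drugs_ranked": len(report),
                "true_multi_target": drug_truth["multi_target_drugs"],
            }
        except Exception as exc:  # noqa: BLE001
            fail("drugs", exc)

    with open(out / "provenance.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(provenance, fh, sort_keys=False)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return out
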