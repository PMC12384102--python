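"""Drug-target mapping and multi-target combined-importance ranking.

Prioritized genes (per disease, each carrying an importance score) are
joined to a bipartite drug-target table; every drug accumulates one
contribution per (disease, targeted gene) and its combined importance is
the sum of those contributions. Multi-target drugs — those with surviving
targets in at least two diseases — address shared vulnerabilities and can
be ranked separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .containers import ValidationError

__all__ = ["DrugRanking", "map_genes_to_drugs", "rank_drugs"]

DRUG_TABLE_COLUMNS = ["drug_id", "drug_name", "gene", "source", "sign"]


@dataclass
class DrugRanking:
    """Per-drug combined importance plus its contribution ledger."""

    table: pd.DataFrame         # index drug_id; drug_name, combined_importance,
                                # n_targets, n_diseases
    contributions: pd.DataFrame  # drug_id, disease, gene, importance


def map_genes_to_drugs(rankings: dict, table: pd.DataFrame,
                       gene_filter: dict | None = None) -> DrugRanking:
    """Join per-disease gene importances onto the drug-target table.

    ``rankings`` maps disease -> Series of importance indexed by gene
    (typically the Total Importance restricted to MR-significant genes);
    ``gene_filter`` optionally maps disease -> iterable of genes allowed to
    contribute (e.g. the MR-significant set). Drugs with no surviving
    targets are absent from the result.
    """
    if not rankings:
        raise ValidationError("rankings must be nonempty")
    if table.empty:
        raise ValidationError("drug-target table is empty")
    if table.duplicated(["drug_id", "gene"]).any():
        raise ValidationError("drug-target table has duplicate (drug, gene) pairs")
    rows = []
    for disease, scores in rankings.items():
        scores = pd.Series(scores)
        if gene_filter is not None:
            allowed = set(gene_filter.get(disease, []))
            scores = scores[scores.index.isin(allowed)]
        hits = table[table["gene"].isin(scores.index)]
        for _, r in hits.iterrows():
            rows.append((r["drug_id"], r.get("drug_name", r["drug_id"]),
                         disease, r["gene"], float(scores[r["gene"]])))
    contributions = pd.DataFrame(
        rows, columns=["drug_id", "drug_name", "disease", "gene", "importance"])
    if contributions.empty:
        table_out = pd.DataFrame(
            columns=["drug_name", "combined_importance", "n_targets", "n_diseases"])
        table_out.index.name = "drug_id"
        return DrugRanking(table_out, contributions)
    grouped = contributions.groupby("drug_id").agg(
        drug_name=("drug_name", "first"),
        combined_importance=("importance", "sum"),
        n_targets=("gene", "nunique"),
        n_diseases=("disease", "nunique"),
    )
    return DrugRanking(grouped, contributions)


def rank_drugs(ranking: DrugRanking, multi_target_only: bool = False) -> pd.DataFrame:
    """Order drugs by descending combined importance; ties by drug id.

    With ``multi_target_only`` the report is restricted to drugs whose
    surviving targets span at least two diseases.
    """
    tab = ranking.table
    if multi_target_only:
        tab = tab[tab["n_diseases"] >= 2]
    return (tab.reset_index()
            .sort_values(["combined_importance", "drug_id"],
                         ascending=[False, True], kind="mergesort")
            .reset_index(drop=True))
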