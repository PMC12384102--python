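"""Phenome-wide screening of colocalized SNPs and bidirectional MR.

SNPs with a per-SNP shared-variant posterior above 0.8 are screened against
a trait association panel with per-SNP BH-FDR across traits; flagged traits
are then tested against the disease in both causal directions with
independently selected instrument sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import ValidationError
from .mr import MRConfig, MRResult, run_mr

__all__ = [
    "select_coloc_snps",
    "phewas_scan",
    "BidirResult",
    "bidirectional_mr",
]

SNP_PP_H4_CUTOFF = 0.8
LOW_INSTRUMENT_THRESHOLD = 10


def select_coloc_snps(reports: dict) -> pd.DataFrame:
    """SNPs with per-SNP PP.H4 strictly above 0.8, deduplicated.

    ``reports`` maps a gene (or region) name to its :class:`ColocPosteriors`.
    Returns a table (SNP, genes, max_snp_pp_h4) keeping provenance for
    SNPs shared across genes.
    """
    rows: dict = {}
    for gene, post in reports.items():
        for snp, pp in post.snp_pp_h4.items():
            if pp > SNP_PP_H4_CUTOFF:
                entry = rows.setdefault(snp, {"genes": [], "max_snp_pp_h4": 0.0})
                entry["genes"].append(gene)
                entry["max_snp_pp_h4"] = max(entry["max_snp_pp_h4"], float(pp))
    if not rows:
        return pd.DataFrame(columns=["SNP", "genes", "max_snp_pp_h4"])
    return pd.DataFrame(
        [(snp, sorted(v["genes"]), v["max_snp_pp_h4"]) for snp, v in rows.items()],
        columns=["SNP", "genes", "max_snp_pp_h4"],
    )


def phewas_scan(snps, panel: pd.DataFrame, fdr_q: float = 0.05,
                method: str = "fdr_bh") -> pd.DataFrame:
    """Screen SNPs across a trait panel; per-SNP FDR across traits.

    Returns the annotated hits table (SNP, trait, BETA, SE, P, p_adj).
    SNPs absent from the panel contribute zero tests and are logged in the
    result's ``attrs["missing"]``.
    """
    hits = []
    missing = []
    for snp in snps:
        sub = panel[panel["SNP"] == snp]
        if sub.empty:
            missing.append(snp)
            continue
        reject, p_adj, _, _ = multipletests(sub["P"].to_numpy(float),
                                            alpha=fdr_q, method=method)
        keep = sub.loc[reject].copy()
        keep["p_adj"] = p_adj[reject]
        hits.append(keep)
    out = (pd.concat(hits, ignore_index=True) if hits
           else pd.DataFrame(columns=list(panel.columns) + ["p_adj"]))
    out.attrs["missing"] = missing
    return out


@dataclass
class BidirResult:
    """Forward (trait -> disease) and reverse (disease -> trait) MR results."""

    forward: MRResult | None
    reverse: MRResult | None
    forward_error: str = ""
    reverse_error: str = ""
    caution: bool = False
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)


def _direction(exposure, outcome, ld, cfg) -> tuple:
    try:
        return run_mr(exposure, outcome, ld, cfg), ""
    except ValidationError as exc:
        return None, str(exc)


def bidirectional_mr(trait_stats: pd.DataFrame, disease_stats: pd.DataFrame,
                     ld=None, config: MRConfig | None = None) -> BidirResult:
    """Run MR in both directions with direction-appropriate instruments.

    Each direction selects instruments from its own exposure table; SNPs
    already serving as forward instruments are excluded from the reverse
    candidate pool (a strong trait instrument can reach genome-wide
    significance for the disease through the causal path itself), keeping
    the two instrument sets disjoint (asserted). The
    summary table retains only p < 0.05 rows, a reporting-level filter; the
    full per-method results stay on the result object. A caution flag is
    set when either direction rests on fewer than 10 instruments.
    """
    cfg = config or MRConfig()
    fwd, fwd_err = _direction(trait_stats, disease_stats, ld, cfg)
    reverse_pool = disease_stats
    if fwd is not None:
        used = set(fwd.harmonized.df["SNP"])
        reverse_pool = disease_stats[~disease_stats["SNP"].isin(used)]
    rev, rev_err = _direction(reverse_pool, trait_stats, ld, cfg)
    if fwd is None and rev is None:
        raise ValidationError("no instruments in either direction: "
                              f"{fwd_err} / {rev_err}")
    if fwd is not None and rev is not None:
        shared = set(fwd.harmonized.df["SNP"]) & set(rev.harmonized.df["SNP"])
        if shared:
            raise ValidationError(
                f"forward and reverse analyses share instruments: {sorted(shared)[:5]}"
            )
    caution = any(
        r is not None and r.harmonized.n_snps < LOW_INSTRUMENT_THRESHOLD
        for r in (fwd, rev)
    )
    frames = []
    for direction, res in (("forward", fwd), ("reverse", rev)):
        if res is None:
            continue
        tab = res.estimates.copy()
        tab.insert(0, "direction", direction)
        frames.append(tab)
    full = pd.concat(frames, ignore_index=True)
    summary = full[full["p"] < 0.05].reset_index(drop=True)
    return BidirResult(fwd, rev, fwd_err, rev_err, caution, summary)
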