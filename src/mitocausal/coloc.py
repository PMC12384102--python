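"""Bayesian colocalization with adaptive expansion windows.

Each SNP contributes a Wakefield approximate Bayes factor per trait;
hypothesis evidence is accumulated in log space over all single-causal
configurations (H1/H2: one trait causal; H3: two distinct causal variants;
H4: one shared variant) with priors p1, p2, p12, and normalized against H0.

The analysis window around the anchor SNP is chosen adaptively: candidate
half-windows are evaluated in increasing order, expansion halts after the
first window whose SNP count exceeds the target (default 500), and the
evaluated window with the count closest to the target wins (ties to the
smaller window, for regional specificity against long-range LD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .containers import ValidationError

__all__ = [
    "ColocConfig",
    "RegionPair",
    "ColocPosteriors",
    "wakefield_log_abf",
    "adaptive_window",
    "coloc_posteriors",
    "run_coloc",
]


@dataclass
class ColocConfig:
    """Windows, priors and effect-size prior SDs.

    ``priors = (p1, p2, p12)`` are the per-SNP prior probabilities of
    trait-1-only, trait-2-only and shared causality (canonical defaults).
    ``W`` is the Wakefield prior SD of true effects: 0.15 for quantitative
    traits, 0.2 on the log-odds scale for case-control.
    """

    half_windows_kb: tuple = (10, 50, 100, 200)
    snp_target: int = 500
    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    w_quant: float = 0.15
    w_cc: float = 0.2
    trait1_type: str = "quantitative"
    trait2_type: str = "quantitative"

    def __post_init__(self) -> None:
        hw = list(self.half_windows_kb)
        if hw != sorted(hw) or len(set(hw)) != len(hw):
            raise ValidationError("half-windows must be strictly increasing")
        for p in (self.p1, self.p2, self.p12):
            if not (0 < p < 1):
                raise ValidationError("priors must lie in (0,1)")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValidationError("p1 + p2 + p12 must be < 1")

    def prior_sd(self, which: int) -> float:
        t = self.trait1_type if which == 1 else self.trait2_type
        return self.w_cc if t == "case-control" else self.w_quant


@dataclass
class RegionPair:
    """Aligned summary stats for two traits over identical SNPs/positions."""

    trait1: pd.DataFrame
    trait2: pd.DataFrame
    anchor_snp: str = ""
    n1: float = np.nan
    n2: float = np.nan

    def __post_init__(self) -> None:
        if not np.array_equal(self.trait1["SNP"].to_numpy(),
                              self.trait2["SNP"].to_numpy()):
            raise ValidationError("trait tables must share identical SNPs in order")
        if not np.array_equal(self.trait1["POS"].to_numpy(),
                              self.trait2["POS"].to_numpy()):
            raise ValidationError("trait tables must share identical positions")
        pos = self.trait1["POS"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValidationError("positions must be sorted")

    @property
    def n_snps(self) -> int:
        return len(self.trait1)

    def subset(self, mask) -> "RegionPair":
        return RegionPair(self.trait1[mask].reset_index(drop=True),
                          self.trait2[mask].reset_index(drop=True),
                          self.anchor_snp, self.n1, self.n2)


@dataclass
class ColocPosteriors:
    """The five regional posteriors plus the per-SNP shared-variant posterior."""

    pp: pd.Series            # index H0..H4, sums to 1
    snp_pp_h4: pd.Series     # per-SNP posterior conditional on H4, sums to 1
    window_kb: float = np.nan
    n_snps: int = 0
    flag: str = ""           # "high" (>0.8), "suggestive" (>0.6) or ""

    @property
    def top_snp(self) -> str:
        return str(self.snp_pp_h4.idxmax())


def wakefield_log_abf(beta, se, W: float) -> np.ndarray:
    """Log approximate Bayes factor (alternative vs null) for one association.

    With shrinkage ``r = W^2/(se^2+W^2)`` and ``z = beta/se``:
    ``log ABF = 0.5 log(1-r) + z^2 r / 2``.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValidationError("se must be > 0")
    if W <= 0:
        raise ValidationError("prior SD W must be > 0")
    r = W ** 2 / (se ** 2 + W ** 2)
    z = beta / se
    return 0.5 * np.log1p(-r) + z ** 2 * r / 2.0


def adaptive_window(positions: np.ndarray, anchor_pos: float,
                    cfg: ColocConfig) -> tuple:
    """Choose the expansion half-window; returns (window_kb, mask, counts).

    Candidates are tried smallest-first; evaluation stops after the first
    candidate whose SNP count exceeds ``snp_target`` (that candidate is
    still eligible). Among evaluated candidates the count closest to the
    target wins; ties go to the smaller window.
    """
    positions = np.asarray(positions)
    counts = {}
    for hw in cfg.half_windows_kb:
        mask = np.abs(positions - anchor_pos) <= hw * 1000
        counts[hw] = int(mask.sum())
        if counts[hw] > cfg.snp_target:
            break
    best = min(counts, key=lambda hw: (abs(counts[hw] - cfg.snp_target), hw))
    if counts[best] == 0:
        raise ValidationError("no SNPs inside the largest evaluated window")
    mask = np.abs(positions - anchor_pos) <= best * 1000
    return best, mask, counts


def coloc_posteriors(region: RegionPair, cfg: ColocConfig | None = None) -> ColocPosteriors:
    """Posterior probabilities of H0..H4 for one aligned region.

    Evidence sums run over every causal configuration in log space:
    ``H1 = p1 sum_j ABF1_j``, ``H2`` symmetric, ``H3 = p1 p2 sum_{j != k}
    ABF1_j ABF2_k``, ``H4 = p12 sum_j ABF1_j ABF2_j``, ``H0 = 1``.
    """
    cfg = cfg or ColocConfig()
    n = region.n_snps
    if n < 1:
        raise ValidationError("region must contain at least one SNP")
    labf1 = wakefield_log_abf(region.trait1["BETA"], region.trait1["SE"],
                              cfg.prior_sd(1))
    labf2 = wakefield_log_abf(region.trait2["BETA"], region.trait2["SE"],
                              cfg.prior_sd(2))
    ls1 = logsumexp(labf1)
    ls2 = logsumexp(labf2)
    ls12 = logsumexp(labf1 + labf2)

    lh = np.full(5, -np.inf)
    lh[0] = 0.0
    lh[1] = np.log(cfg.p1) + ls1
    lh[2] = np.log(cfg.p2) + ls2
    # sum over j != k equals (sum_j)(sum_k) minus the diagonal
    if n > 1:
        cross = ls1 + ls2
        with np.errstate(divide="ignore"):  # diagonal may carry all the mass
            diff = cross + np.log1p(-np.exp(np.minimum(ls12 - cross, 0.0)))
        if np.isfinite(diff):
            lh[3] = np.log(cfg.p1) + np.log(cfg.p2) + diff
    lh[4] = np.log(cfg.p12) + ls12

    pp = np.exp(lh - logsumexp(lh))
    pp = pp / pp.sum()
    snp_pp = np.exp((labf1 + labf2) - ls12)
    snp_pp = snp_pp / snp_pp.sum()
    return ColocPosteriors(
        pp=pd.Series(pp, index=["H0", "H1", "H2", "H3", "H4"]),
        snp_pp_h4=pd.Series(snp_pp, index=region.trait1["SNP"].to_numpy()),
        n_snps=n,
    )


def clean_pvalues(df: pd.DataFrame) -> pd.DataFrame:
    """Replace extreme/invalid p-values (<=0, >1, NaN) by representable bounds."""
    out = df.copy()
    p = out["P"].to_numpy(float)
    p = np.where(~np.isfinite(p), 1.0, p)
    out["P"] = np.clip(p, 1e-300, 1.0)
    return out


def run_coloc(anchor_snp: str, eqtl: pd.DataFrame, disease: pd.DataFrame,
              cfg: ColocConfig | None = None) -> ColocPosteriors:
    """Align two trait tables on shared SNPs, pick the adaptive window around
    the anchor, and compute colocalization posteriors.

    The high/suggestive flags use the top per-SNP PP.H4 score against the
    0.8 / 0.6 cutoffs; the regional PP.H4 is reported alongside in ``pp``.
    """
    cfg = cfg or ColocConfig()
    shared = np.intersect1d(eqtl["SNP"].to_numpy(), disease["SNP"].to_numpy())
    if shared.size == 0:
        raise ValidationError("no shared SNPs between the two traits")
    e = clean_pvalues(eqtl[eqtl["SNP"].isin(shared)]).sort_values("POS")
    d = clean_pvalues(disease[disease["SNP"].isin(shared)])
    d = d.set_index("SNP").loc[e["SNP"]].reset_index()
    region = RegionPair(e.reset_index(drop=True), d[e.columns],
                        anchor_snp=anchor_snp)
    anchor_rows = region.trait1.loc[region.trait1["SNP"] == anchor_snp, "POS"]
    if anchor_rows.empty:
        raise ValidationError(f"anchor SNP {anchor_snp!r} not in the shared set")
    window_kb, mask, _ = adaptive_window(
        region.trait1["POS"].to_numpy(), float(anchor_rows.iloc[0]), cfg)
    post = coloc_posteriors(region.subset(mask), cfg)
    post.window_kb = float(window_kb)
    top = float(post.snp_pp_h4.max())
    post.flag = "high" if top > 0.8 else ("suggestive" if top > 0.6 else "")
    return post
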