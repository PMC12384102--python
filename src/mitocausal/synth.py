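"""Seeded generators for every input the pipeline consumes.

Each generator returns its artifact together with a :class:`TruthRecord`
holding the injected ground truth (affected genes, causal effect theta,
per-SNP pleiotropy, causal SNP indices, multi-target drug set), so recovery
can be scored without re-deriving anything from the outputs.

Conventions
-----------
* Expression values are Gaussian on a log-like scale; control genes have unit
  SD, cases in affected pathways get a mean shift (in SD units) and a
  variance inflation factor.
* Summary-statistic standard errors follow ``1/sqrt(2 maf (1-maf) n)`` on the
  standardized-trait scale (case-control effects are on the log-odds scale
  with the same form, with an effective-n correction for the case fraction).
* LD is simulated at the z-score level with AR(1) adjacent-SNP correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    SUMSTATS_COLUMNS,
    ExpressionMatrix,
    TruthRecord,
    se_from_maf_n,
    validate_sumstats,
)

__all__ = [
    "ExprSimConfig",
    "MRSimConfig",
    "RegionSimConfig",
    "gen_expression",
    "gen_two_sample_gwas",
    "gen_region_pair",
    "gen_trait_panel",
    "gen_drug_table",
]

_P_FLOOR = 1e-300  # keep p-values representable and strictly positive

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


class ConfigError(ValueError):
    """A simulation config violates its invariants."""


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class ExprSimConfig:
    """Case/control expression cohort with pathway-localized shifts.

    ``mean_shift`` is expressed in within-gene SD units; ``var_inflation``
    multiplies the case variance of affected genes; ``batch_shift`` is an
    additive offset between consecutive batches.
    """

    n_cases: int = 60
    n_controls: int = 60
    n_genes: int = 80
    pathway_sizes: list = field(default_factory=lambda: [10] * 8)
    affected_pathways: set = field(default_factory=set)
    mean_shift: float = 0.0
    var_inflation: float = 1.0
    n_batches: int = 1
    batch_shift: float = 0.0
    missing_rate: float = 0.0
    outlier_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise ConfigError("need at least 2 cases and 2 controls")
        if any(s < 1 for s in self.pathway_sizes):
            raise ConfigError("pathway sizes must all be >= 1")
        if sum(self.pathway_sizes) > self.n_genes:
            raise ConfigError("pathway sizes exceed the number of genes")
        for rate in (self.missing_rate, self.outlier_rate):
            if not (0.0 <= rate < 1.0):
                raise ConfigError("rates must lie in [0,1)")
        if self.var_inflation < 0:
            raise ConfigError("var_inflation must be >= 0")
        names = self.pathway_names()
        unknown = set(self.affected_pathways) - set(names)
        if unknown:
            raise ConfigError(f"affected pathways not generated: {sorted(unknown)}")

    def pathway_names(self) -> list:
        return [f"PW{k + 1:03d}" for k in range(len(self.pathway_sizes))]


def gen_expression(cfg: ExprSimConfig):
    """Simulate an expression cohort; returns (matrix, pathway map, truth).

    Genes are partitioned into pathways per ``cfg.pathway_sizes`` (left-over
    genes stay pathway-free background). Genes in affected pathways have case
    mean shifted by ``mean_shift`` SD and case variance multiplied by
    ``var_inflation``; batch offsets, MCAR missingness and +/-6 SD outliers
    are injected afterwards, in that order.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cases + cfg.n_controls
    genes = [f"G{j + 1:04d}" for j in range(cfg.n_genes)]
    samples = [f"S{i + 1:04d}" for i in range(n)]
    labels = pd.Series([1] * cfg.n_cases + [0] * cfg.n_controls,
                       index=samples, name="label")

    pmap: dict = {}
    cursor = 0
    for name, size in zip(cfg.pathway_names(), cfg.pathway_sizes):
        pmap[name] = set(genes[cursor:cursor + size])
        cursor += size
    affected_genes = sorted(set().union(*(pmap[p] for p in cfg.affected_pathways))
                            if cfg.affected_pathways else set())

    base_mean = rng.normal(7.0, 1.0, size=cfg.n_genes)
    values = rng.normal(base_mean, 1.0, size=(n, cfg.n_genes))
    is_case = labels.to_numpy() == 1
    aff_idx = np.array([genes.index(g) for g in affected_genes], dtype=int)
    if aff_idx.size:
        block = values[np.ix_(is_case, aff_idx)]
        mu = base_mean[aff_idx]
        values[np.ix_(is_case, aff_idx)] = (
            mu + cfg.mean_shift + (block - mu) * np.sqrt(cfg.var_inflation)
        )

    batch = pd.Series(np.arange(n) % cfg.n_batches, index=samples, name="batch")
    # shuffle batch membership so batches are not confounded with label
    batch[:] = rng.permutation(batch.to_numpy())
    offsets = (np.arange(cfg.n_batches) - (cfg.n_batches - 1) / 2.0) * cfg.batch_shift
    values = values + offsets[batch.to_numpy()][:, None]

    n_out = int(round(cfg.outlier_rate * values.size))
    outlier_cells = []
    if n_out:
        flat = rng.choice(values.size, size=n_out, replace=False)
        rows, cols = np.unravel_index(flat, values.shape)
        signs = rng.choice([-1.0, 1.0], size=n_out)
        values[rows, cols] = base_mean[cols] + signs * 6.0
        outlier_cells = list(zip(rows.tolist(), cols.tolist()))

    n_miss = int(round(cfg.missing_rate * values.size))
    if n_miss:
        flat = rng.choice(values.size, size=n_miss, replace=False)
        rows, cols = np.unravel_index(flat, values.shape)
        values[rows, cols] = np.nan

    em = ExpressionMatrix(
        pd.DataFrame(values, index=samples, columns=genes), labels, batch
    )
    truth = TruthRecord("expression", {
        "affected_pathways": sorted(cfg.affected_pathways),
        "affected_genes": affected_genes,
        "mean_shift": cfg.mean_shift,
        "var_inflation": cfg.var_inflation,
        "outlier_cells": outlier_cells,
    })
    return em, pmap, truth


# ---------------------------------------------------------------------------
# two-sample GWAS pairs
# ---------------------------------------------------------------------------

@dataclass
class MRSimConfig:
    """Exposure/outcome summary-statistic pair under causal effect theta.

    ``gamma_dist`` specifies the SNP-exposure effects: ``("normal", mu, sd)``,
    ``("uniform", lo, hi)`` or an explicit sequence of per-SNP values.
    A ``frac_invalid`` fraction of SNPs carries pleiotropy
    ``alpha_j ~ N(pleiotropy_mean, pleiotropy_sd)`` acting directly on the
    outcome.
    """

    n_snps: int = 30
    theta: float = 0.0
    gamma_dist: object = ("normal", 0.1, 0.02)
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    frac_invalid: float = 0.0
    n_exposure: int = 100_000
    n_outcome: int = 100_000
    maf_range: tuple = (0.1, 0.5)
    outcome_type: str = "quantitative"
    case_fraction: float = 0.5
    palindromic_fraction: float = 0.0
    outcome_swap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        if not (0.0 <= self.frac_invalid <= 1.0):
            raise ConfigError("frac_invalid must lie in [0,1]")
        if self.n_exposure < 100 or self.n_outcome < 100:
            raise ConfigError("sample sizes must be >= 100")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if self.outcome_type not in ("quantitative", "case-control"):
            raise ConfigError("outcome_type must be quantitative or case-control")
        if isinstance(self.gamma_dist, (tuple, list)) and len(self.gamma_dist) == 0:
            raise ConfigError("empty gamma_dist")


def _draw_gamma(spec, n_snps: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec, (tuple, list)) and spec and isinstance(spec[0], str):
        kind = spec[0]
        if kind == "normal":
            return rng.normal(spec[1], spec[2], size=n_snps)
        if kind == "uniform":
            return rng.uniform(spec[1], spec[2], size=n_snps)
        raise ConfigError(f"unknown gamma_dist kind: {kind}")
    arr = np.asarray(spec, dtype=float)
    if arr.size == 0:
        raise ConfigError("empty gamma_dist")
    if arr.size != n_snps:
        raise ConfigError("explicit gamma_dist length must equal n_snps")
    return arr


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, _P_FLOOR, 1.0)


def _assign_alleles(n_snps, palindromic_fraction, rng):
    n_pal = int(round(palindromic_fraction * n_snps))
    pal = np.zeros(n_snps, dtype=bool)
    if n_pal:
        pal[rng.choice(n_snps, size=n_pal, replace=False)] = True
    ea, oa = [], []
    for flag in pal:
        pool = _PALINDROMIC_PAIRS if flag else _NONPALINDROMIC_PAIRS
        a, b = pool[rng.integers(len(pool))]
        ea.append(a)
        oa.append(b)
    return np.array(ea), np.array(oa)


def gen_two_sample_gwas(cfg: MRSimConfig):
    """Simulate an exposure/outcome summary-stat pair.

    Returns ``(exposure, outcome, truth)`` where truth records theta, the
    per-SNP pleiotropy alpha_j and validity flags.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps
    snp = np.array([f"rs{j + 1:05d}" for j in range(n)])
    chrom = np.ones(n, dtype=int)
    pos = np.sort(rng.integers(1, 250_000_000, size=n))
    while len(np.unique(pos)) < n:  # collisions are astronomically rare
        pos = np.sort(rng.integers(1, 250_000_000, size=n))
    maf = rng.uniform(*cfg.maf_range, size=n)
    ea, oa = _assign_alleles(n, cfg.palindromic_fraction, rng)

    gamma = _draw_gamma(cfg.gamma_dist, n, rng)
    se_x = se_from_maf_n(maf, cfg.n_exposure)
    beta_x = gamma + rng.normal(0.0, se_x)

    invalid = np.zeros(n, dtype=bool)
    n_inv = int(round(cfg.frac_invalid * n))
    if n_inv:
        invalid[rng.choice(n, size=n_inv, replace=False)] = True
    alpha = np.where(
        invalid, rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=n), 0.0
    )

    if cfg.outcome_type == "case-control":
        # log-odds scale; binomial phenotype variance shrinks effective n
        n_eff = cfg.n_outcome * cfg.case_fraction * (1 - cfg.case_fraction) * 4
        se_y = se_from_maf_n(maf, n_eff)
    else:
        se_y = se_from_maf_n(maf, cfg.n_outcome)
    big_gamma = cfg.theta * gamma + alpha
    beta_y = big_gamma + rng.normal(0.0, se_y)

    def table(beta, se, nn):
        return pd.DataFrame({
            "SNP": snp, "CHR": chrom, "POS": pos, "EA": ea, "OA": oa,
            "EAF": maf, "BETA": beta, "SE": se, "P": _pvalues(beta, se),
            "N": nn,
        })[SUMSTATS_COLUMNS]

    exposure = table(beta_x, se_x, cfg.n_exposure)
    outcome = table(beta_y, se_y, cfg.n_outcome)

    n_swap = int(round(cfg.outcome_swap_fraction * n))
    if n_swap:
        idx = rng.choice(n, size=n_swap, replace=False)
        outcome.loc[idx, ["EA", "OA"]] = outcome.loc[idx, ["OA", "EA"]].to_numpy()
        outcome.loc[idx, "BETA"] *= -1.0
        outcome.loc[idx, "EAF"] = 1.0 - outcome.loc[idx, "EAF"]

    validate_sumstats(exposure, "exposure")
    validate_sumstats(outcome, "outcome")
    truth = TruthRecord("two_sample_gwas", {
        "theta": cfg.theta,
        "gamma": gamma,
        "alpha": alpha,
        "invalid": invalid,
        "snp": snp,
    })
    return exposure, outcome, truth


# ---------------------------------------------------------------------------
# colocalization regions
# ---------------------------------------------------------------------------

@dataclass
class RegionSimConfig:
    """A pair of aligned association signals under one of H0..H4.

    z-scores are drawn from MVN(mean, Sigma) with AR(1) LD
    ``Sigma_ij = ld_rho^|i-j|``; the mean is the LD-propagated causal signal
    ``z_scale * Sigma[:, causal]`` for whichever traits the hypothesis makes
    causal. Betas and SEs are back-computed from z, MAF and study size.
    """

    n_snps: int = 300
    span_bp: int = 200_000
    hypothesis: str = "H0"
    causal_index_1: int = 0
    causal_index_2: int = 0
    z_scale: float = 8.0
    ld_rho: float = 0.5
    n1: int = 10_000
    n2: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hypothesis not in ("H0", "H1", "H2", "H3", "H4"):
            raise ConfigError("hypothesis must be one of H0..H4")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigError("ld_rho must lie in [0,1)")
        for idx in (self.causal_index_1, self.causal_index_2):
            if not (0 <= idx < self.n_snps):
                raise ConfigError("causal indices must be < n_snps")
        if self.hypothesis == "H4" and self.causal_index_1 != self.causal_index_2:
            raise ConfigError("under H4 the two causal indices must be equal")
        if self.hypothesis == "H3" and self.causal_index_1 == self.causal_index_2:
            raise ConfigError("under H3 the two causal indices must differ")


def gen_region_pair(cfg: RegionSimConfig):
    """Simulate two aligned summary-stat tables over one genomic region."""
    from .coloc import RegionPair  # local import to avoid a cycle

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps
    lag = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    sigma = cfg.ld_rho ** lag
    chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(n))

    mean1 = np.zeros(n)
    mean2 = np.zeros(n)
    if cfg.hypothesis in ("H1", "H3", "H4"):
        mean1 = cfg.z_scale * sigma[:, cfg.causal_index_1]
    if cfg.hypothesis in ("H2", "H3", "H4"):
        mean2 = cfg.z_scale * sigma[:, cfg.causal_index_2]

    z1 = mean1 + chol @ rng.standard_normal(n)
    z2 = mean2 + chol @ rng.standard_normal(n)

    start = 1_000_000
    pos = start + np.sort(
        rng.choice(np.arange(cfg.span_bp), size=n, replace=False)
    )
    maf = rng.uniform(0.05, 0.5, size=n)
    snp = np.array([f"rs{j + 1:05d}" for j in range(n)])
    ea, oa = _assign_alleles(n, 0.0, rng)

    def table(z, nn):
        se = se_from_maf_n(maf, nn)
        beta = z * se
        return pd.DataFrame({
            "SNP": snp, "CHR": 1, "POS": pos, "EA": ea, "OA": oa,
            "EAF": maf, "BETA": beta, "SE": se, "P": _pvalues(beta, se),
            "N": nn,
        })[SUMSTATS_COLUMNS]

    trait1 = table(z1, cfg.n1)
    trait2 = table(z2, cfg.n2)
    anchor = snp[cfg.causal_index_1]
    truth = TruthRecord("region_pair", {
        "hypothesis": cfg.hypothesis,
        "causal_index_1": cfg.causal_index_1,
        "causal_index_2": cfg.causal_index_2,
        "causal_snp_1": snp[cfg.causal_index_1],
        "causal_snp_2": snp[cfg.causal_index_2],
    })
    return RegionPair(trait1, trait2, anchor_snp=anchor, n1=cfg.n1, n2=cfg.n2), truth


# ---------------------------------------------------------------------------
# trait panels and drug tables
# ---------------------------------------------------------------------------

def gen_trait_panel(n_traits: int, n_snps: int, effects=None, seed: int = 0,
                    se: float = 0.02, n: int = 50_000) -> tuple:
    """Simulate a traits x SNPs association panel for a PheWAS screen.

    ``effects`` is a list of ``(trait_index, snp_index, effect_in_se_units)``
    triples designating true associations; everything else is null.
    Returns ``(panel, truth)`` where the panel is a long-form DataFrame with
    columns trait/SNP/BETA/SE/P/N.
    """
    if n_traits < 1:
        raise ConfigError("n_traits must be >= 1")
    rng = np.random.default_rng(seed)
    effects = list(effects or [])
    traits = [f"trait_{t + 1:04d}" for t in range(n_traits)]
    snps = [f"rs{j + 1:05d}" for j in range(n_snps)]
    beta = rng.normal(0.0, se, size=(n_traits, n_snps))
    for t, j, units in effects:
        beta[t, j] = units * se
    se_arr = np.full_like(beta, se)
    p = np.clip(2.0 * stats.norm.sf(np.abs(beta / se_arr)), _P_FLOOR, 1.0)
    panel = pd.DataFrame({
        "trait": np.repeat(traits, n_snps),
        "SNP": np.tile(snps, n_traits),
        "BETA": beta.ravel(),
        "SE": se_arr.ravel(),
        "P": p.ravel(),
        "N": n,
    })
    truth = TruthRecord("trait_panel", {
        "effects": [(traits[t], snps[j], units) for t, j, units in effects],
    })
    return panel, truth


def gen_drug_table(genes, drugs_per_gene: int = 3, multi_target_fraction: float = 0.0,
                   seed: int = 0) -> tuple:
    """Simulate a bipartite drug-target table (unique (drug, gene) pairs).

    Every gene receives ``drugs_per_gene`` dedicated drugs; a
    ``multi_target_fraction`` of all drugs is then given 1-2 extra random
    gene targets. Truth records the multi-target drug set.
    """
    genes = list(genes)
    if not genes:
        raise ConfigError("genes must be nonempty")
    rng = np.random.default_rng(seed)
    rows = []
    drug_ids = []
    for gi, gene in enumerate(genes):
        for k in range(drugs_per_gene):
            drug = f"D{gi * drugs_per_gene + k + 1:05d}"
            drug_ids.append(drug)
            rows.append((drug, f"drug-{drug}", gene, "synthetic", "+"))
    n_multi = int(round(multi_target_fraction * len(drug_ids)))
    multi = sorted(rng.choice(drug_ids, size=n_multi, replace=False)) if n_multi else []
    targets = {d: {r[2] for r in rows if r[0] == d} for d in multi}
    for drug in multi:
        extras = [g for g in genes if g not in targets[drug]]
        if not extras:
            continue
        k = min(int(rng.integers(1, 3)), len(extras))
        for gene in rng.choice(extras, size=k, replace=False):
            rows.append((drug, f"drug-{drug}", gene, "synthetic", "+"))
    table = pd.DataFrame(
        rows, columns=["drug_id", "drug_name", "gene", "source", "sign"]
    ).drop_duplicates(["drug_id", "gene"]).reset_index(drop=True)
    truth = TruthRecord("drug_table", {"multi_target_drugs": list(multi)})
    return table, truth
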