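"""Deterministic preprocessing of expression matrices and distribution contrasts.

The fixed pipeline order is: median imputation -> percentile capping ->
label-protected batch adjustment -> variance filter; standardization is fit
inside cross-validation training folds only (see :mod:`mitocausal.pathway_ml`).
Sample count is never changed by preprocessing; gene count changes only
through the variance filter and pathway filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, ValidationError

__all__ = [
    "impute_median",
    "cap_outliers",
    "standardize",
    "variance_filter",
    "batch_adjust",
    "filter_pathways",
    "contrast_distributions",
    "preprocess",
    "ContrastReport",
]

#: Significance stars thresholds (descending stringency).
STAR_LEVELS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]


def _stars(p: float) -> str:
    for cut, mark in STAR_LEVELS:
        if p < cut:
            return mark
    return ""


def impute_median(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace missing entries by the gene's median over observed values."""
    all_missing = m.values.isna().all(axis=0)
    if all_missing.any():
        gene = m.values.columns[all_missing][0]
        raise ValidationError(f"gene {gene!r} has no observed values to impute from")
    return m.with_values(m.values.fillna(m.values.median(axis=0)))


def cap_outliers(m: ExpressionMatrix, lower: float = 1.0, upper: float = 99.0) -> ExpressionMatrix:
    """Winsorize each gene at its 1st/99th percentile.

    Percentiles use linear interpolation between order statistics (numpy's
    default), the convention documented for reproducibility. Requires a
    complete matrix (run after imputation).
    """
    if m.values.isna().any().any():
        raise ValidationError("cap_outliers requires a complete matrix; impute first")
    lo = m.values.quantile(lower / 100.0, axis=0, interpolation="linear")
    hi = m.values.quantile(upper / 100.0, axis=0, interpolation="linear")
    return m.with_values(m.values.clip(lower=lo, upper=hi, axis=1))


def standardize(train: ExpressionMatrix, apply_to: ExpressionMatrix | None = None) -> ExpressionMatrix:
    """Center/scale genes by training-set mean and SD (population SD, ddof=0).

    Fitting statistics come only from ``train`` so validation folds never
    leak into the scaler. ``apply_to`` defaults to ``train``.
    """
    if apply_to is None:
        apply_to = train
    missing = [g for g in apply_to.gene_ids if g not in train.gene_ids]
    if missing:
        raise ValidationError(f"genes absent from training data: {missing[:5]}")
    mean = train.values.mean(axis=0)
    sd = train.values.std(axis=0, ddof=0)
    zero = sd[sd == 0]
    if len(zero):
        raise ValidationError(
            f"zero-SD gene(s) {list(zero.index[:5])}; run variance_filter first"
        )
    out = (apply_to.values - mean[apply_to.gene_ids]) / sd[apply_to.gene_ids]
    return apply_to.with_values(out)


def variance_filter(m: ExpressionMatrix, threshold: float = 0.01):
    """Drop genes with variance <= threshold; returns (matrix, removed genes).

    Population variance (ddof=0), matching the usual low-variance feature
    filter; at threshold 0 only exactly-constant genes are removed.
    """
    var = m.values.var(axis=0, ddof=0)
    removed = list(var.index[var <= threshold])
    kept = [g for g in m.gene_ids if g not in set(removed)]
    if not kept:
        raise ValidationError("variance filter removed every gene")
    return m.with_values(m.values.loc[:, kept].copy()), removed


def batch_adjust(m: ExpressionMatrix) -> ExpressionMatrix:
    """Location/scale batch adjustment with the disease label protected.

    Per gene the label effect is estimated by OLS and removed; batch means
    and SDs are then computed on label-adjusted residuals, each batch is
    recentred/rescaled to the pooled residual scale, and the label effect is
    added back. Single-batch input passes through unchanged. This is a
    deliberately simple location/scale method, not empirical-Bayes ComBat:
    there is no shrinkage across genes.
    """
    batches = m.batch.unique()
    if len(batches) == 1:
        return m.with_values(m.values.copy())
    counts = m.batch.value_counts()
    if (counts < 2).any():
        raise ValidationError("batch adjustment needs >= 2 samples per batch")
    tab = pd.crosstab(m.batch, m.labels)
    if ((tab > 0).sum(axis=1) == 1).all():
        raise ValidationError("batches confounded 1:1 with label; inestimable")

    y = m.labels.to_numpy().astype(float)
    X = m.values.to_numpy(dtype=float)
    # per-gene OLS on the label: slope = cov(x, y)/var(y)
    yc = y - y.mean()
    slope = (yc @ X) / (yc @ yc)
    fitted = X.mean(axis=0) + np.outer(yc, slope)
    resid = X - fitted

    codes = m.batch.to_numpy()
    centered = np.empty_like(resid)
    for b in batches:
        sel = codes == b
        centered[sel] = resid[sel] - resid[sel].mean(axis=0)
    # pooled within-batch scale: between-batch offsets must not inflate it
    pooled_sd = centered.std(axis=0, ddof=1)
    pooled_sd[pooled_sd == 0] = 1.0
    adj = np.empty_like(resid)
    for b in batches:
        sel = codes == b
        sd = centered[sel].std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        adj[sel] = centered[sel] / sd * pooled_sd
    out = pd.DataFrame(adj + fitted, index=m.sample_ids, columns=m.gene_ids)
    return m.with_values(out)


def filter_pathways(pmap: dict, m: ExpressionMatrix, min_genes: int = 5) -> dict:
    """Intersect pathways with measured genes; drop those below ``min_genes``."""
    measured = set(m.gene_ids)
    out = {}
    for name, genes in pmap.items():
        hit = set(genes) & measured
        if len(hit) >= min_genes:
            out[name] = hit
    if not out:
        raise ValidationError("no pathway retains the minimum number of genes")
    return out


@dataclass
class ContrastReport:
    """Pooled and per-gene case-vs-control distribution contrasts."""

    pooled: pd.Series       # t, t_p, levene, levene_p, mean_diff, stars, group sizes
    per_gene: pd.DataFrame  # one row per gene, same statistics


def contrast_distributions(m: ExpressionMatrix, genes=None) -> ContrastReport:
    """Welch t-test (central tendency) and Brown-Forsythe Levene (variance).

    The pooled contrast flattens all selected genes' values per group, the
    way a violin-plot comparison of the whole gene set is read; per-gene
    rows carry the same statistics gene by gene. Levene uses the
    median-centered variant for robustness.
    """
    sub = m if genes is None else m.subset_genes(genes)
    case_mask = sub.labels.to_numpy() == 1
    if case_mask.sum() < 2 or (~case_mask).sum() < 2:
        raise ValidationError("each class needs >= 2 samples for contrasts")
    case = sub.values.to_numpy()[case_mask]
    ctrl = sub.values.to_numpy()[~case_mask]

    def contrast(a: np.ndarray, b: np.ndarray) -> dict:
        if np.array_equal(np.sort(a), np.sort(b)):
            t, tp = 0.0, 1.0
        else:
            t, tp = stats.ttest_ind(a, b, equal_var=False)
        lv, lvp = stats.levene(a, b, center="median")
        return {
            "mean_diff": float(a.mean() - b.mean()),
            "t": float(t), "t_p": float(tp), "t_stars": _stars(float(tp)),
            "levene": float(lv), "levene_p": float(lvp),
            "levene_stars": _stars(float(lvp)),
            "n_case": len(a), "n_control": len(b),
        }

    pooled = pd.Series(contrast(case.ravel(), ctrl.ravel()))
    rows = {g: contrast(case[:, j], ctrl[:, j])
            for j, g in enumerate(sub.gene_ids)}
    return ContrastReport(pooled, pd.DataFrame(rows).T)


def preprocess(m: ExpressionMatrix, variance_threshold: float = 0.01):
    """Run the fixed pipeline: impute -> cap -> batch-adjust -> variance filter.

    Returns ``(matrix, removed_genes)``. Standardization is intentionally not
    part of this function: it belongs inside CV folds.
    """
    m = impute_median(m)
    m = cap_outliers(m)
    m = batch_adjust(m)
    return variance_filter(m, variance_threshold)
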