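"""Two-sample Mendelian randomization from summary statistics.

Implements the full battery: instrument selection (p-value filter, greedy LD
clumping, F-statistic filter), allele harmonization with palindromic-SNP
handling, the estimators (Wald ratio, IVW with multiplicative random
effects, MR-Egger, weighted median, simple/weighted mode) and the
sensitivity suite (Cochran's Q, Egger intercept, a PRESSO-style outlier
test with parametric null simulation).

All estimates are on the scale of the outcome per unit (SD) of exposure;
odds ratios are ``exp(beta)`` with Wald 95% CIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import COMPLEMENT, ValidationError, is_palindromic, validate_sumstats

__all__ = [
    "MRConfig",
    "InstrumentSet",
    "HarmonizedPair",
    "MRResult",
    "f_statistic",
    "clump",
    "select_instruments",
    "harmonize",
    "wald_ratios",
    "ivw",
    "egger",
    "weighted_median",
    "mode_estimators",
    "cochran_q",
    "presso",
    "run_mr",
    "adjust_exposures",
]

PALINDROMIC_EAF_ZONE = 0.08  # |eaf - 0.5| <= zone => strand not inferable


@dataclass
class MRConfig:
    """Thresholds of the instrument pipeline (defaults as commonly reported
    for eQTL-exposure MR: p < 1e-8, r^2 < 0.001 in a 10,000 kb window,
    F >= 10)."""

    p_threshold: float = 1e-8
    r2_max: float = 0.001
    window_kb: float = 10_000.0
    f_min: float = 10.0
    palindromic_policy: str = "infer"  # or "drop_all"
    n_boot: int = 1000
    presso_sims: int = 1000
    run_presso: bool = True
    seed: int = 0


@dataclass
class InstrumentSet:
    """Surviving exposure SNPs plus per-SNP F and the filter decision log."""

    df: pd.DataFrame  # summary stats + column F
    log: pd.DataFrame  # SNP, stage, decision


@dataclass
class HarmonizedPair:
    """Aligned exposure/outcome effects on a common effect allele."""

    df: pd.DataFrame  # SNP, EA, OA, EAF_exp, EAF_out, beta_exp, se_exp, beta_out, se_out
    drop_log: pd.DataFrame  # SNP, reason

    @property
    def n_snps(self) -> int:
        return len(self.df)


@dataclass
class MRResult:
    """Per-method estimates and the sensitivity battery for one pair."""

    estimates: pd.DataFrame  # method, beta, se, p, n_snps, OR, OR_lo, OR_hi
    q: float = np.nan
    q_df: int = 0
    q_p: float = np.nan
    presso_global_p: float = np.nan
    presso_outliers: list = field(default_factory=list)
    presso_corrected: dict = field(default_factory=dict)
    harmonized: HarmonizedPair | None = None
    instruments: InstrumentSet | None = None

    def estimate(self, method: str) -> pd.Series:
        hit = self.estimates[self.estimates["method"] == method]
        if hit.empty:
            raise KeyError(method)
        return hit.iloc[0]


def _or_ci(beta: float, se: float) -> tuple:
    return (float(np.exp(beta)),
            float(np.exp(beta - 1.96 * se)),
            float(np.exp(beta + 1.96 * se)))


def _entry(method, beta, se, p, n_snps) -> dict:
    orr, lo, hi = _or_ci(beta, se)
    return {"method": method, "beta": float(beta), "se": float(se),
            "p": float(p), "n_snps": int(n_snps),
            "OR": orr, "OR_lo": lo, "OR_hi": hi}


# ---------------------------------------------------------------------------
# instrument selection
# ---------------------------------------------------------------------------

def f_statistic(beta, se):
    """Single-instrument approximation ``F = (beta/se)^2``."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if (se <= 0).any():
        raise ValidationError("se must be > 0")
    return (beta / se) ** 2


def _ld_lookup(ld, s1: str, s2: str):
    """r^2 between two SNPs from a square DataFrame or pair dict; None if absent."""
    if ld is None:
        return None
    if isinstance(ld, pd.DataFrame):
        if s1 in ld.index and s2 in ld.columns:
            return float(ld.loc[s1, s2])
        return None
    return ld.get((s1, s2), ld.get((s2, s1)))


def clump(df: pd.DataFrame, ld=None, r2_max: float = 0.001,
          window_kb: float = 10_000.0, log: list | None = None) -> pd.DataFrame:
    """Greedy LD clumping: sweep SNPs by ascending p, keep a SNP iff no
    already-kept SNP on the same chromosome within ``window_kb`` has
    r^2 >= ``r2_max`` with it. Absent LD entries are treated as independent
    (r^2 = 0) and logged."""
    order = df.sort_values(["P", "SNP"], kind="mergesort")
    kept_rows = []
    for _, row in order.iterrows():
        clumped = False
        for kept in kept_rows:
            if kept["CHR"] != row["CHR"]:
                continue
            if abs(kept["POS"] - row["POS"]) > window_kb * 1000:
                continue
            r2 = _ld_lookup(ld, kept["SNP"], row["SNP"])
            if r2 is None:
                if log is not None:
                    log.append((row["SNP"], "clump",
                                f"no LD entry vs {kept['SNP']}; assumed independent"))
                r2 = 0.0
            if r2 >= r2_max:
                if log is not None:
                    log.append((row["SNP"], "clump",
                                f"removed: r2={r2:.3g} with {kept['SNP']}"))
                clumped = True
                break
        if not clumped:
            kept_rows.append(row)
    kept = pd.DataFrame(kept_rows)
    return df.loc[df["SNP"].isin(kept["SNP"])].copy() if len(kept) else df.iloc[:0].copy()


def select_instruments(exposure: pd.DataFrame, ld=None, p_threshold: float = 1e-8,
                       r2_max: float = 0.001, window_kb: float = 10_000.0,
                       f_min: float = 10.0) -> InstrumentSet:
    """p-value filter, then greedy clumping, then weak-instrument (F) filter."""
    validate_sumstats(exposure, "exposure")
    log: list = []
    passed = exposure[exposure["P"] < p_threshold].copy()
    for snp in exposure.loc[~exposure["SNP"].isin(passed["SNP"]), "SNP"]:
        log.append((snp, "p_filter", f"removed: p >= {p_threshold:g}"))
    passed = clump(passed, ld, r2_max, window_kb, log)
    passed["F"] = f_statistic(passed["BETA"], passed["SE"])
    weak = passed["F"] < f_min
    for snp in passed.loc[weak, "SNP"]:
        log.append((snp, "f_filter", f"removed: F < {f_min:g}"))
    passed = passed[~weak].copy()
    if passed.empty:
        raise ValidationError("no valid instruments")
    for snp in passed["SNP"]:
        log.append((snp, "final", "kept"))
    return InstrumentSet(passed.reset_index(drop=True),
                         pd.DataFrame(log, columns=["SNP", "stage", "decision"]))


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              palindromic_policy: str = "infer") -> HarmonizedPair:
    """Align outcome effects onto the exposure's effect allele.

    Swapped alleles flip the outcome beta sign and EAF; strand-complement
    alleles are complemented first. Palindromic (A/T, C/G) SNPs are dropped
    under ``drop_all``; under ``infer`` they are kept only when both EAFs
    are outside the ambiguity zone ``|eaf-0.5| <= 0.08``, with the outcome
    orientation corrected so allele frequencies agree across studies.
    Incompatible allele sets are dropped with a reason; drops are logged,
    never fatal.
    """
    if palindromic_policy not in ("infer", "drop_all"):
        raise ValidationError(f"unknown palindromic policy: {palindromic_policy!r}")
    merged = exposure.merge(outcome, on="SNP", suffixes=("_exp", "_out"))
    rows, drops = [], []
    for _, r in merged.iterrows():
        ex_ea, ex_oa = r["EA_exp"], r["OA_exp"]
        out_ea, out_oa = r["EA_out"], r["OA_out"]
        beta, eaf = r["BETA_out"], r["EAF_out"]
        if is_palindromic(ex_ea, ex_oa):
            if {out_ea, out_oa} != {ex_ea, ex_oa}:
                drops.append((r["SNP"], "allele mismatch"))
                continue
            if palindromic_policy == "drop_all":
                drops.append((r["SNP"], "palindromic (drop_all)"))
                continue
            if (abs(r["EAF_exp"] - 0.5) <= PALINDROMIC_EAF_ZONE
                    or abs(eaf - 0.5) <= PALINDROMIC_EAF_ZONE):
                drops.append((r["SNP"], "palindromic ambiguous"))
                continue
            if out_ea != ex_ea:  # nominal order alignment
                beta, eaf = -beta, 1.0 - eaf
            if (r["EAF_exp"] - 0.5) * (eaf - 0.5) < 0:  # frequency correction
                beta, eaf = -beta, 1.0 - eaf
        else:
            pair = (out_ea, out_oa)
            comp_pair = (COMPLEMENT[out_ea], COMPLEMENT[out_oa])
            if pair == (ex_ea, ex_oa) or comp_pair == (ex_ea, ex_oa):
                pass
            elif pair == (ex_oa, ex_ea) or comp_pair == (ex_oa, ex_ea):
                beta, eaf = -beta, 1.0 - eaf
            else:
                drops.append((r["SNP"], "allele mismatch"))
                continue
        rows.append({
            "SNP": r["SNP"], "EA": ex_ea, "OA": ex_oa,
            "EAF_exp": r["EAF_exp"], "EAF_out": eaf,
            "beta_exp": r["BETA_exp"], "se_exp": r["SE_exp"],
            "beta_out": beta, "se_out": r["SE_out"],
        })
    cols = ["SNP", "EA", "OA", "EAF_exp", "EAF_out",
            "beta_exp", "se_exp", "beta_out", "se_out"]
    return HarmonizedPair(pd.DataFrame(rows, columns=cols),
                          pd.DataFrame(drops, columns=["SNP", "reason"]))


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def wald_ratios(h: HarmonizedPair) -> pd.DataFrame:
    """Per-SNP ratio estimates with first-order delta-method SEs.

    SNPs with zero exposure beta are excluded (nothing to instrument) and
    reported in the ``excluded`` attribute of the returned frame.
    """
    df = h.df
    nonzero = df["beta_exp"] != 0
    sub = df[nonzero]
    out = pd.DataFrame({
        "SNP": sub["SNP"].to_numpy(),
        "ratio": (sub["beta_out"] / sub["beta_exp"]).to_numpy(),
        "se": (sub["se_out"] / sub["beta_exp"].abs()).to_numpy(),
    })
    out.attrs["excluded"] = list(df.loc[~nonzero, "SNP"])
    return out


def _ivw_closed_form(bx, by, se_y):
    w = 1.0 / se_y ** 2
    denom = float(np.sum(w * bx ** 2))
    theta = float(np.sum(w * bx * by)) / denom
    se_fixed = float(np.sqrt(1.0 / denom))
    return theta, se_fixed


def ivw(h: HarmonizedPair, random_effects: bool = True) -> dict:
    """Inverse-variance-weighted estimate: weighted regression of outcome on
    exposure betas through the origin, weights ``1/se_out^2``.

    The SE uses multiplicative random-effects inflation ``sqrt(max(1, Q/df))``
    so it is never narrower than the fixed-effect SE. A single SNP degrades
    to its Wald ratio, labeled as such.
    """
    df = h.df
    if len(df) < 1:
        raise ValidationError("IVW needs at least one SNP")
    if len(df) == 1:
        r = wald_ratios(h)
        if r.empty:
            raise ValidationError("single SNP has zero exposure beta")
        beta, se = float(r["ratio"][0]), float(r["se"][0])
        p = 2 * stats.norm.sf(abs(beta / se))
        return _entry("Wald ratio", beta, se, p, 1)
    bx = df["beta_exp"].to_numpy(float)
    by = df["beta_out"].to_numpy(float)
    se_y = df["se_out"].to_numpy(float)
    theta, se = _ivw_closed_form(bx, by, se_y)
    if random_effects:
        q, q_df, _ = cochran_q(h, theta)
        se *= np.sqrt(max(1.0, q / q_df))
    p = 2 * stats.norm.sf(abs(theta / se))
    return _entry("IVW", theta, se, p, len(df))


def egger(h: HarmonizedPair) -> tuple:
    """MR-Egger weighted regression with intercept; returns (slope, intercept).

    Exposure betas are oriented positive first (flipping the paired outcome
    betas), the conventional orientation that makes the intercept a
    directional-pleiotropy estimate. SEs use multiplicative inflation
    ``sqrt(max(1, sigma^2))`` over the unit-weight model; p-values from a
    t distribution with n-2 df.
    """
    df = h.df
    if len(df) < 3:
        raise ValidationError("MR-Egger needs at least 3 SNPs")
    sign = np.sign(df["beta_exp"].to_numpy(float))
    sign[sign == 0] = 1.0
    bx = df["beta_exp"].to_numpy(float) * sign
    by = df["beta_out"].to_numpy(float) * sign
    w = 1.0 / df["se_out"].to_numpy(float) ** 2
    X = np.column_stack([np.ones_like(bx), bx])
    # weighted least squares normal equations
    WX = X * w[:, None]
    xtx_inv = np.linalg.inv(X.T @ WX)
    coef = xtx_inv @ (WX.T @ by)
    resid = by - X @ coef
    dof = len(bx) - 2
    sigma2 = float(np.sum(w * resid ** 2) / dof)
    se_unit = np.sqrt(np.diag(xtx_inv))
    se = se_unit * np.sqrt(max(1.0, sigma2))
    p = 2 * stats.t.sf(np.abs(coef / se), dof)
    slope = _entry("Egger", coef[1], se[1], p[1], len(bx))
    intercept = _entry("Egger intercept", coef[0], se[0], p[0], len(bx))
    return slope, intercept


def _weighted_median_1d(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if cum[0] >= 0.5:
        return float(r[0])
    below = int(np.max(np.nonzero(cum < 0.5)[0]))
    if below == len(r) - 1:
        return float(r[-1])
    frac = (0.5 - cum[below]) / (cum[below + 1] - cum[below])
    return float(r[below] + (r[below + 1] - r[below]) * frac)


def weighted_median(h: HarmonizedPair, n_boot: int = 1000, seed: int = 0) -> dict:
    """Weighted median of Wald ratios, inverse-variance weighted.

    The estimate interpolates the cumulative-weight function at 50%; the SE
    comes from a seeded parametric bootstrap (betas resampled from their
    reported SEs, ``n_boot`` draws).
    """
    df = h.df
    if len(df) < 3:
        raise ValidationError("weighted median needs at least 3 SNPs")
    r = wald_ratios(h)
    weights = 1.0 / r["se"].to_numpy(float) ** 2
    est = _weighted_median_1d(r["ratio"].to_numpy(float), weights)
    se = _bootstrap_se(h, lambda rat, wt: _weighted_median_1d(rat, wt),
                       n_boot, seed, weighted=True)
    p = 2 * stats.norm.sf(abs(est / se)) if se > 0 else (1.0 if est == 0 else 0.0)
    return _entry("Weighted median", est, se, p, len(r))


def _mode_1d(ratios: np.ndarray, weights: np.ndarray,
             bandwidth_factor: float = 1.0) -> float:
    """Mode of the Gaussian-kernel-smoothed (weighted) ratio density.

    Bandwidth follows the modified Silverman rule
    ``h = factor * 0.9 * min(sd, normalized MAD) * n^(-1/5)``.
    """
    n = len(ratios)
    sd = np.std(ratios, ddof=1) if n > 1 else 0.0
    mad = stats.median_abs_deviation(ratios, scale="normal")
    s = 0.9 * min(sd if sd > 0 else np.inf, mad if mad > 0 else np.inf) * n ** (-1 / 5)
    if not np.isfinite(s) or s <= 0:
        return float(ratios[0])  # all ratios identical
    bw = bandwidth_factor * s
    grid = np.linspace(ratios.min() - 3 * bw, ratios.max() + 3 * bw, 512)
    dens = (weights[None, :] * stats.norm.pdf(
        (grid[:, None] - ratios[None, :]) / bw)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def _bootstrap_se(h: HarmonizedPair, estimator, n_boot: int, seed: int,
                  weighted: bool) -> float:
    rng = np.random.default_rng(seed)
    df = h.df
    bx = df["beta_exp"].to_numpy(float)
    by = df["beta_out"].to_numpy(float)
    sx = df["se_exp"].to_numpy(float)
    sy = df["se_out"].to_numpy(float)
    ests = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        nz = bxs != 0
        rat = bys[nz] / bxs[nz]
        se_rat = sy[nz] / np.abs(bxs[nz])
        wt = 1.0 / se_rat ** 2 if weighted else np.ones(nz.sum())
        ests[b] = estimator(rat, wt)
    return float(np.std(ests, ddof=1))


def mode_estimators(h: HarmonizedPair, bandwidth_factor: float = 1.0,
                    n_boot: int = 1000, seed: int = 0) -> tuple:
    """Simple-mode and weighted-mode entries (kernel-density mode of ratios)."""
    df = h.df
    if len(df) < 3:
        raise ValidationError("mode estimators need at least 3 SNPs")
    r = wald_ratios(h)
    ratios = r["ratio"].to_numpy(float)
    iv_w = 1.0 / r["se"].to_numpy(float) ** 2
    eq_w = np.ones_like(ratios)
    out = []
    for name, weights, use_w in (("Simple mode", eq_w, False),
                                 ("Weighted mode", iv_w, True)):
        est = _mode_1d(ratios, weights, bandwidth_factor)
        se = _bootstrap_se(
            h, lambda rat, wt: _mode_1d(rat, wt, bandwidth_factor),
            n_boot, seed, weighted=use_w)
        p = 2 * stats.norm.sf(abs(est / se)) if se > 0 else (1.0 if est == 0 else 0.0)
        out.append(_entry(name, est, se, p, len(ratios)))
    return tuple(out)


def cochran_q(h: HarmonizedPair, theta: float) -> tuple:
    """Heterogeneity of Wald ratios around ``theta``: (Q, df, p)."""
    r = wald_ratios(h)
    if len(r) < 2:
        raise ValidationError("Cochran's Q needs at least 2 SNPs")
    w = 1.0 / r["se"].to_numpy(float) ** 2
    q = float(np.sum(w * (r["ratio"].to_numpy(float) - theta) ** 2))
    q_df = len(r) - 1
    return q, q_df, float(stats.chi2.sf(q, q_df))


# ---------------------------------------------------------------------------
# PRESSO-style outlier test
# ---------------------------------------------------------------------------

def presso(h: HarmonizedPair, n_sim: int = 1000, seed: int = 0,
           alpha: float = 0.05) -> dict:
    """Global pleiotropy test and per-SNP outlier flags by parametric simulation.

    The observed statistic is the weighted residual sum of squares of each
    SNP's outcome beta around its leave-one-out IVW prediction. Outcome
    betas are then resampled from their SEs around the fitted model to build
    the null; the global p is the exceedance fraction, per-SNP outlier
    p-values use the same comparison per SNP with Bonferroni correction.
    A corrected IVW excluding flagged SNPs is refit when outliers exist.
    """
    df = h.df
    n = len(df)
    if n < 4:
        raise ValidationError("PRESSO needs at least 4 SNPs")
    rng = np.random.default_rng(seed)
    bx = df["beta_exp"].to_numpy(float)
    by = df["beta_out"].to_numpy(float)
    sy = df["se_out"].to_numpy(float)
    w = 1.0 / sy ** 2

    A = np.sum(w * bx * by)
    B = np.sum(w * bx ** 2)
    theta_loo = (A - w * bx * by) / (B - w * bx ** 2)
    resid_obs = w * (by - theta_loo * bx) ** 2
    rss_obs = float(resid_obs.sum())

    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, n))
    A_sim = by_sim @ (w * bx)
    theta_loo_sim = (A_sim[:, None] - by_sim * (w * bx)[None, :]) / \
        (B - (w * bx ** 2))[None, :]
    resid_sim = w[None, :] * (by_sim - theta_loo_sim * bx[None, :]) ** 2
    rss_sim = resid_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    p_snp = (1 + (resid_sim >= resid_obs[None, :]).sum(axis=0)) / (n_sim + 1)
    outliers = list(df["SNP"].to_numpy()[p_snp * n < alpha])

    corrected = {}
    if outliers:
        keep = ~df["SNP"].isin(outliers)
        if keep.sum() >= 2:
            sub = HarmonizedPair(df[keep].reset_index(drop=True), h.drop_log)
            corrected = ivw(sub)
    return {"global_p": global_p, "outliers": outliers,
            "per_snp_p": pd.Series(p_snp, index=df["SNP"]),
            "corrected_ivw": corrected}


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_mr(exposure: pd.DataFrame, outcome: pd.DataFrame, ld=None,
           config: MRConfig | None = None) -> MRResult:
    """Full pipeline: select instruments, harmonize, all estimators + sensitivity."""
    cfg = config or MRConfig()
    inst = select_instruments(exposure, ld, cfg.p_threshold, cfg.r2_max,
                              cfg.window_kb, cfg.f_min)
    h = harmonize(inst.df, outcome, cfg.palindromic_policy)
    if h.n_snps == 0:
        raise ValidationError("no SNPs survive harmonization")
    entries = []
    wald = wald_ratios(h)
    main = ivw(h)
    entries.append(main)
    q = q_df = q_p = np.nan
    if h.n_snps >= 2:
        q, q_df, q_p = cochran_q(h, main["beta"])
    if h.n_snps >= 3:
        slope, intercept = egger(h)
        entries += [slope, intercept]
        entries.append(weighted_median(h, cfg.n_boot, cfg.seed))
        entries += list(mode_estimators(h, 1.0, cfg.n_boot, cfg.seed))
    presso_res = {"global_p": np.nan, "outliers": [], "corrected_ivw": {}}
    if cfg.run_presso and h.n_snps >= 4:
        presso_res = presso(h, cfg.presso_sims, cfg.seed)
    result = MRResult(
        estimates=pd.DataFrame(entries),
        q=q, q_df=int(q_df) if not np.isnan(q) else 0, q_p=q_p,
        presso_global_p=presso_res["global_p"],
        presso_outliers=presso_res["outliers"],
        presso_corrected=presso_res["corrected_ivw"],
        harmonized=h, instruments=inst,
    )
    result.estimates.attrs["wald_excluded"] = wald.attrs.get("excluded", [])
    return result


def adjust_exposures(pvalues: pd.Series, method: str = "fdr_bh",
                     alpha: float = 0.05) -> pd.DataFrame:
    """Multiple-testing adjustment across an exposure panel (BH default,
    Bonferroni optional)."""
    from statsmodels.stats.multitest import multipletests

    if method not in ("fdr_bh", "bonferroni"):
        raise ValidationError(f"unknown adjustment method: {method!r}")
    reject, adj, _, _ = multipletests(pvalues.to_numpy(float), alpha=alpha,
                                      method=method)
    return pd.DataFrame({"p": pvalues, "p_adj": adj, "significant": reject},
                        index=pvalues.index)
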