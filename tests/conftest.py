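import numpy as np
import pandas as pd
import pytest

from mitocausal.containers import ExpressionMatrix, SUMSTATS_COLUMNS
from mitocausal.mr import HarmonizedPair


def make_expression(values, labels, batch=None, genes=None):
    """Build an ExpressionMatrix from a plain array."""
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    samples = [f"S{i}" for i in range(n)]
    genes = genes or [f"G{j}" for j in range(g)]
    batch = batch if batch is not None else [0] * n
    return ExpressionMatrix(
        pd.DataFrame(values, index=samples, columns=genes),
        pd.Series(labels, index=samples, name="label"),
        pd.Series(batch, index=samples, name="batch"),
    )


def make_sumstats(betas, ses, pvals=None, eas=None, oas=None, eafs=None,
                  positions=None, n=100_000):
    """Build a minimal valid summary-statistics table."""
    k = len(betas)
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if pvals is None:
        from scipy import stats
        pvals = np.clip(2 * stats.norm.sf(np.abs(betas / ses)), 1e-300, 1.0)
    df = pd.DataFrame({
        "SNP": [f"rs{j + 1}" for j in range(k)],
        "CHR": 1,
        "POS": positions if positions is not None else np.arange(1, k + 1) * 1000,
        "EA": eas if eas is not None else ["A"] * k,
        "OA": oas if oas is not None else ["G"] * k,
        "EAF": eafs if eafs is not None else [0.3] * k,
        "BETA": betas, "SE": ses, "P": pvals, "N": n,
    })
    return df[SUMSTATS_COLUMNS]


def make_harmonized(beta_exp, se_exp, beta_out, se_out):
    """Build a HarmonizedPair directly from aligned effect arrays."""
    k = len(beta_exp)
    df = pd.DataFrame({
        "SNP": [f"rs{j + 1}" for j in range(k)],
        "EA": "A", "OA": "G", "EAF_exp": 0.3, "EAF_out": 0.3,
        "beta_exp": np.asarray(beta_exp, float),
        "se_exp": np.asarray(se_exp, float),
        "beta_out": np.asarray(beta_out, float),
        "se_out": np.asarray(se_out, float),
    })
    return HarmonizedPair(df, pd.DataFrame(columns=["SNP", "reason"]))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
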