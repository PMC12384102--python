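"""Shared in-memory containers for the pipeline.

Expression data travel as an :class:`ExpressionMatrix` (samples x genes with
binary disease labels and batch ids); GWAS/eQTL associations travel as plain
:class:`pandas.DataFrame` tables in the summary-statistics dialect validated by
:func:`validate_sumstats`; pathway membership is a mapping ``name -> set of
gene ids``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Required columns of a summary-statistics table, in canonical order.
SUMSTATS_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

VALID_ALLELES = frozenset("ACGT")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ValidationError(ValueError):
    """An input table violates the documented dialect."""


@dataclass
class ExpressionMatrix:
    """Log-scale expression values with per-sample labels and batch ids.

    Parameters
    ----------
    values
        samples x genes matrix; index = sample ids, columns = gene ids.
        May contain NaN before imputation.
    labels
        Binary disease status (0 = control, 1 = case), indexed like ``values``.
    batch
        Categorical batch id per sample, indexed like ``values``.
    """

    values: pd.DataFrame
    labels: pd.Series
    batch: pd.Series

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()]
            raise ValidationError(f"duplicate gene ids: {sorted(set(dupes))}")
        if not self.values.index.equals(self.labels.index):
            raise ValidationError("labels index does not match sample index")
        if not self.values.index.equals(self.batch.index):
            raise ValidationError("batch index does not match sample index")
        bad = set(pd.unique(self.labels.dropna())) - {0, 1}
        if bad:
            raise ValidationError(f"labels must be binary 0/1, found {sorted(bad)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """Return a copy carrying ``values`` and the same sample metadata."""
        return ExpressionMatrix(values, self.labels.copy(), self.batch.copy())

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.columns]
        return self.with_values(self.values.loc[:, genes].copy())


# A pathway map is a plain mapping pathway-name -> set of gene ids; GMT
# descriptions live alongside in the IO layer.
PathwayMap = dict


def validate_sumstats(df: pd.DataFrame, name: str = "summary stats") -> pd.DataFrame:
    """Validate (and return) a summary-statistics table.

    Checks the required columns, unique SNP ids, alleles in {A,C,G,T},
    SE > 0, EAF in (0,1), P in (0,1].
    """
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{name}: missing column: {missing[0]}")
    if df["SNP"].duplicated().any():
        dupes = df.loc[df["SNP"].duplicated(), "SNP"].tolist()
        raise ValidationError(f"{name}: duplicate SNP ids: {dupes[:5]}")
    for col in ("EA", "OA"):
        bad = ~df[col].isin(list(VALID_ALLELES))
        if bad.any():
            raise ValidationError(
                f"{name}: invalid {col} alleles at rows {list(df.index[bad][:5])}"
            )
    if (df["SE"] <= 0).any():
        raise ValidationError(f"{name}: SE must be > 0")
    if ((df["EAF"] <= 0) | (df["EAF"] >= 1)).any():
        raise ValidationError(f"{name}: EAF must lie in (0,1)")
    if ((df["P"] <= 0) | (df["P"] > 1)).any():
        raise ValidationError(f"{name}: P must lie in (0,1]")
    return df


def is_palindromic(ea: str, oa: str) -> bool:
    """A/T and C/G pairs cannot be resolved from alleles alone."""
    return COMPLEMENT.get(ea) == oa


@dataclass
class TruthRecord:
    """Ground truth of a synthetic dataset, sufficient to score recovery."""

    kind: str
    params: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.params[key]


def se_from_maf_n(maf: np.ndarray, n: float | np.ndarray) -> np.ndarray:
    """Standard error of a per-allele effect on a standardized trait.

    Uses the usual GWAS approximation ``se = 1/sqrt(2 maf (1-maf) n)``,
    which makes instrument strength analytically predictable.
    """
    maf = np.asarray(maf, dtype=float)
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * np.asarray(n, dtype=float))
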