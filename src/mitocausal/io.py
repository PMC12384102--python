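"""On-disk formats and pipeline configuration.

All tables are tab-separated UTF-8 with a header row; genomic positions are
1-based inclusive. Pathways use the GMT dialect (name, description, member
genes per line). Malformed rows are rejected with their line number;
missing required columns are named in the error.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .containers import ExpressionMatrix, SUMSTATS_COLUMNS, ValidationError, validate_sumstats
from .drugs import DRUG_TABLE_COLUMNS

__all__ = [
    "PipelineConfig",
    "read_expression_tsv", "write_expression_tsv",
    "read_gmt", "write_gmt",
    "read_sumstats_tsv", "write_sumstats_tsv",
    "read_ld_matrix", "write_ld_matrix",
    "read_trait_panel", "write_trait_panel",
    "read_drug_table", "write_drug_table",
]

_EXPR_META = ["sample_id", "label", "batch"]


# ---------------------------------------------------------------------------
# expression + pathways
# ---------------------------------------------------------------------------

def write_expression_tsv(m: ExpressionMatrix, path) -> None:
    df = m.values.copy()
    df.insert(0, "batch", m.batch)
    df.insert(0, "label", m.labels)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_expression_tsv(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _EXPR_META if c not in df.columns]
    if missing:
        raise ValidationError(f"expression table: missing column: {missing[0]}")
    df = df.set_index("sample_id")
    df.index.name = None
    return ExpressionMatrix(df.drop(columns=["label", "batch"]),
                            df["label"], df["batch"])


def write_gmt(pmap: dict, path, descriptions: dict | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in pmap.items():
            desc = descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_gmt(path) -> tuple:
    """Parse a GMT file; returns (pathway map, descriptions)."""
    pmap, desc = {}, {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"GMT line {lineno}: expected name, description and >=1 gene")
            name = parts[0]
            if name in pmap:
                raise ValidationError(f"GMT line {lineno}: duplicate pathway {name!r}")
            pmap[name] = set(parts[2:])
            desc[name] = parts[1]
    return pmap, desc


# ---------------------------------------------------------------------------
# summary statistics, LD, panels, drug tables
# ---------------------------------------------------------------------------

def write_sumstats_tsv(df: pd.DataFrame, path) -> None:
    validate_sumstats(df)[SUMSTATS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sumstats_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_sumstats(df, str(path))


def write_ld_matrix(ld: pd.DataFrame, path) -> None:
    if not ld.index.equals(ld.columns):
        raise ValidationError("LD matrix must be square and SNP-id indexed")
    ld.to_csv(path, sep="\t")


def read_ld_matrix(path) -> pd.DataFrame:
    ld = pd.read_csv(path, sep="\t", index_col=0)
    if list(ld.index) != list(ld.columns):
        raise ValidationError("LD matrix must be square with matching SNP ids")
    return ld


_PANEL_COLUMNS = ["trait", "SNP", "BETA", "SE", "P", "N"]


def write_trait_panel(panel: pd.DataFrame, path) -> None:
    missing = [c for c in _PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValidationError(f"trait panel: missing column: {missing[0]}")
    panel[_PANEL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_trait_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"trait panel: missing column: {missing[0]}")
    if df.duplicated(["trait", "SNP"]).any():
        raise ValidationError("trait panel: duplicate (trait, SNP) pairs")
    return df


def write_drug_table(table: pd.DataFrame, path) -> None:
    missing = [c for c in DRUG_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"drug table: missing column: {missing[0]}")
    table[DRUG_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_drug_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DRUG_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"drug table: missing column: {missing[0]}")
    if df.duplicated(["drug_id", "gene"]).any():
        raise ValidationError("drug table: duplicate (drug, gene) pairs")
    return df


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every stage threshold in one place, defaulting to the study values.

    Round-trips losslessly through YAML. Unset seeds are an error when
    ``strict_seeds`` is on (the default for tests and reproducible runs).
    """

    # stage toggles
    run_ml: bool = True
    run_mr: bool = True
    run_coloc: bool = True
    run_phewas: bool = True
    run_drugs: bool = True
    # ML
    cv_folds: int = 10
    model_set: list = field(default_factory=lambda: ["logistic_regression",
                                                     "random_forest"])
    variance_threshold: float = 0.01
    min_pathway_genes: int = 5
    # MR
    mr_p_threshold: float = 1e-8
    mr_r2_max: float = 0.001
    mr_window_kb: float = 10_000.0
    mr_f_min: float = 10.0
    fdr_q: float = 0.05
    # coloc
    coloc_half_windows_kb: list = field(default_factory=lambda: [10, 50, 100, 200])
    coloc_snp_target: int = 500
    coloc_priors: list = field(default_factory=lambda: [1e-4, 1e-4, 1e-5])
    snp_pp_h4_high: float = 0.8
    snp_pp_h4_suggestive: float = 0.6
    # seeds / paths
    seed: int | None = 0
    out_dir: str = "results/run"
    strict_seeds: bool = True

    def __post_init__(self) -> None:
        if self.strict_seeds and self.seed is None:
            raise ValidationError("seed must be set (strict_seeds is on)")
        if not self.run_coloc:
            # phewas screens coloc-flagged SNPs, so it cannot run without coloc
            self.run_phewas = False

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))
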