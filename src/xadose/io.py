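"""Strict TSV readers/writers for the pipeline's tabular formats.

Canonical dialect: tab-separated, UTF-8, no quoting, '.' decimal. Gene and
sample order is preserved as given; downstream statistics are order-invariant.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, FormatError, InputError
from .simulate import GENOTYPES

__all__ = [
    "PipelineConfig",
    "read_count_matrix", "write_count_matrix",
    "read_annotation", "write_annotation",
    "read_sample_sheet", "write_sample_sheet",
    "read_allele_counts", "write_allele_counts",
    "read_truth_table", "write_truth_table",
    "read_config", "write_config",
    "validate_tables",
]

_ANN_COLS = ["gene_id", "chrom_class", "x_category", "trans_target", "trans_beta"]
_SHEET_COLS = ["sample_id", "genotype", "replicate"]
_ALLELE_COLS = ["gene_id", "snp_id", "sample_id", "count_allele_A", "count_allele_B"]


@dataclass
class PipelineConfig:
    """Analysis thresholds and run settings.

    Defaults follow the published workflow: DE at padj <= 0.05 and
    |log2FC| >= 0.5, rowSums >= 10 pre-filter, top-500 variable genes for
    structure analysis, 100,000 resampling draws for set overlap, and a
    10-read coverage floor for informative SNPs.
    """

    lfc_threshold: float = 0.5
    padj_threshold: float = 0.05
    min_row_sum: int = 10
    top_n_variable: int = 500
    n_permutations: int = 100000
    min_snp_coverage: int = 10
    ase_mono_threshold: float = 0.95
    ase_biallelic_threshold: float = 0.80
    erosion_biallelic_cutoff: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.padj_threshold < 1:
            raise InputError("padj_threshold must be in (0, 1)")
        for name in ("lfc_threshold", "top_n_variable", "n_permutations",
                     "ase_mono_threshold", "ase_biallelic_threshold"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.min_row_sum < 0 or self.min_snp_coverage < 0:
            raise InputError("min_row_sum and min_snp_coverage must be >= 0")
        if self.ase_biallelic_threshold >= self.ase_mono_threshold:
            raise InputError(
                "ase_biallelic_threshold must be < ase_mono_threshold")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols:
                raise FormatError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(parts)} fields, expected {n_cols})")
            rows.append(parts)
    return pd.DataFrame(rows, columns=header)


def _require_columns(df: pd.DataFrame, cols: list[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")


def _check_unique(values: pd.Series, what: str, path: str | Path) -> None:
    dup = values[values.duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate {what}: {sorted(set(dup))[:5]}")


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample count matrix (first column gene_id).

    Entries must be nonnegative integers; duplicate gene or sample labels
    and ragged rows are rejected with the offending label/line.
    """
    df = _read_tsv(path)
    if df.columns[0] != "gene_id":
        raise FormatError(f"{path}: first column must be 'gene_id', "
                          f"got {df.columns[0]!r}")
    _check_unique(pd.Series(df.columns[1:]), "sample_id", path)
    _check_unique(df["gene_id"], "gene_id", path)
    counts = df.set_index("gene_id")
    for col in counts.columns:
        try:
            as_num = pd.to_numeric(counts[col])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric count in sample {col!r}: "
                              f"{exc}") from None
        as_int = as_num.astype(np.int64, errors="ignore")
        if not np.array_equal(as_num.to_numpy(dtype=float),
                              np.floor(as_num.to_numpy(dtype=float))):
            raise FormatError(f"{path}: non-integer count in sample {col!r}")
        if (as_num < 0).any():
            raise FormatError(f"{path}: negative count in sample {col!r}")
        counts[col] = as_int.astype(np.int64)
    counts.index.name = "gene_id"
    return counts


def write_count_matrix(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the gene annotation; enums are validated and canonicalized."""
    df = _read_tsv(path)
    _require_columns(df, ["gene_id", "chrom_class"], path)
    _check_unique(df["gene_id"], "gene_id", path)
    bad = set(df["chrom_class"]) - {"autosome", "X", "Y"}
    if bad:
        raise FormatError(f"{path}: unknown chrom_class value(s): {sorted(bad)}")
    if "x_category" not in df.columns:
        df["x_category"] = np.where(df["chrom_class"] == "X", "xci_subject", "none")
    bad = set(df["x_category"]) - {"xci_subject", "escapee", "xist_like", "none"}
    if bad:
        raise FormatError(f"{path}: unknown x_category value(s): {sorted(bad)}")
    mismatch = (df["x_category"] != "none") != (df["chrom_class"] == "X")
    if mismatch.any():
        genes = df.loc[mismatch, "gene_id"].tolist()[:5]
        raise FormatError(f"{path}: x_category inconsistent with chrom_class "
                          f"for gene(s) {genes}")
    if "trans_target" in df.columns:
        df["trans_target"] = df["trans_target"].str.strip().str.lower().map(
            {"true": True, "false": False, "1": True, "0": False})
        if df["trans_target"].isna().any():
            raise FormatError(f"{path}: trans_target must be boolean")
    else:
        df["trans_target"] = False
    df["trans_beta"] = (pd.to_numeric(df["trans_beta"])
                        if "trans_beta" in df.columns else 0.0)
    non_aut_target = df["trans_target"] & (df["chrom_class"] != "autosome")
    if non_aut_target.any():
        raise FormatError(f"{path}: trans_target requires chrom_class=autosome")
    return df[_ANN_COLS]


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann[_ANN_COLS].to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the sample sheet; genotypes are canonicalized to upper case."""
    df = _read_tsv(path)
    _require_columns(df, _SHEET_COLS, path)
    _check_unique(df["sample_id"], "sample_id", path)
    df["genotype"] = df["genotype"].str.strip().str.upper()
    bad = set(df["genotype"]) - set(GENOTYPES)
    if bad:
        raise FormatError(
            f"{path}: unknown genotype value(s): {sorted(bad)}; "
            f"allowed: {sorted(GENOTYPES)}")
    df["replicate"] = pd.to_numeric(df["replicate"]).astype(int)
    if (df["replicate"] < 1).any():
        raise FormatError(f"{path}: replicate must be >= 1")
    if "eroded" in df.columns:
        df["eroded"] = df["eroded"].str.strip().str.lower().map(
            {"true": True, "false": False, "1": True, "0": False})
        if df["eroded"].isna().any():
            raise FormatError(f"{path}: eroded must be boolean")
    else:
        df["eroded"] = False
    return df[_SHEET_COLS + ["eroded"]]


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    cols = _SHEET_COLS + (["eroded"] if "eroded" in sheet.columns else [])
    sheet[cols].to_csv(path, sep="\t", index=False)


def read_allele_counts(path: str | Path) -> pd.DataFrame:
    """Read the optional allele-count table; an empty table is valid."""
    df = _read_tsv(path)
    if df.empty and list(df.columns) == [""]:
        return pd.DataFrame(columns=_ALLELE_COLS)
    _require_columns(df, _ALLELE_COLS, path)
    for col in ("count_allele_A", "count_allele_B"):
        df[col] = pd.to_numeric(df[col]).astype(np.int64)
        if (df[col] < 0).any():
            raise FormatError(f"{path}: negative value in {col}")
    return df[_ALLELE_COLS]


def write_allele_counts(table: pd.DataFrame, path: str | Path) -> None:
    table[_ALLELE_COLS].to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require_columns(df, ["gene_id", "mu"], path)
    for col in df.columns:
        if col.startswith("dose_") or col in ("mu", "trans_beta"):
            df[col] = pd.to_numeric(df[col])
        elif col == "trans_target":
            df[col] = df[col].str.strip().str.lower().map(
                {"true": True, "false": False})
    return df


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def validate_tables(counts: pd.DataFrame, annotation: pd.DataFrame | None = None,
                    sample_sheet: pd.DataFrame | None = None) -> None:
    """Cross-table consistency: every count-matrix sample must appear in the
    sample sheet and every gene in the annotation."""
    if sample_sheet is not None:
        missing = [s for s in counts.columns
                   if s not in set(sample_sheet["sample_id"])]
        if missing:
            raise ConsistencyError(
                f"sample(s) in count matrix but not in sample sheet: "
                f"{missing[:10]}")
    if annotation is not None:
        known = set(annotation["gene_id"])
        missing = [g for g in counts.index if g not in known]
        if missing:
            raise ConsistencyError(
                f"gene(s) in count matrix but not in annotation: "
                f"{missing[:10]}")


def read_config(path: str | Path) -> PipelineConfig:
    """Read a flat ``key = value`` config file ('#' starts a comment)."""
    cfg = PipelineConfig()
    fields = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}: line {lineno} is not 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in fields:
                raise FormatError(f"{path}: unknown config key {key!r}")
            current = getattr(cfg, key)
            setattr(cfg, key, type(current)(float(value))
                    if isinstance(current, int) else float(value))
    cfg.validate()
    return cfg


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for f in dataclasses.fields(PipelineConfig):
            fh.write(f"{f.name} = {getattr(cfg, f.name)}\n")


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, np.bool_):
            return bool(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")
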