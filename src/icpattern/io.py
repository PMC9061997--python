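"""Readers, writers and in-memory containers for the pipeline's file formats.

Formats: TSV and GCT v1.2 for expression, GMT for gene sets, MAF for somatic
mutations, TSV for clinical tables and thresholded CNV calls.  Gene symbols
are the join key everywhere; all outputs are TSV with a header row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "GeneSetCollection",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical",
    "write_clinical",
    "read_maf",
    "write_maf",
    "read_gmt",
    "write_gmt",
    "read_cnv",
    "write_cnv",
]

MAF_REQUIRED_COLUMNS = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


@dataclass
class ExpressionMatrix:
    """Genes x samples continuous expression (log2 scale by convention).

    ``values`` is a DataFrame with gene symbols as the index and sample ids as
    columns; ``batch`` is an optional per-sample categorical Series aligned to
    the columns.
    """

    values: pd.DataFrame
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene symbols: {dup}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dup}")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise FormatError("expression values must be finite")
        if self.batch is not None:
            self.batch = self.batch.reindex(v.columns)
            if self.batch.isna().any():
                missing = self.batch.index[self.batch.isna()].tolist()
                raise FormatError(f"samples missing batch label: {missing}")

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        missing = sorted(set(genes) - set(present))
        if missing:
            warnings.warn(f"{len(missing)} requested genes absent from matrix: {missing[:5]}...")
        return ExpressionMatrix(self.values.loc[present].copy(), self.batch)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): unique names, no empty set."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    # keep the duplicate row with the largest mean (microarray probe convention)
    if not df.index.duplicated().any():
        return df
    means = df.mean(axis=1).to_numpy()
    keep = np.zeros(len(df), dtype=bool)
    order = pd.Series(means).groupby(df.index.to_numpy()).idxmax()
    keep[order.to_numpy()] = True
    return df.loc[keep]


def read_expression_matrix(
    path: str | Path,
    format: str = "tsv",
    batch: pd.Series | None = None,
    log2: bool = False,
) -> ExpressionMatrix:
    """Read a genes x samples expression table.

    TSV dialect: first column gene symbols, remaining columns samples.
    GCT v1.2: ``#1.2`` header, dimension line, then Name/Description columns.
    Duplicate gene rows are collapsed by keeping the row with the largest mean.
    ``log2=True`` applies log2(x+1) for raw TPM-like input.
    """
    path = Path(path)
    if format == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        dup = sorted({s for s in header if header.count(s) > 1})
        if dup:
            raise FormatError(f"duplicate sample id(s): {dup}")
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.columns = header  # undo pandas' mangling of any remaining oddities
    elif format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version not in ("#1.2",):
                raise FormatError(f"unsupported GCT version line: {version!r}")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise FormatError("malformed GCT dimension line")
            df = pd.read_csv(fh, sep="\t", index_col=0)
        df = df.drop(columns=["Description"], errors="ignore")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        if df.shape != (n_genes, n_samples):
            raise FormatError(
                f"GCT dimension line says {n_genes}x{n_samples}, table is {df.shape}"
            )
    else:
        raise FormatError(f"unknown expression format: {format!r}")

    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample id(s): {dup}")
    for j, col in enumerate(df.columns):
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any():
            i = int(np.flatnonzero(bad.isna().to_numpy())[0])
            raise FormatError(
                f"non-numeric cell at gene {df.index[i]!r}, sample {col!r} "
                f"(row {i + 1}, column {j + 2})"
            )
    df = df.astype(float)
    df = _collapse_duplicate_genes(df)
    if log2:
        if (df.to_numpy() < 0).any():
            raise FormatError("log2 transform requested but matrix has negative values")
        df = np.log2(df + 1.0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, batch=batch)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV keyed by ``sample_id`` with os_time/os_event columns."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError("clinical table must have a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample ids in clinical table")
    df = df.set_index("sample_id")
    for col in ("os_time", "os_event"):
        if col not in df.columns:
            raise FormatError(f"clinical table missing required column {col!r}")
    if not df["os_event"].isin([0, 1]).all():
        raise FormatError("os_event must be 0/1")
    if (df["os_time"] < 0).any():
        raise FormatError("os_time must be nonnegative")
    return df


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    out = clinical.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_maf(path: str | Path) -> pd.DataFrame:
    """Read a MAF file; '#'-comment lines skipped, extra columns kept as payload."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MAF_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"MAF missing required column(s): {missing}")
    return df.reset_index(drop=True)


def write_maf(maf: pd.DataFrame, path: str | Path) -> None:
    maf.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read GMT gene sets: name TAB description TAB gene TAB gene..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            genes = [g for g in fields[2:] if g.strip()]
            if not genes:
                raise FormatError(f"GMT line {lineno}: set {name!r} has no genes")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *collection[name]]) + "\n")


def read_cnv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples CNV call table; GISTIC-like +/-2 collapsed to +/-1."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy()
    if not np.isin(vals, [-2, -1, 0, 1, 2]).all():
        raise FormatError("CNV calls must be integers in -2..2")
    df = df.clip(-1, 1).astype(int)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_cnv(cnv: pd.DataFrame, path: str | Path) -> None:
    out = cnv.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
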