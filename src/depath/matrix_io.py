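"""Expression-matrix and design-table containers and file I/O.

The central container is :class:`ExpressionMatrix`, a thin wrapper around a
genes x samples :class:`pandas.DataFrame` that tracks whether the values are
raw read counts, normalized expression (e.g. CPM/FPKM), or log-transformed
data. Input files are plain CSV/TSV with the first column holding gene
identifiers; a design table maps samples to experimental factor levels.

Duplicate gene identifiers can arise when several probe or transcript ids
map to the same gene: :func:`collapse_duplicate_ids` resolves them by
keeping, per target id, the row with the largest standard deviation across
samples (the most informative measurement).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DesignTable",
    "MatrixIOError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_design",
    "collapse_duplicate_ids",
]


class MatrixIOError(ValueError):
    """Raised for malformed expression or design input."""


SCALE_KINDS = ("counts", "normalized", "transformed")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with one column per sample.
    scale_kind
        One of ``"counts"`` (non-negative integers), ``"normalized"``
        (non-negative reals such as CPM), or ``"transformed"`` (reals,
        e.g. log2 scale).
    allow_duplicate_ids
        Reading a file keeps duplicate gene-id rows so they can be
        collapsed explicitly later; analysis steps require unique ids.
    """

    data: pd.DataFrame
    scale_kind: str = "normalized"
    allow_duplicate_ids: bool = False

    def __post_init__(self) -> None:
        if self.scale_kind not in SCALE_KINDS:
            raise MatrixIOError(f"unknown scale_kind {self.scale_kind!r}")
        if self.data.shape[1] < 2:
            raise MatrixIOError("expression matrix needs at least 2 samples")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise MatrixIOError(f"duplicate sample names: {dups}")
        if not self.allow_duplicate_ids and self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise MatrixIOError(f"duplicate gene ids: {dups[:5]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise MatrixIOError("expression values must be numeric")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise MatrixIOError(
                f"missing value at gene {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}; missing values are not supported"
            )
        if not np.isfinite(values).all():
            raise MatrixIOError("expression values must be finite")
        if self.scale_kind == "counts" and (values < 0).any():
            raise MatrixIOError("counts matrix contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: pd.DataFrame, scale_kind: str | None = None) -> "ExpressionMatrix":
        """Return a new matrix sharing configuration but with new data."""
        return ExpressionMatrix(data, scale_kind or self.scale_kind)


@dataclass
class DesignTable:
    """Per-sample experimental factor levels.

    ``data`` is indexed by sample id, one column per factor. Every factor
    must have at least two observed levels; ``reference_levels`` records
    the baseline level per factor (defaults to the lexicographically first).
    """

    data: pd.DataFrame
    reference_levels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise MatrixIOError("duplicate sample names in design")
        for factor in self.data.columns:
            levels = self.data[factor].astype(str).unique()
            if len(levels) < 2:
                raise MatrixIOError(
                    f"factor {factor!r} has a single level {levels[0]!r}; "
                    "factors must vary across samples"
                )
            self.reference_levels.setdefault(factor, sorted(levels)[0])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def factors(self) -> list[str]:
        return list(self.data.columns)

    def levels(self, factor: str) -> pd.Series:
        if factor not in self.data.columns:
            raise KeyError(f"unknown factor {factor!r}")
        return self.data[factor].astype(str)


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text().splitlines()
    head = "\n".join(sample[:10])
    try:
        return csv.Sniffer().sniff(head, delimiters=",\t;").delimiter
    except csv.Error:
        # single-column or ambiguous header; count candidates in first line
        first = sample[0] if sample else ""
        best = max(",\t;", key=first.count)
        return best


def read_expression_matrix(
    path: str | Path, delimiter: str | None = None, scale_kind: str | None = None
) -> ExpressionMatrix:
    """Read a genes x samples table from CSV/TSV.

    First column holds gene ids, remaining columns numeric expression
    values. The delimiter is auto-detected among comma/tab/semicolon when
    not given. Duplicate gene-id rows are retained (collapse them with
    :func:`collapse_duplicate_ids`). ``scale_kind`` is guessed as
    ``"counts"`` iff every value is a non-negative integer, unless
    overridden.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise MatrixIOError(f"{path} is empty")
    delim = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delim, index_col=0, comment="#")
    if df.shape[1] < 2:
        raise MatrixIOError(f"{path}: fewer than 2 sample columns (delimiter {delim!r})")
    df.index = df.index.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise MatrixIOError(
                f"{path}: non-numeric value {bad.iloc[0]!r} at gene {row!r}, column {col!r}"
            )
    values = df.to_numpy()
    if scale_kind is None:
        is_counts = (
            np.isfinite(values).all()
            and (values >= 0).all()
            and np.allclose(values, np.round(values))
        )
        scale_kind = "counts" if is_counts else "normalized"
    return ExpressionMatrix(df.astype(float), scale_kind, allow_duplicate_ids=True)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path, float_format: str = "%.10g") -> None:
    """Write a matrix as TSV (gene ids in the first column)."""
    matrix.data.to_csv(Path(path), sep="\t", index_label="gene_id", float_format=float_format)


def read_design(path: str | Path, matrix: ExpressionMatrix) -> DesignTable:
    """Read a design table and harmonize its sample order to ``matrix``.

    The first column holds sample names; remaining columns are factors.
    The sample set must match the matrix's sample set exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delim = _sniff_delimiter(path)
    # factor levels are labels: never interpret "null"/"NA" as missing
    df = pd.read_csv(path, sep=delim, index_col=0, comment="#", dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    missing = set(matrix.sample_ids) - set(df.index)
    extra = set(df.index) - set(matrix.sample_ids)
    if missing or extra:
        raise MatrixIOError(
            f"design/matrix sample mismatch: missing from design {sorted(missing)}, "
            f"not in matrix {sorted(extra)}"
        )
    df = df.loc[matrix.sample_ids]
    return DesignTable(df)


def collapse_duplicate_ids(
    matrix: ExpressionMatrix, mapping: Sequence[tuple[int, str]]
) -> ExpressionMatrix:
    """Collapse rows that map to the same target id, keeping the max-SD row.

    ``mapping`` is a list of ``(row_index, target_id)`` pairs covering every
    row (identity mapping allowed). When several rows share a target id,
    only the one with the largest sample standard deviation (ddof=1) across
    samples is retained and relabeled; ties keep the row appearing first in
    the mapping. Output row order follows first appearance of each target.
    """
    if len(mapping) == 0:
        raise MatrixIOError("empty mapping")
    rows = [r for r, _ in mapping]
    if sorted(rows) != list(range(matrix.n_genes)):
        raise MatrixIOError("mapping must cover every row exactly once")
    values = matrix.values
    sds = values.std(axis=1, ddof=1)
    best: dict[str, tuple[float, int]] = {}
    order: list[str] = []
    for row, target in mapping:
        if target not in best:
            order.append(target)
            best[target] = (sds[row], row)
        elif sds[row] > best[target][0]:  # strict: ties keep the earlier row
            best[target] = (sds[row], row)
    keep_rows = [best[t][1] for t in order]
    out = matrix.data.iloc[keep_rows].copy()
    out.index = pd.Index(order, name=matrix.data.index.name)
    return ExpressionMatrix(out, matrix.scale_kind)
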