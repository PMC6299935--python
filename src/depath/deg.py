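"""Differential expression: a Welch-t two-group test, thresholding, overlaps.

The built-in test is a simple per-gene Welch two-sample t-test on
log-scale data with Benjamini-Hochberg FDR — a deliberately plain
fallback so the pipeline runs end to end; results from dedicated count
models (DESeq2, limma, edgeR, cuffdiff) can be imported instead via
:func:`read_de_table` and drive all downstream enrichment and pathway
steps.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from depath.matrix_io import DesignTable, ExpressionMatrix

__all__ = ["DEResult", "welch_de", "apply_thresholds", "venn_counts", "read_de_table"]


@dataclass
class DEResult:
    """Per-gene differential-expression statistics.

    ``table`` columns: gene_id, log2_fold_change (test vs reference),
    p_value, fdr, direction (up/down/ns once thresholds are applied).
    """

    table: pd.DataFrame
    comparison: str = ""

    def __post_init__(self) -> None:
        required = {"gene_id", "log2_fold_change", "fdr"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DE table missing columns {sorted(missing)}")
        if "direction" not in self.table.columns:
            self.table = self.table.assign(direction="ns")
        bad = ~self.table["fdr"].between(0, 1)
        if bad.any():
            raise ValueError("fdr values outside [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])

    def fold_changes(self) -> pd.Series:
        return pd.Series(
            self.table["log2_fold_change"].to_numpy(), index=self.table["gene_id"]
        )


def welch_de(
    matrix: ExpressionMatrix,
    design: DesignTable,
    factor: str,
    level_a: str,
    level_b: str,
) -> DEResult:
    """Per-gene Welch t-test of ``level_a`` vs ``level_b`` (log2 scale).

    log2FC = mean(level_a) - mean(level_b); BH FDR across all genes.
    Genes with zero variance in both groups get p = 1 (no evidence).
    """
    levels = design.levels(factor)
    for lv in (level_a, level_b):
        if lv not in set(levels):
            raise KeyError(f"level {lv!r} not in factor {factor!r}")
    samples_a = levels.index[levels == level_a]
    samples_b = levels.index[levels == level_b]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need >= 2 samples per level for the Welch test")
    a = matrix.data[samples_a].to_numpy()
    b = matrix.data[samples_b].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "log2_fold_change": log2fc,
            "p_value": p,
            "fdr": fdr,
        }
    )
    return DEResult(table, comparison=f"{factor}:{level_a}_vs_{level_b}")


def apply_thresholds(
    result: DEResult, fdr_cut: float = 0.1, fc_cut: float = 2.0
) -> tuple[list[str], list[str]]:
    """Split genes into up/down lists at FDR < fdr_cut and fold-change > fc_cut.

    Both inequalities are strict; ``fc_cut`` is on the linear scale
    (fc_cut=2 requires |log2FC| > 1). Directions are recorded in the
    result table (up/down/ns).
    """
    if fc_cut <= 1:
        raise ValueError("fc_cut must be > 1 (linear fold-change)")
    t = result.table
    log2_cut = np.log2(fc_cut)
    sig = t["fdr"] < fdr_cut
    up = sig & (t["log2_fold_change"] > log2_cut)
    down = sig & (t["log2_fold_change"] < -log2_cut)
    direction = np.where(up, "up", np.where(down, "down", "ns"))
    result.table = t.assign(direction=direction)
    return list(t.loc[up, "gene_id"]), list(t.loc[down, "gene_id"])


def venn_counts(lists: dict[str, list[str]]) -> dict[str, int]:
    """Region counts for the Venn diagram of 2-3 named gene lists.

    Keys are '&'-joined sorted combinations of list names ('A', 'A&B', ...)
    holding the number of genes exclusive to that region.
    """
    if not 2 <= len(lists) <= 3:
        raise ValueError("venn_counts takes 2 or 3 lists")
    sets = {name: set(v) for name, v in lists.items()}
    if any(len(s) == 0 for s in sets.values()):
        raise ValueError("lists must be non-empty")
    names = sorted(sets)
    counts: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(*(sets[n] for n in names if n not in combo), set())
            counts["&".join(combo)] = len(inside - outside)
    return counts


def read_de_table(path: str | Path) -> DEResult:
    """Import an external DE table (e.g. from DESeq2 or cuffdiff).

    TSV/CSV with columns ``gene_id``, ``log2FoldChange`` and ``FDR``
    (``PValue`` optional); common aliases (log2FC, padj, adj.P.Val,
    qvalue) are recognized.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    aliases = {
        "gene": "gene_id",
        "gene_id": "gene_id",
        "log2foldchange": "log2_fold_change",
        "log2fc": "log2_fold_change",
        "log2_fold_change": "log2_fold_change",
        "pvalue": "p_value",
        "p_value": "p_value",
        "fdr": "fdr",
        "padj": "fdr",
        "adj.p.val": "fdr",
        "qvalue": "fdr",
    }
    renamed = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in aliases:
            renamed[col] = aliases[key]
    df = df.rename(columns=renamed)
    if "gene_id" not in df.columns:
        df = df.rename(columns={df.columns[0]: "gene_id"})
    keep = [c for c in ("gene_id", "log2_fold_change", "p_value", "fdr") if c in df.columns]
    df = df[keep]
    df["gene_id"] = df["gene_id"].astype(str)
    return DEResult(df, comparison=path.stem)
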