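"""Count pre-processing and QC.

Low-expression filtering on the counts-per-million (CPM) scale, a started
log2 transform, skew detection (which enforces the log transform on raw,
highly right-skewed data), and a one-way ANOVA of per-library total counts
across sample groups — uneven sequencing depth between groups is a
confounder worth flagging before any differential analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from depath.matrix_io import DesignTable, ExpressionMatrix

__all__ = [
    "PreprocessConfig",
    "compute_cpm",
    "filter_low_expression",
    "transform_counts",
    "detect_skew",
    "library_size_anova",
]


@dataclass
class PreprocessConfig:
    """Pre-processing parameters.

    cpm_threshold
        Keep a gene if its CPM reaches this value in at least
        ``min_samples`` samples. Default 0.5 CPM in >=1 sample.
    pseudocount
        Offset c of the started log transform log2(CPM + c). Default 4,
        which damps the variance of low-count genes.
    skew_threshold
        Sample skewness above which a non-negative value distribution is
        declared highly skewed, enforcing log transformation.
    anova_alpha
        Significance level for the library-size ANOVA warning.
    """

    cpm_threshold: float = 0.5
    min_samples: int = 1
    transform: str = "log_started"  # or "none"
    pseudocount: float = 4.0
    skew_threshold: float = 2.0
    anova_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.cpm_threshold < 0:
            raise ValueError("cpm_threshold must be >= 0")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.transform not in ("log_started", "none"):
            raise ValueError(f"unknown transform {self.transform!r}")


def _require_counts(matrix: ExpressionMatrix) -> None:
    if matrix.scale_kind != "counts":
        raise ValueError(f"expected a counts matrix, got scale_kind={matrix.scale_kind!r}")


def compute_cpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Counts per million: value / library size * 1e6, per sample column."""
    _require_counts(matrix)
    libsizes = matrix.data.sum(axis=0)
    zero = libsizes[libsizes == 0]
    if len(zero):
        raise ValueError(f"zero-total libraries: {list(zero.index)}")
    cpm = matrix.data.div(libsizes, axis=1) * 1e6
    return ExpressionMatrix(cpm, "normalized")


def filter_low_expression(
    matrix: ExpressionMatrix, cfg: PreprocessConfig | None = None
) -> tuple[ExpressionMatrix, int]:
    """Remove genes below ``cfg.cpm_threshold`` CPM in all but < min_samples samples.

    Returns the filtered matrix (original row order preserved, counts
    scale) and the number of genes removed.
    """
    cfg = cfg or PreprocessConfig()
    _require_counts(matrix)
    cpm = compute_cpm(matrix)
    keep = (cpm.data >= cfg.cpm_threshold).sum(axis=1) >= cfg.min_samples
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError(
            f"all {matrix.n_genes} genes removed at {cfg.cpm_threshold} CPM; "
            "lower cpm_threshold"
        )
    return ExpressionMatrix(matrix.data.loc[keep], "counts"), n_removed


def transform_counts(
    matrix: ExpressionMatrix, cfg: PreprocessConfig | None = None
) -> ExpressionMatrix:
    """Started log transform of CPM: log2(CPM + pseudocount).

    With ``cfg.transform == "none"`` the CPM values are returned
    untransformed; either way the result is marked ``transformed`` and
    ready for EDA/DE.
    """
    cfg = cfg or PreprocessConfig()
    cpm = compute_cpm(matrix)
    if cfg.transform == "none":
        return ExpressionMatrix(cpm.data, "transformed")
    out = np.log2(cpm.data + cfg.pseudocount)
    return ExpressionMatrix(out, "transformed")


def detect_skew(
    matrix: ExpressionMatrix, skew_threshold: float = 2.0
) -> tuple[bool, float]:
    """Sample skewness of the pooled value distribution.

    Returns ``(is_skewed, skewness)``; highly right-skewed non-negative
    data (skewness above threshold) indicates raw counts that should be
    log-transformed. A constant matrix has skewness 0 by convention.
    """
    values = matrix.values.ravel()
    if values.size < 10:
        raise ValueError("need at least 10 values to assess skew")
    if np.allclose(values, values[0]):
        return False, 0.0
    skewness = float(stats.skew(values))
    is_skewed = bool(skewness > skew_threshold and (values >= 0).all())
    return is_skewed, skewness


def library_size_anova(
    matrix: ExpressionMatrix,
    design: DesignTable,
    group_factor: str,
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """One-way ANOVA of per-sample total counts across groups.

    Returns ``(p_value, warning)``; the warning flags group-confounded
    sequencing depth at level ``alpha``.
    """
    _require_counts(matrix)
    totals = matrix.data.sum(axis=0)
    levels = design.levels(group_factor)
    groups = [totals[levels.index[levels == lv]].to_numpy() for lv in levels.unique()]
    if len(groups) < 2:
        raise ValueError(f"factor {group_factor!r} needs >= 2 levels")
    for lv, g in zip(levels.unique(), groups):
        if len(g) < 2:
            raise ValueError(f"level {lv!r} has fewer than 2 samples")
    if all(np.allclose(g, groups[0].mean()) for g in groups):
        return 1.0, False
    f, p = stats.f_oneway(*groups)
    p = float(p) if np.isfinite(p) else 1.0
    return p, bool(p < alpha)


def qc_report(
    matrix: ExpressionMatrix,
    design: DesignTable | None = None,
    group_factor: str | None = None,
    cfg: PreprocessConfig | None = None,
) -> pd.DataFrame:
    """Per-sample QC table: library size plus ANOVA p when a design is given."""
    cfg = cfg or PreprocessConfig()
    totals = matrix.data.sum(axis=0)
    report = pd.DataFrame({"sample": matrix.sample_ids, "total_counts": totals.to_numpy()})
    if design is not None and group_factor is not None:
        p, warn = library_size_anova(matrix, design, group_factor, cfg.anova_alpha)
        report.attrs["libsize_anova_p"] = p
        report.attrs["libsize_warning"] = warn
        report["group"] = design.levels(group_factor).loc[matrix.sample_ids].to_numpy()
    return report
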