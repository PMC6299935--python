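"""Parametric gene-set pathway analysis (PAGE) and per-sample activity scores.

PAGE scores a gene set against a vector of per-gene statistics (log2
fold-changes, one sample's centered expression, or PCA loadings): with
global mean mu and sample SD sigma over all G genes and set mean Sm over
its m members,

    Z = (Sm - mu) * sqrt(m) / sigma,

approximately standard normal under the null that the set is a random
draw. Applied per sample column on row-centered expression this yields a
pathways x samples activity matrix (the PGSEA display); a one-way ANOVA
of each pathway's Z across sample groups, BH-FDR cut, then ranking by the
SD of the per-sample Z surfaces the most differentially active pathways.
An absolute-value mode finds pathways that are strongly *regulated*
regardless of direction. PCA loadings can be scored the same way via a
per-set one-sample t-test against the global mean loading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from depath.enrich import GeneSetCollection
from depath.eda import PCAResult
from depath.matrix_io import DesignTable, ExpressionMatrix

__all__ = [
    "page_scores",
    "pgsea_sample_scores",
    "anova_rank_pathways",
    "pca_loading_pathways",
    "PathwayActivityMatrix",
]


@dataclass
class PathwayActivityMatrix:
    """Gene sets x samples Z-scores with per-set test statistics.

    ``z`` is indexed by set name with one column per sample; ``stats``
    (populated by :func:`anova_rank_pathways`) holds anova_p, fdr and
    spread (SD of the set's per-sample Z); ``groups`` maps samples to the
    factor levels used for the ANOVA.
    """

    z: pd.DataFrame
    stats: pd.DataFrame | None = None
    groups: pd.Series | None = None

    @property
    def set_names(self) -> list[str]:
        return list(self.z.index)


def _membership(
    collection: GeneSetCollection, gene_ids: list[str]
) -> tuple[list[str], np.ndarray]:
    """Set-membership indicator matrix restricted to the size window."""
    index = {g: i for i, g in enumerate(gene_ids)}
    names, rows = [], []
    for name, members in collection.sets.items():
        idx = [index[m] for m in members if m in index]
        if collection.size_min <= len(idx) <= collection.size_max:
            names.append(name)
            row = np.zeros(len(gene_ids), dtype=bool)
            row[idx] = True
            rows.append(row)
    M = np.array(rows) if rows else np.zeros((0, len(gene_ids)), dtype=bool)
    return names, M


def page_scores(
    fold_changes: pd.Series,
    collection: GeneSetCollection,
    abs_mode: bool = False,
) -> pd.DataFrame:
    """PAGE Z-test of each gene set on a per-gene fold-change vector.

    ``fold_changes`` is indexed by gene id. With ``abs_mode`` the absolute
    values are scored, detecting regulated (rather than directionally
    shifted) pathways. Returns columns set_name, m, set_mean, z, p_value,
    fdr sorted by p.
    """
    fc = fold_changes.astype(float)
    if fc.size < 10:
        raise ValueError("need >= 10 genes for PAGE")
    values = fc.to_numpy()
    if abs_mode:
        values = np.abs(values)
    mu = values.mean()
    sigma = values.std(ddof=1)
    if sigma == 0:
        raise ValueError("fold-change vector has zero variance")
    names, M = _membership(collection, list(fc.index))
    if not names:
        return pd.DataFrame(columns=["set_name", "m", "set_mean", "z", "p_value", "fdr"])
    m = M.sum(axis=1)
    set_means = (M @ values) / m
    z = (set_means - mu) * np.sqrt(m) / sigma
    p = 2.0 * stats.norm.sf(np.abs(z))
    fdr = multipletests(p, method="fdr_bh")[1]
    df = pd.DataFrame(
        {"set_name": names, "m": m, "set_mean": set_means, "z": z, "p_value": p, "fdr": fdr}
    )
    return df.sort_values(["p_value", "set_name"], kind="stable").reset_index(drop=True)


def pgsea_sample_scores(
    matrix: ExpressionMatrix, collection: GeneSetCollection
) -> PathwayActivityMatrix:
    """Per-sample PAGE Z-scores on row-centered expression.

    Each gene is centered by its mean across samples so a column measures
    that sample's deviation from the average profile; the PAGE statistic
    is then computed per set within each column (mu, sigma from that
    column over all genes). Returns sets x samples Z.
    """
    if matrix.n_samples < 2:
        raise ValueError("need >= 2 samples")
    X = matrix.values
    centered = X - X.mean(axis=1, keepdims=True)
    mu = centered.mean(axis=0)  # per sample
    sigma = centered.std(axis=0, ddof=1)
    if np.any(sigma == 0):
        bad = [matrix.sample_ids[j] for j in np.nonzero(sigma == 0)[0]]
        raise ValueError(f"constant column(s) after centering: {bad}")
    names, M = _membership(collection, matrix.gene_ids)
    m = M.sum(axis=1)
    set_means = (M @ centered) / m[:, None]
    z = (set_means - mu[None, :]) * np.sqrt(m)[:, None] / sigma[None, :]
    zdf = pd.DataFrame(z, index=names, columns=matrix.sample_ids)
    return PathwayActivityMatrix(z=zdf)


def anova_rank_pathways(
    activity: PathwayActivityMatrix,
    design: DesignTable,
    factor: str,
    fdr_cut: float = 0.05,
    top_k: int = 30,
    rank_by: str = "z_sd",
) -> PathwayActivityMatrix:
    """ANOVA-filter and SD-rank a pathway activity matrix.

    Per set, a one-way ANOVA of its per-sample Z across the groups of
    ``factor``; BH FDR across sets; survivors of ``fdr < fdr_cut`` are
    ranked by spread — the SD of the set's per-sample Z (``rank_by=
    "z_sd"``) or of the group means (``"group_mean_sd"``) — descending,
    ties by set name, truncated to ``top_k``.
    """
    levels = design.levels(factor)
    uniq = list(levels.unique())
    if len(uniq) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels")
    samples = list(activity.z.columns)
    group_cols = {lv: [s for s in samples if levels[s] == lv] for lv in uniq}
    for lv, cols in group_cols.items():
        if len(cols) < 2:
            raise ValueError(f"level {lv!r} has fewer than 2 samples")
    Z = activity.z
    pvals = np.ones(len(Z))
    for i, (_, row) in enumerate(Z.iterrows()):
        groups = [row[cols].to_numpy() for cols in group_cols.values()]
        pooled = np.concatenate(groups)
        if np.allclose(pooled, pooled[0]):
            pvals[i] = 1.0
            continue
        _, p = stats.f_oneway(*groups)
        pvals[i] = p if np.isfinite(p) else 1.0
    fdr = multipletests(pvals, method="fdr_bh")[1]
    if rank_by == "z_sd":
        spread = Z.to_numpy().std(axis=1, ddof=1)
    elif rank_by == "group_mean_sd":
        means = np.array(
            [[row[cols].mean() for cols in group_cols.values()] for _, row in Z.iterrows()]
        )
        spread = means.std(axis=1, ddof=1)
    else:
        raise ValueError(f"unknown rank_by {rank_by!r}")
    st = pd.DataFrame(
        {"anova_p": pvals, "fdr": fdr, "spread": spread}, index=Z.index
    )
    keep = st[st["fdr"] < fdr_cut]
    keep = keep.sort_values(["spread", "anova_p"], ascending=[False, True], kind="stable")
    # deterministic tie-break on identical spread: set name
    keep = keep.iloc[
        np.lexsort((keep.index.to_numpy(), -keep["spread"].to_numpy()))
    ].head(top_k)
    return PathwayActivityMatrix(
        z=Z.loc[keep.index], stats=keep, groups=levels.loc[samples]
    )


def pca_loading_pathways(
    pca: PCAResult,
    collection: GeneSetCollection,
    n_components: int = 5,
    per_pc: int = 5,
    min_set: int = 3,
) -> pd.DataFrame:
    """Pathway analysis of PCA loadings, component by component.

    Treats the loadings on each gene as expression data: per component, a
    one-sample t-test of each set's member loadings against the mean
    loading of all genes, BH-adjusted within the component. The top
    ``per_pc`` sets per component are reported, skipping sets already
    reported for an earlier component; labels carry the FDR then the
    component id.

    Returns columns component, set_name, m, t, p_value, fdr, label.
    """
    if pca.loadings.shape[0] < 10:
        raise ValueError("need loadings for >= 10 genes")
    n_components = min(n_components, pca.n_components)
    gene_ids = list(pca.loadings.index)
    index = {g: i for i, g in enumerate(gene_ids)}
    reported: set[str] = set()
    out_rows = []
    for c in range(n_components):
        comp = pca.loadings.columns[c]
        loadings = pca.loadings[comp].to_numpy()
        global_mean = loadings.mean()
        rows = []
        for name, members in collection.sets.items():
            idx = [index[g] for g in members if g in index]
            if len(idx) < min_set:
                continue
            if not collection.size_min <= len(idx) <= collection.size_max:
                continue
            vals = loadings[idx]
            if np.allclose(vals, vals[0]):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_1samp(vals, popmean=global_mean)
            rows.append((name, len(idx), float(t), float(p)))
        if not rows:
            continue
        df = pd.DataFrame(rows, columns=["set_name", "m", "t", "p_value"])
        df["fdr"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values(["fdr", "p_value", "set_name"], kind="stable")
        picked = df[~df["set_name"].isin(reported)].head(per_pc).copy()
        reported.update(picked["set_name"])
        picked.insert(0, "component", comp)
        picked["label"] = [
            f"{row.fdr:.2g} {comp} {row.set_name}" for row in picked.itertuples()
        ]
        out_rows.append(picked)
    if not out_rows:
        return pd.DataFrame(
            columns=["component", "set_name", "m", "t", "p_value", "fdr", "label"]
        )
    return pd.concat(out_rows, ignore_index=True)
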