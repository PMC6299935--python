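"""Exploratory analysis: variable-gene selection, clustering, PCA.

Genes are ranked by standard deviation across samples and the top slice
(1000 by default, more for complex designs) feeds hierarchical clustering
(correlation distance, average linkage), k-means with a within-group
sum-of-squares elbow curve, and PCA where samples are the observations.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from depath.matrix_io import ExpressionMatrix

__all__ = [
    "ClusterAssignment",
    "PCAResult",
    "select_top_variable",
    "hierarchical_cluster",
    "dendrogram_to_newick",
    "correlation_matrix",
    "kmeans_cluster",
    "run_pca",
]


@dataclass
class ClusterAssignment:
    """k-means gene clusters labeled A, B, ... by descending size."""

    gene_ids: list[str]
    cluster_labels: list[str]
    k: int
    wss_curve: list[tuple[int, float]]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.gene_ids, "cluster": self.cluster_labels})

    def members(self, label: str) -> list[str]:
        return [g for g, lab in zip(self.gene_ids, self.cluster_labels) if lab == label]


@dataclass
class PCAResult:
    """PCA of samples over gene variables.

    scores: samples x components; loadings: genes x components with
    unit-norm columns; variance_fraction sums to 1 over all components.
    Sign convention: the largest-magnitude loading of each component is
    positive.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def select_top_variable(matrix: ExpressionMatrix, n: int) -> ExpressionMatrix:
    """Top-``n`` genes by standard deviation (ddof=1) across samples.

    Rows are returned sorted by SD descending; ties keep input order.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > matrix.n_genes:
        raise ValueError(f"n={n} exceeds gene count {matrix.n_genes}")
    sds = matrix.values.std(axis=1, ddof=1)
    order = np.argsort(-sds, kind="stable")[:n]
    return matrix.with_data(matrix.data.iloc[order])


def _correlation_distance(items: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson r between rows; zero-variance rows -> r = 0."""
    sds = items.std(axis=1, ddof=1)
    degenerate = sds == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance item(s): correlations set to 0",
            stacklevel=3,
        )
    centered = items - items.mean(axis=1, keepdims=True)
    safe_sd = np.where(degenerate, 1.0, sds)
    standardized = centered / safe_sd[:, None]
    n = items.shape[1]
    corr = standardized @ standardized.T / (n - 1)
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return dist


def hierarchical_cluster(
    matrix: ExpressionMatrix,
    axis: str = "samples",
    metric: str = "correlation",
    method: str = "average",
) -> np.ndarray:
    """Average-linkage clustering with 1 - Pearson correlation distance.

    Gene rows are centered before distances are computed. Returns the
    scipy linkage matrix (merge list + heights); convert with
    :func:`dendrogram_to_newick` for export. Items are genes or samples
    depending on ``axis``.
    """
    if axis not in ("genes", "samples"):
        raise ValueError("axis must be 'genes' or 'samples'")
    centered = matrix.values - matrix.values.mean(axis=1, keepdims=True)
    items = centered if axis == "genes" else centered.T
    if items.shape[0] < 2:
        raise ValueError(f"need >= 2 {axis} to cluster")
    if metric == "correlation":
        dist = _correlation_distance(items)
        condensed = squareform(dist, checks=False)
    elif metric == "euclidean":
        from scipy.spatial.distance import pdist

        condensed = pdist(items)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return hierarchy.linkage(condensed, method=method)


def dendrogram_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def correlation_matrix(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Samples x samples Pearson correlation; constant samples give NaN."""
    if matrix.n_genes < 2:
        raise ValueError("need >= 2 genes")
    return matrix.data.corr(method="pearson")


def kmeans_cluster(
    matrix: ExpressionMatrix,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_k_curve: int = 15,
) -> ClusterAssignment:
    """k-means over row-standardized genes with an elbow (WSS) curve.

    Genes are standardized to mean 0, SD 1 across samples (constant genes
    are centered only). The WSS curve covers k = 1..max(max_k_curve, k);
    clusters are relabeled A, B, ... by descending size.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > matrix.n_genes:
        raise ValueError(f"k={k} exceeds number of genes {matrix.n_genes}")
    values = matrix.values
    sds = values.std(axis=1, ddof=1)
    centered = values - values.mean(axis=1, keepdims=True)
    standardized = centered / np.where(sds == 0, 1.0, sds)[:, None]

    wss_curve: list[tuple[int, float]] = []
    labels_for_k: np.ndarray | None = None
    for kk in range(1, max(max_k_curve, k) + 1):
        if kk > matrix.n_genes:
            break
        km = KMeans(n_clusters=kk, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(standardized)
        wss_curve.append((kk, float(km.inertia_)))
        if kk == k:
            labels_for_k = labels
    assert labels_for_k is not None
    # relabel by descending cluster size, ties by original label id
    sizes = pd.Series(labels_for_k).value_counts().sort_values(ascending=False)
    ordered = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    letters = _cluster_letters(len(ordered))
    rename = {orig: letters[i] for i, orig in enumerate(ordered)}
    return ClusterAssignment(
        gene_ids=matrix.gene_ids,
        cluster_labels=[rename[c] for c in labels_for_k],
        k=k,
        wss_curve=wss_curve,
    )


def _cluster_letters(n: int) -> list[str]:
    alphabet = string.ascii_uppercase
    out = []
    for i in range(n):
        label = ""
        j = i
        while True:
            label = alphabet[j % 26] + label
            j = j // 26 - 1
            if j < 0:
                break
        out.append(label)
    return out


def run_pca(matrix: ExpressionMatrix) -> PCAResult:
    """PCA with samples as observations and genes as variables.

    Gene-wise centering; components come from the SVD of the centered
    samples x genes matrix. Loadings are unit length per component with
    the largest-magnitude loading positive; scores carry the variance.
    """
    if matrix.n_samples < 2:
        raise ValueError("need >= 2 samples for PCA")
    X = matrix.values.T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    n_comp = min(matrix.n_samples - 1, matrix.n_genes)
    U, S, Vt = U[:, :n_comp], S[:n_comp], Vt[:n_comp]
    # sign convention: largest-|loading| entry positive per component
    for c in range(n_comp):
        idx = np.argmax(np.abs(Vt[c]))
        if Vt[c, idx] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    total = (S**2).sum()
    var_frac = (S**2) / total if total > 0 else np.zeros_like(S)
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    scores = pd.DataFrame(U * S, index=matrix.sample_ids, columns=comp_names)
    loadings = pd.DataFrame(Vt.T, index=matrix.gene_ids, columns=comp_names)
    return PCAResult(scores=scores, loadings=loadings, variance_fraction=var_frac)
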