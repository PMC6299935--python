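"""Gene-set enrichment by the hypergeometric test, plus redundancy summaries.

Gene sets arrive in GMT format. For a query list (e.g. upregulated DEGs)
against a background universe, each set's overlap is scored with the
hypergeometric upper tail P(X >= k) and Benjamini-Hochberg FDR across the
collection. Because ontology terms are heavily redundant (``cell cycle``
vs ``cell cycle process``), enriched terms are additionally summarized by
the fraction of shared query genes: an average-linkage tree and a network
whose edges connect terms whose overlap coefficient clears a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "hypergeometric_enrich",
    "term_overlap_distance",
    "build_term_summary",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with a size window used at test time.

    Sets outside ``[size_min, size_max]`` members (after intersection with
    the background) are not tested; defaults 15-2000.
    """

    sets: dict[str, list[str]]
    category: str = ""
    size_min: int = 15
    size_max: int = 2000

    def __post_init__(self) -> None:
        deduped = {}
        for name, members in self.sets.items():
            seen: dict[str, None] = dict.fromkeys(members)
            deduped[name] = list(seen)
        self.sets = deduped

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out.update(members)
        return out

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, category: str = "", size_min: int = 15, size_max: int = 2000) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, member genes.

    Duplicate members within a set are stored once; empty sets are dropped
    with a warning; a line without a description/member field is an error
    reported with its line number.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 2 tab-separated fields, got {len(fields)}"
                )
            name = fields[0].strip()
            members = [f.strip() for f in fields[2:] if f.strip()]
            if not members:
                warnings.warn(f"{path}:{lineno}: empty set {name!r} dropped", stacklevel=2)
                continue
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
    return GeneSetCollection(sets, category=category or path.stem, size_min=size_min, size_max=size_max)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, collection.category or "na", *members]) + "\n")


def hypergeometric_enrich(
    query: list[str],
    collection: GeneSetCollection,
    background: list[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    For a set with K genes in the background universe of size N and a
    query of n background genes, the overlap k is scored with the upper
    tail p = P(X >= k), X ~ Hypergeom(N, K, n). BH FDR is computed across
    all tested sets of the collection. Rows sorted by fdr, then p, then
    set name.

    Returns a DataFrame with columns set_name, k, K, n, N, p_value, fdr,
    overlap_genes.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    q = set(query) & bg
    if not q:
        raise ValueError("query is empty after intersection with background")
    N, n = len(bg), len(q)
    rows = []
    for name, members in collection.sets.items():
        eff = set(members) & bg
        K = len(eff)
        if not collection.size_min <= K <= collection.size_max:
            continue
        overlap = sorted(eff & q)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, p, overlap))
    if not rows:
        return pd.DataFrame(
            columns=["set_name", "k", "K", "n", "N", "p_value", "fdr", "overlap_genes"]
        )
    df = pd.DataFrame(
        rows, columns=["set_name", "k", "K", "n", "N", "p_value", "overlap_genes"]
    )
    df["fdr"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    df = df.sort_values(["fdr", "p_value", "set_name"], kind="stable").reset_index(drop=True)
    return df[["set_name", "k", "K", "n", "N", "p_value", "fdr", "overlap_genes"]]


def term_overlap_distance(
    members_a: list[str], members_b: list[str], method: str = "overlap"
) -> float:
    """Distance between two terms from the fraction of shared genes.

    ``overlap``: 1 - |A&B| / min(|A|, |B|) (overlap-coefficient
    complement, the default); ``jaccard``: 1 - |A&B| / |A|B| union size.
    Member lists should already be restricted to the query list.
    """
    a, b = set(members_a), set(members_b)
    if not a or not b:
        raise ValueError("restricted member lists must be non-empty")
    inter = len(a & b)
    if method == "overlap":
        return 1.0 - inter / min(len(a), len(b))
    if method == "jaccard":
        return 1.0 - inter / len(a | b)
    raise ValueError(f"unknown method {method!r}")


def build_term_summary(
    enriched: pd.DataFrame,
    query: list[str],
    edge_threshold: float = 0.5,
    method: str = "overlap",
) -> dict:
    """Summarize enriched terms by gene-overlap similarity.

    Builds an average-linkage clustering tree on pairwise
    :func:`term_overlap_distance` (computed on set members restricted to
    the query list) and a network whose nodes are the enriched terms
    (annotated with -log10 FDR and overlap count k) with an undirected
    edge wherever the overlap coefficient reaches ``edge_threshold``.

    Returns ``{"newick": str | None, "linkage": ndarray | None,
    "nodes": DataFrame, "edges": DataFrame}``.
    """
    from depath.eda import dendrogram_to_newick

    if not 0 < edge_threshold < 1:
        raise ValueError("edge_threshold must be in (0, 1)")
    qset = set(query)
    terms = list(enriched["set_name"])
    restricted = {
        row.set_name: sorted(set(row.overlap_genes) & qset)
        for row in enriched.itertuples()
    }
    empty = [t for t, m in restricted.items() if not m]
    if empty:
        raise ValueError(f"terms with no query genes cannot be summarized: {empty[:3]}")
    nodes = pd.DataFrame(
        {
            "set_name": terms,
            "k": enriched["k"].to_numpy(),
            "neg_log10_fdr": -np.log10(np.maximum(enriched["fdr"].to_numpy(), 1e-300)),
        }
    )
    edges_rows = []
    n = len(terms)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = term_overlap_distance(restricted[terms[i]], restricted[terms[j]], method)
            dist[i, j] = dist[j, i] = d
            if 1.0 - d >= edge_threshold:
                edges_rows.append((terms[i], terms[j], 1.0 - d))
    edges = pd.DataFrame(edges_rows, columns=["source", "target", "similarity"])
    if n < 2:
        return {"newick": None, "linkage": None, "nodes": nodes, "edges": edges}
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    newick = dendrogram_to_newick(linkage, terms)
    return {"newick": newick, "linkage": linkage, "nodes": nodes, "edges": edges}
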