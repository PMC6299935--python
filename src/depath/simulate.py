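"""Synthetic data generators for every pipeline stage.

Everything the pipeline consumes can be generated offline: negative-
binomial count matrices with planted differentially expressed genes and a
group design, GMT gene-set collections with planted enriched sets,
promoter FASTA with planted motif occurrences, and mock two-species ID
mapping tables. All generators are seed-deterministic: the same spec and
seed reproduce byte-identical files.

Counts follow the mean/dispersion negative-binomial parameterization used
for RNA-seq (variance = mu + dispersion * mu^2); gene means are
log-normal, matching the right-skewed expression distributions of real
libraries. Defaults (dispersion 0.1, 5 samples/group, 5% DE genes at 2
log2 units) reflect a typical well-powered bulk experiment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from depath.enrich import GeneSetCollection
from depath.idmap import IDMappingTable, MappingRecord, normalize_id
from depath.matrix_io import DesignTable, ExpressionMatrix

__all__ = [
    "SimulationSpec",
    "simulate_counts",
    "simulate_genesets",
    "simulate_promoters",
    "simulate_mapping",
]


@dataclass
class SimulationSpec:
    """Parameters of the count simulator.

    nb_dispersion is the extra-Poisson dispersion alpha in
    var = mu + alpha * mu^2; mean_log_mu / sd_log_mu parameterize the
    natural-log-normal distribution of true gene means; de_fraction of
    genes receive a +-effect_log2fc shift in every non-reference group.
    """

    n_genes: int = 2000
    n_samples_per_group: int = 5
    n_groups: int = 2
    nb_dispersion: float = 0.1
    mean_log_mu: float = 4.0
    sd_log_mu: float = 1.5
    de_fraction: float = 0.05
    effect_log2fc: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction in [0, 1]")
        if self.n_groups < 2 or self.n_samples_per_group < 2:
            raise ValueError("need >= 2 groups and >= 2 samples per group")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean mu, var mu + dispersion*mu^2) via gamma-Poisson mixture."""
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_counts(
    spec: SimulationSpec,
) -> tuple[ExpressionMatrix, DesignTable, pd.DataFrame]:
    """Simulate an NB count matrix, its design, and the DE truth table.

    The first ``round(n_genes * de_fraction)`` genes are differentially
    expressed: their mean is multiplied by 2**(+-effect_log2fc) in every
    group except the first (reference) group, with the sign drawn once
    per gene. The truth table lists gene_id, is_de, direction and
    true_log2fc.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"gene{i:05d}" for i in range(spec.n_genes)]
    base_mu = rng.lognormal(spec.mean_log_mu, spec.sd_log_mu, size=spec.n_genes)
    n_de = int(round(spec.n_genes * spec.de_fraction))
    signs = np.zeros(spec.n_genes)
    if n_de:
        signs[:n_de] = rng.choice([-1.0, 1.0], size=n_de)
    true_log2fc = signs * spec.effect_log2fc

    columns = {}
    sample_ids, group_labels = [], []
    for g in range(spec.n_groups):
        group = f"g{g + 1}"
        mu = base_mu if g == 0 else base_mu * 2.0**true_log2fc
        for r in range(spec.n_samples_per_group):
            sid = f"{group}_s{r + 1}"
            columns[sid] = _nb_draw(rng, mu, spec.nb_dispersion)
            sample_ids.append(sid)
            group_labels.append(group)
    data = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"), dtype=float)
    matrix = ExpressionMatrix(data, "counts")
    design = DesignTable(
        pd.DataFrame({"group": group_labels}, index=pd.Index(sample_ids, name="sample")),
        reference_levels={"group": "g1"},
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_de": signs != 0,
            "direction": np.where(signs > 0, "up", np.where(signs < 0, "down", "ns")),
            "true_log2fc": true_log2fc,
        }
    )
    return matrix, design, truth


def simulate_genesets(
    n_sets: int,
    set_size_range: tuple[int, int],
    universe: list[str],
    planted: dict[str, list[str]] | None = None,
    seed: int = 0,
    category: str = "synthetic",
    size_min: int = 15,
    size_max: int = 2000,
) -> GeneSetCollection:
    """Random gene sets over ``universe`` plus verbatim planted sets."""
    rng = np.random.default_rng(seed)
    lo, hi = set_size_range
    if not 0 < lo <= hi <= len(universe):
        raise ValueError("set sizes must satisfy 0 < lo <= hi <= |universe|")
    universe_set = set(universe)
    sets: dict[str, list[str]] = {}
    for name, members in (planted or {}).items():
        outside = set(members) - universe_set
        if outside:
            raise ValueError(f"planted set {name!r} has genes outside universe: {sorted(outside)[:3]}")
        sets[name] = list(members)
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = list(rng.choice(universe, size=size, replace=False))
        sets[f"random_set_{i:04d}"] = members
    return GeneSetCollection(sets, category=category, size_min=size_min, size_max=size_max)


def simulate_promoters(
    n: int,
    length: int = 300,
    planted_motif: str | None = None,
    planted_ids: list[str] | None = None,
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> dict[str, str]:
    """i.i.d. uniform-ACGT promoters; planted ids get one motif occurrence.

    ``planted_motif`` is a consensus string inserted at a random offset on
    a random strand of each planted promoter. Returns gene id -> sequence;
    write with :func:`write_fasta`.
    """
    if length not in (300, 600):
        raise ValueError("promoter length must be 300 or 600")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"gene{i:05d}" for i in range(n)]
    if len(gene_ids) != n:
        raise ValueError("gene_ids length must equal n")
    planted_set = set(planted_ids or [])
    unknown = planted_set - set(gene_ids)
    if unknown:
        raise ValueError(f"planted ids not among promoters: {sorted(unknown)[:3]}")
    if planted_motif is not None and len(planted_motif) >= length:
        raise ValueError("consensus length must be < promoter length")
    bases = np.array(list("ACGT"))
    out: dict[str, str] = {}
    for gid in gene_ids:
        seq = "".join(rng.choice(bases, size=length))
        if gid in planted_set and planted_motif:
            motif = planted_motif.upper()
            if rng.random() < 0.5:
                from depath.motif import reverse_complement

                motif = reverse_complement(motif)
            offset = int(rng.integers(0, length - len(motif) + 1))
            seq = seq[:offset] + motif + seq[offset + len(motif):]
        out[gid] = seq
    return out


def write_fasta(promoters: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid, seq in promoters.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def simulate_mapping(
    species_list: list[str],
    ids_per_species: int = 50,
    overlap_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[IDMappingTable, dict[str, list[str]]]:
    """Mock mapping table; the first species strictly dominates its query.

    Each species gets ``ids_per_species`` source ids (``{sp}_src{i}``)
    mapping to canonical ids ``{sp}_ENS{i}``; a fraction of every other
    species' source ids is shared with the first species so detection has
    to count matches rather than look for exclusivity. Returns the table
    and a dict of per-species source-id lists (the first species' list is
    the designated query that it strictly dominates).
    """
    if not species_list:
        raise ValueError("need >= 1 species")
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction in [0, 1)")
    rng = np.random.default_rng(seed)
    records: list[MappingRecord] = []
    source_ids: dict[str, list[str]] = {}
    dominant = species_list[0]
    for sp in species_list:
        ids = [f"{sp}_src{i:04d}" for i in range(ids_per_species)]
        if sp != dominant and overlap_fraction > 0:
            n_shared = int(overlap_fraction * ids_per_species)
            shared = rng.choice(source_ids[dominant], size=n_shared, replace=False)
            ids[:n_shared] = list(shared)
        source_ids[sp] = ids
        for i, sid in enumerate(ids):
            records.append(
                MappingRecord(sid, f"{sp}_ENS{i:06d}", sp, "symbol", normalize_id(sid))
            )
    return IDMappingTable(records), source_ids


def write_mapping_table(table: IDMappingTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source_id\tcanonical_id\tspecies\tid_type\n")
        for rec in table.records:
            fh.write(f"{rec.source_id}\t{rec.canonical_id}\t{rec.species}\t{rec.id_type}\n")
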