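"""Gene-ID conversion and species detection.

Uploaded expression matrices carry gene identifiers in many namespaces
(symbols, Entrez, RefSeq, array probe ids...). Given a user-supplied
mapping table (source_id, canonical_id, species, id_type), this module
guesses the most likely species by counting how many query ids each
species' mapping covers, and converts matrix row ids to the canonical
(Ensembl-style) namespace. Matching is case-insensitive and tolerant of
trailing version suffixes (``ENSG00000141510.11`` matches
``ensg00000141510``); both behaviors are configurable.

Rows that end up sharing a canonical id after conversion are collapsed by
keeping the row with the largest standard deviation across samples.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

from depath.matrix_io import ExpressionMatrix, collapse_duplicate_ids

__all__ = [
    "IDMappingTable",
    "MappingRecord",
    "ConversionReport",
    "load_mapping_table",
    "detect_species",
    "convert_ids",
    "normalize_id",
]

_VERSION_RE = re.compile(r"\.\d+$")


def normalize_id(raw: str, case_insensitive: bool = True, strip_version: bool = True) -> str:
    """Normalized lookup key for a gene id."""
    key = raw.strip()
    if strip_version:
        key = _VERSION_RE.sub("", key)
    if case_insensitive:
        key = key.lower()
    return key


class MappingRecord(NamedTuple):
    source_id: str
    canonical_id: str
    species: str
    id_type: str
    key: str  # normalized source id


@dataclass
class IDMappingTable:
    """Source-id -> canonical-id records across one or more species."""

    records: list[MappingRecord]

    def __post_init__(self) -> None:
        seen = set()
        deduped = []
        for rec in self.records:
            ident = (rec.key, rec.canonical_id, rec.species, rec.id_type)
            if ident not in seen:
                seen.add(ident)
                deduped.append(rec)
        self.records = deduped

    @property
    def species(self) -> list[str]:
        return sorted({r.species for r in self.records})

    def keys_for_species(self, species: str) -> set[str]:
        return {r.key for r in self.records if r.species == species}

    def lookup(self, species: str) -> dict[str, str]:
        """Normalized key -> canonical id for one species.

        A key mapping to several canonical ids resolves to the
        alphabetically first (deterministic one-to-many rule).
        """
        table: dict[str, str] = {}
        for r in self.records:
            if r.species != species:
                continue
            if r.key not in table or r.canonical_id < table[r.key]:
                table[r.key] = r.canonical_id
        return table


def load_mapping_table(
    path: str | Path, case_insensitive: bool = True, strip_version: bool = True
) -> IDMappingTable:
    """Load a TSV mapping table: source_id, canonical_id, species[, id_type].

    An optional header line (first field literally ``source_id``) is
    skipped. Malformed lines are reported with their line number.
    """
    path = Path(path)
    records: list[MappingRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].strip().lower() == "source_id":
                continue
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields "
                    f"(source_id, canonical_id, species), got {len(fields)}"
                )
            source, canonical, species = (f.strip() for f in fields[:3])
            id_type = fields[3].strip() if len(fields) > 3 else ""
            if not source or not canonical or not species:
                raise ValueError(f"{path}:{lineno}: empty field")
            records.append(
                MappingRecord(
                    source,
                    canonical,
                    species,
                    id_type,
                    normalize_id(source, case_insensitive, strip_version),
                )
            )
    return IDMappingTable(records)


def detect_species(
    query_ids: list[str],
    table: IDMappingTable,
    case_insensitive: bool = True,
    strip_version: bool = True,
) -> tuple[list[tuple[str, int]], bool]:
    """Rank candidate species by the number of matched query ids.

    Returns ``(ranking, warning)`` where ranking is a list of
    ``(species, matched_count)`` sorted by count descending then species
    name, and ``warning`` is True when no species matches any id.
    """
    if not query_ids:
        raise ValueError("empty query")
    keys = {normalize_id(q, case_insensitive, strip_version) for q in query_ids}
    ranking = []
    for sp in table.species:
        matched = len(keys & table.keys_for_species(sp))
        ranking.append((sp, matched))
    ranking.sort(key=lambda t: (-t[1], t[0]))
    warning = all(count == 0 for _, count in ranking)
    return ranking, warning


@dataclass
class ConversionReport:
    species: str
    n_input: int
    n_matched: int
    n_unmatched: int
    n_collapsed: int  # rows lost to duplicate-canonical collapsing
    kept_unmatched: bool


def convert_ids(
    matrix: ExpressionMatrix,
    table: IDMappingTable,
    species: str,
    keep_unmatched: bool = True,
    case_insensitive: bool = True,
    strip_version: bool = True,
) -> tuple[ExpressionMatrix, ConversionReport]:
    """Convert matrix row ids to the canonical namespace of ``species``.

    Unmatched rows keep their original ids (``keep_unmatched=True``) or are
    dropped. Rows sharing a canonical id after conversion are collapsed to
    the max-SD row. Never increases the row count.
    """
    if species not in table.species:
        raise KeyError(f"species {species!r} not in mapping table {table.species}")
    lookup = table.lookup(species)
    targets: list[tuple[int, str]] = []
    n_matched = 0
    kept_rows: list[int] = []
    for i, gid in enumerate(matrix.gene_ids):
        canonical = lookup.get(normalize_id(gid, case_insensitive, strip_version))
        if canonical is not None:
            n_matched += 1
            kept_rows.append(i)
            targets.append((i, canonical))
        elif keep_unmatched:
            kept_rows.append(i)
            targets.append((i, gid))
    n_unmatched = matrix.n_genes - n_matched
    if not kept_rows:
        raise ValueError("no rows left after conversion (all unmatched and dropped)")
    sub = matrix.data.iloc[kept_rows]
    sub_matrix = ExpressionMatrix(sub, matrix.scale_kind, allow_duplicate_ids=True)
    remapped = [(new_i, t) for new_i, (_, t) in enumerate(targets)]
    collapsed = collapse_duplicate_ids(sub_matrix, remapped)
    report = ConversionReport(
        species=species,
        n_input=matrix.n_genes,
        n_matched=n_matched,
        n_unmatched=n_unmatched,
        n_collapsed=len(kept_rows) - collapsed.n_genes,
        kept_unmatched=keep_unmatched,
    )
    return collapsed, report
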