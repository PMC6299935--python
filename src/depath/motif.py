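"""Promoter PWM scanning and best-score motif enrichment.

Rather than calling binding sites at an arbitrary score cutoff, every
promoter is scanned with each position weight matrix (PWM) over both
strands and all offsets, and only the best log2-odds score is kept. Motif
enrichment in a gene list is then a Welch t-test comparing best scores of
the listed promoters against all remaining promoters, with BH-FDR across
motifs — a cutoff-free alternative to overlap-based TF-target enrichment
that works for any species with promoter sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["PWM", "read_pwms", "scan_best_scores", "motif_ttest_enrich"]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class PWM:
    """Position weight matrix: length-L x 4 base probabilities (A,C,G,T).

    Probabilities are re-normalized per position after adding
    ``pseudocount`` to every cell, so raw count matrices can be passed
    directly.
    """

    name: str
    matrix: np.ndarray
    tf_name: str = ""
    family: str = ""
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"PWM {self.name!r}: matrix must be L x 4 (A,C,G,T)")
        if self.matrix.shape[0] < 4:
            raise ValueError(f"PWM {self.name!r}: length must be >= 4")
        if (self.matrix < 0).any():
            raise ValueError(f"PWM {self.name!r}: negative entries")
        rowsum = self.matrix.sum(axis=1)
        if (rowsum == 0).any():
            raise ValueError(f"PWM {self.name!r}: zero row sum")
        padded = self.matrix + self.pseudocount
        self.matrix = padded / padded.sum(axis=1, keepdims=True)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    def log_odds(self, background: np.ndarray) -> np.ndarray:
        """L x 5 log2-odds score matrix; column 5 (N) scores 0."""
        lo = np.log2(self.matrix / background[None, :])
        return np.hstack([lo, np.zeros((self.length, 1))])


def _parse_meme(text: str, path: Path, pseudocount: float) -> list[PWM]:
    pwms: list[PWM] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            name = parts[1] if len(parts) > 1 else f"motif{len(pwms) + 1}"
            tf = parts[2] if len(parts) > 2 else ""
            # advance to the letter-probability header
            j = i + 1
            width = None
            while j < len(lines) and not lines[j].strip().lower().startswith(
                "letter-probability matrix"
            ):
                if lines[j].strip().startswith("MOTIF"):
                    raise ValueError(f"{path}: motif {name!r} has no probability matrix")
                j += 1
            if j >= len(lines):
                raise ValueError(f"{path}: motif {name!r} has no probability matrix")
            header = lines[j]
            if "w=" in header:
                width = int(header.split("w=")[1].split()[0])
            rows = []
            j += 1
            while j < len(lines):
                stripped = lines[j].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL")):
                    break
                rows.append([float(x) for x in stripped.split()])
                j += 1
            if width is not None and len(rows) != width:
                raise ValueError(
                    f"{path}: motif {name!r} declares w={width} but has {len(rows)} rows"
                )
            pwms.append(PWM(name, np.array(rows), tf_name=tf, pseudocount=pseudocount))
            i = j
        else:
            i += 1
    if not pwms:
        raise ValueError(f"{path}: no MOTIF blocks found")
    return pwms


def _parse_count_blocks(text: str, path: Path, pseudocount: float) -> list[PWM]:
    """4-row count matrices: '>name[ tf[ family]]' then rows A, C, G, T."""
    pwms: list[PWM] = []
    block_header: list[str] | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal rows, block_header
        if block_header is None:
            return
        if len(rows) != 4:
            raise ValueError(
                f"{path}: matrix {block_header[0]!r} has {len(rows)} rows, expected 4 (A,C,G,T)"
            )
        name = block_header[0]
        tf = block_header[1] if len(block_header) > 1 else ""
        family = block_header[2] if len(block_header) > 2 else ""
        pwms.append(
            PWM(name, np.array(rows).T, tf_name=tf, family=family, pseudocount=pseudocount)
        )
        rows = []
        block_header = None

    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            flush()
            block_header = stripped[1:].split("\t") if "\t" in stripped else stripped[1:].split()
        else:
            if block_header is None:
                raise ValueError(f"{path}:{lineno}: matrix rows before any '>' header")
            try:
                rows.append([float(x) for x in stripped.replace(",", " ").split()])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric matrix entry") from exc
    flush()
    if not pwms:
        raise ValueError(f"{path}: no PWM blocks found")
    return pwms


def read_pwms(path: str | Path, pseudocount: float = 0.01) -> list[PWM]:
    """Read PWMs from MEME-minimal text or '>'-headed 4-row count matrices.

    Counts (or probabilities) are converted to per-position probabilities
    after adding ``pseudocount`` to every cell.
    """
    path = Path(path)
    text = path.read_text()
    if "MEME version" in text or "MOTIF" in text:
        return _parse_meme(text, path, pseudocount)
    return _parse_count_blocks(text, path, pseudocount)


def _encode(sequence: str) -> np.ndarray:
    """A,C,G,T -> 0..3; N (or any other IUPAC code) -> 4."""
    seq = sequence.upper()
    out = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return out


def reverse_complement(sequence: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(sequence.upper()))


def pooled_background(sequences: list[str]) -> np.ndarray:
    """Strand-symmetric 0-order base frequencies pooled over all sequences.

    Complementary bases are averaged (A with T, C with G) so scores are
    invariant to which strand a promoter was reported on; N is excluded.
    """
    counts = np.zeros(4)
    for seq in sequences:
        enc = _encode(seq)
        for i in range(4):
            counts[i] += int((enc == i).sum())
    if counts.sum() == 0:
        return np.full(4, 0.25)
    freq = counts / counts.sum()
    a, c, g, t = freq
    freq = np.array([(a + t) / 2, (c + g) / 2, (c + g) / 2, (a + t) / 2])
    return np.clip(freq, 1e-6, None) / np.clip(freq, 1e-6, None).sum()


def _best_score(encoded: np.ndarray, score_matrix: np.ndarray) -> float:
    """Max sum of per-position scores over all offsets of one strand."""
    L = score_matrix.shape[0]
    n = encoded.size
    if n < L:
        return -np.inf
    # windows[o, j] = encoded[o + j]
    windows = np.lib.stride_tricks.sliding_window_view(encoded, L)
    scores = score_matrix[np.arange(L)[None, :], windows].sum(axis=1)
    return float(scores.max())


def scan_best_scores(
    promoters: dict[str, str] | str | Path,
    pwms: list[PWM],
    background: np.ndarray | None = None,
) -> pd.DataFrame:
    """Best log2-odds score of every PWM in every promoter.

    ``promoters`` maps gene id -> sequence, or is a FASTA path (record id
    = gene id). Scores are maximized over both strands and all offsets; N
    positions contribute 0. The background defaults to the pooled base
    composition of the supplied promoters. Promoters shorter than a motif
    get NaN for it.

    Returns a promoters x motifs DataFrame.
    """
    if not isinstance(promoters, dict):
        records = SeqIO.parse(str(promoters), "fasta")
        promoters = {rec.id: str(rec.seq) for rec in records}
    if not promoters:
        raise ValueError("no promoter sequences")
    if background is None:
        background = pooled_background(list(promoters.values()))
    background = np.asarray(background, dtype=float)
    if not np.isclose(background.sum(), 1.0):
        raise ValueError("background frequencies must sum to 1")
    encoded = {gid: _encode(seq) for gid, seq in promoters.items()}
    encoded_rc = {gid: _encode(reverse_complement(seq)) for gid, seq in promoters.items()}
    out = np.full((len(promoters), len(pwms)), np.nan)
    gene_ids = list(promoters)
    for j, pwm in enumerate(pwms):
        sm = pwm.log_odds(background)
        for i, gid in enumerate(gene_ids):
            fwd = _best_score(encoded[gid], sm)
            rev = _best_score(encoded_rc[gid], sm)
            best = max(fwd, rev)
            out[i, j] = best if np.isfinite(best) else np.nan
    return pd.DataFrame(out, index=gene_ids, columns=[p.name for p in pwms])


def motif_ttest_enrich(
    scores: pd.DataFrame,
    query: list[str],
    pwms: list[PWM] | None = None,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Per-motif Welch t-test of best scores, query promoters vs the rest.

    One-sided by default (enrichment = higher binding scores in the
    list); BH FDR across motifs. Output columns mirror a motif-enrichment
    report: motif, tf, family, t, p_value, fdr, sorted by fdr then p.
    """
    qset = set(query)
    in_query = scores.index.isin(qset)
    if in_query.sum() < 3 or (~in_query).sum() < 3:
        raise ValueError("need >= 3 promoters in both the query and the complement")
    meta = {p.name: (p.tf_name, p.family) for p in pwms} if pwms else {}
    rows = []
    for motif in scores.columns:
        col = scores[motif]
        a = col[in_query].dropna().to_numpy()
        b = col[~in_query].dropna().to_numpy()
        if len(a) < 3 or len(b) < 3:
            continue
        if np.allclose(a, a.mean()) and np.allclose(b, a.mean()):
            t, p = 0.0, 0.5 if alternative == "greater" else 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
        tf, family = meta.get(motif, ("", ""))
        rows.append((motif, tf, family, float(t), float(p)))
    df = pd.DataFrame(rows, columns=["motif", "tf", "family", "t", "p_value"])
    df["fdr"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return df.sort_values(["fdr", "p_value", "motif"], kind="stable").reset_index(drop=True)
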