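"""Progressive multiple sequence alignment.

A self-contained Clustal-style progressive aligner: pairwise global
alignments give fractional-identity distances, a UPGMA guide tree orders the
merges, and profiles are merged by affine-gap (Gotoh) dynamic programming on
sum-of-pairs BLOSUM62 column scores.  Deterministic for a fixed input order;
adequate for the small (<= a few dozen sequences, ~100 residues) nsLTP
families this package targets — it makes no claim to Clustal Omega's HMM
machinery, so conserved-residue counts derived from it are engine-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .homology import AlignmentParams, pairwise_align, percent_identity
from .residues import AMINO_ACIDS, GAP
from .seq_io import SequenceRecord


@dataclass(frozen=True)
class MultipleAlignment:
    """An MSA: per-row id and gapped residue string, all rows equal length."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate row ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"no row with id {seq_id!r}") from None

    def column(self, index: int) -> str:
        return "".join(r[index] for r in self.rows)

    def degapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def reorder(self, ids: Sequence[str]) -> "MultipleAlignment":
        return MultipleAlignment(tuple(ids), tuple(self.row(i) for i in ids))


_ALPHA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def _column_counts(rows: Sequence[str]) -> np.ndarray:
    """(n_cols, 20) residue count matrix; gaps contribute nothing."""
    n_cols = len(rows[0])
    counts = np.zeros((n_cols, 20))
    for row in rows:
        for j, ch in enumerate(row):
            if ch != GAP:
                counts[j, _ALPHA_INDEX[ch]] += 1
    return counts


def _profile_align(
    rows_a: Sequence[str],
    rows_b: Sequence[str],
    matrix: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> tuple[list[str], list[str]]:
    """Affine-gap global alignment of two profiles (Gotoh three-state DP).

    Column score is the average BLOSUM score over all residue pairs between
    the two columns (gap characters score 0).  New gap columns cost
    ``gap_open`` for the first column of a run and ``gap_extend`` thereafter.
    Tie-break: diagonal > gap-in-B > gap-in-A, which keeps the result
    deterministic.
    """
    ca = _column_counts(rows_a)
    cb = _column_counts(rows_b)
    na_cols, nb_cols = ca.shape[0], cb.shape[0]
    weight = 1.0 / (len(rows_a) * len(rows_b))
    score = (ca @ matrix @ cb.T) * weight  # (na_cols, nb_cols)

    neg = -np.inf
    m = np.full((na_cols + 1, nb_cols + 1), neg)  # diagonal state
    ga = np.full_like(m, neg)  # gap in profile A (consume B column)
    gb = np.full_like(m, neg)  # gap in profile B (consume A column)
    m[0, 0] = 0.0
    for i in range(1, na_cols + 1):
        gb[i, 0] = -gap_open - gap_extend * (i - 1)
    for j in range(1, nb_cols + 1):
        ga[0, j] = -gap_open - gap_extend * (j - 1)
    ptr_m = np.zeros((na_cols + 1, nb_cols + 1), dtype=np.int8)
    ptr_ga = np.zeros_like(ptr_m)
    ptr_gb = np.zeros_like(ptr_m)
    for i in range(1, na_cols + 1):
        for j in range(1, nb_cols + 1):
            s = score[i - 1, j - 1]
            best_prev = m[i - 1, j - 1]
            ptr = 0
            if gb[i - 1, j - 1] > best_prev:
                best_prev, ptr = gb[i - 1, j - 1], 2
            if ga[i - 1, j - 1] > best_prev:
                best_prev, ptr = ga[i - 1, j - 1], 1
            m[i, j] = best_prev + s
            ptr_m[i, j] = ptr

            open_a = m[i, j - 1] - gap_open
            ext_a = ga[i, j - 1] - gap_extend
            if open_a >= ext_a:
                ga[i, j], ptr_ga[i, j] = open_a, 0
            else:
                ga[i, j], ptr_ga[i, j] = ext_a, 1

            open_b = m[i - 1, j] - gap_open
            ext_b = gb[i - 1, j] - gap_extend
            if open_b >= ext_b:
                gb[i, j], ptr_gb[i, j] = open_b, 0
            else:
                gb[i, j], ptr_gb[i, j] = ext_b, 1

    # traceback from the best end state (prefer M, then GB, then GA)
    i, j = na_cols, nb_cols
    state = max(((m[i, j], 0), (gb[i, j], 2), (ga[i, j], 1)), key=lambda t: t[0])[1]
    take_a: list[int] = []  # -1 marks a gap column inserted into that profile
    take_b: list[int] = []
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            take_a.append(i - 1)
            take_b.append(j - 1)
            state = ptr_m[i, j]
            i, j = i - 1, j - 1
        elif state == 1 and j > 0:  # gap in A
            take_a.append(-1)
            take_b.append(j - 1)
            state = 0 if ptr_ga[i, j] == 0 else 1
            j -= 1
        else:  # state == 2, gap in B
            take_a.append(i - 1)
            take_b.append(-1)
            state = 0 if ptr_gb[i, j] == 0 else 2
            i -= 1
    take_a.reverse()
    take_b.reverse()

    def expand(rows: Sequence[str], take: list[int]) -> list[str]:
        return ["".join(GAP if t < 0 else row[t] for t in take) for row in rows]

    return expand(rows_a, take_a), expand(rows_b, take_b)


def identity_distance_matrix(
    records: Sequence[SequenceRecord], params: AlignmentParams | None = None
) -> np.ndarray:
    """Pairwise 1 - fractional-identity distances from global alignments."""
    params = params or AlignmentParams()
    n = len(records)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = pairwise_align(records[i].residues, records[j].residues, "global", params)
            dist[i, j] = dist[j, i] = 1.0 - percent_identity(aln, params.denominator) / 100.0
    return dist


def progressive_msa(
    records: Sequence[SequenceRecord], params: AlignmentParams | None = None
) -> MultipleAlignment:
    """Align >=2 records progressively along a UPGMA guide tree.

    Row order in the result follows the input record order; de-gapping any
    row recovers its input sequence.
    """
    if len(records) < 2:
        raise ValueError("progressive_msa requires at least 2 records")
    if len({r.id for r in records}) != len(records):
        raise ValueError("duplicate record ids")
    params = params or AlignmentParams()
    blosum = substitution_matrices.load(params.matrix)
    matrix = np.array(
        [[blosum[a, b] for b in AMINO_ACIDS] for a in AMINO_ACIDS], dtype=float
    )

    if len(records) == 2:
        merge_order = [(0, 1)]
    else:
        dist = identity_distance_matrix(records, params)
        z = linkage(squareform(dist, checks=False), method="average")
        merge_order = [(int(a), int(b)) for a, b, *_ in z]

    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([r.id], [r.residues]) for i, r in enumerate(records)
    }
    next_idx = len(records)
    for a, b in merge_order:
        ids_a, rows_a = clusters.pop(a)
        ids_b, rows_b = clusters.pop(b)
        new_a, new_b = _profile_align(rows_a, rows_b, matrix, params.gap_open, params.gap_extend)
        clusters[next_idx] = (ids_a + ids_b, new_a + new_b)
        next_idx += 1
    (ids, rows), = clusters.values()
    order = {r.id: i for i, r in enumerate(records)}
    paired = sorted(zip(ids, rows), key=lambda t: order[t[0]])
    return MultipleAlignment(tuple(i for i, _ in paired), tuple(r for _, r in paired))


def read_aligned_fasta(path: str | Path) -> MultipleAlignment:
    """Read an aligned FASTA (rows may contain '-') into a MultipleAlignment."""
    ids: list[str] = []
    rows: list[str] = []
    header: str | None = None
    chunks: list[str] = []
    with open(path, encoding="utf-8") as handle:
        for raw in handle:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    ids.append(header)
                    rows.append("".join(chunks))
                header = line[1:].split(None, 1)[0]
                chunks = []
            else:
                chunks.append("".join(line.split()).upper())
    if header is not None:
        ids.append(header)
        rows.append("".join(chunks))
    return MultipleAlignment(tuple(ids), tuple(rows))


def write_aligned_fasta(msa: MultipleAlignment, path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for seq_id, row in zip(msa.ids, msa.rows):
            handle.write(f">{seq_id}\n")
            for start in range(0, len(row), width):
                handle.write(row[start : start + width] + "\n")
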