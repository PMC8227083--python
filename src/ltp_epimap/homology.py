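"""Dual-mode allergenicity homology screen.

Two search modes are standard in regulatory allergenicity assessment of a
novel food protein:

* **full-length** global alignment of the query against every database
  allergen, reporting percent identity over the whole alignment; and
* the Codex-style **80-amino-acid sliding window**, where every length-80
  query window (step 1) is locally aligned against each allergen and the
  best window per subject is reported.  A window hit >= 35% identity is the
  conventional trigger for further scrutiny; > 70% full-length identity is
  generally read as probable structural (and hence epitope) similarity.

Alignments are computed with Biopython's exact dynamic-programming
``PairwiseAligner``; defaults are BLOSUM62 with affine gap penalties
(open 10, extend 0.5).  Percent identity uses the alignment length
(gap columns included) as denominator, rounded half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .seq_io import SequenceRecord


class SearchMode(str, Enum):
    FULL_LENGTH = "full_length"
    WINDOW80 = "window80"


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for both search modes."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    #: identity denominator: "alignment" (gap columns included) or "shorter"
    denominator: str = "alignment"


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    mode: SearchMode
    identity_pct: float
    aligned_length: int
    query_window: tuple[int, int] | None = field(default=None)

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError(f"identity_pct out of range: {self.identity_pct}")


def _make_aligner(scope: str, params: AlignmentParams) -> Align.PairwiseAligner:
    if scope not in ("global", "local"):
        raise ValueError(f"scope must be 'global' or 'local', got {scope!r}")
    aligner = Align.PairwiseAligner()
    aligner.mode = scope
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def pairwise_align(
    a: str,
    b: str,
    scope: str = "global",
    params: AlignmentParams | None = None,
) -> tuple[str, str]:
    """Optimal pairwise alignment of two residue strings as two gapped strings.

    ``scope="global"`` (Needleman–Wunsch, end gaps penalized) or
    ``scope="local"`` (Smith–Waterman; the returned strings cover only the
    aligned region).  Removing gaps from the output recovers the inputs
    (global) or contiguous substrings of them (local).
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    params = params or AlignmentParams()
    aligner = _make_aligner(scope, params)
    alignment = aligner.align(a, b)[0]
    return _gapped_strings(alignment, a, b)


def _gapped_strings(alignment: Align.Alignment, a: str, b: str) -> tuple[str, str]:
    """Render the aligned region of a Biopython alignment as two gapped strings."""
    blocks = alignment.aligned  # pairs of (a_start,a_end),(b_start,b_end)
    if len(blocks[0]) == 0:  # empty local alignment
        return "", ""
    out_a: list[str] = []
    out_b: list[str] = []
    prev_a = blocks[0][0][0]
    prev_b = blocks[1][0][0]
    for (a_start, a_end), (b_start, b_end) in zip(blocks[0], blocks[1]):
        out_a.append(a[prev_a:a_start] + "-" * (b_start - prev_b))
        out_b.append("-" * (a_start - prev_a) + b[prev_b:b_start])
        out_a.append(a[a_start:a_end])
        out_b.append(b[b_start:b_end])
        prev_a, prev_b = a_end, b_end
    return "".join(out_a), "".join(out_b)


def percent_identity(alignment: tuple[str, str], denominator: str = "alignment") -> float:
    """Percent identity of a gapped alignment, rounded half-up to two decimals.

    Denominator is the full alignment length including gap columns
    (conservative, the convention of Codex-style screening), or the shorter
    ungapped sequence length when ``denominator="shorter"``.
    """
    row_a, row_b = alignment
    if len(row_a) != len(row_b):
        raise ValueError("alignment rows differ in length")
    if not row_a:
        return 0.0
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    if denominator == "alignment":
        denom = len(row_a)
    elif denominator == "shorter":
        denom = min(len(row_a.replace("-", "")), len(row_b.replace("-", "")))
    else:
        raise ValueError(f"unknown denominator rule {denominator!r}")
    return float(
        (Decimal(100 * matches) / Decimal(denom)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def full_length_screen(
    query: SequenceRecord,
    db: Sequence[SequenceRecord],
    params: AlignmentParams | None = None,
) -> list[AlignmentHit]:
    """Global-alignment identity of the query against every database member.

    Returns one hit per subject, sorted by identity descending, then
    subject id ascending.
    """
    params = params or AlignmentParams()
    hits = []
    for subject in db:
        aln = pairwise_align(query.residues, subject.residues, "global", params)
        hits.append(
            AlignmentHit(
                query_id=query.id,
                subject_id=subject.id,
                mode=SearchMode.FULL_LENGTH,
                identity_pct=percent_identity(aln, params.denominator),
                aligned_length=len(aln[0]),
            )
        )
    hits.sort(key=lambda h: (-h.identity_pct, h.subject_id))
    return hits


def sliding_window_screen(
    query: SequenceRecord,
    db: Sequence[SequenceRecord],
    window: int = 80,
    step: int = 1,
    params: AlignmentParams | None = None,
) -> list[AlignmentHit]:
    """Best 80-aa-window local-alignment identity of the query per subject.

    Every length-``window`` query window (step ``step``) is aligned locally
    against the full subject; the window with maximum identity is reported
    (ties: earliest window).  Queries shorter than ``window`` are screened as
    a single degenerate window.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    params = params or AlignmentParams()
    eff_window = min(window, len(query.residues))
    starts = range(0, len(query.residues) - eff_window + 1, step)
    hits = []
    for subject in db:
        best: tuple[float, int, int] | None = None  # identity, start0, aligned_len
        for start in starts:
            fragment = query.residues[start : start + eff_window]
            aln = pairwise_align(fragment, subject.residues, "local", params)
            ident = percent_identity(aln, params.denominator) if aln[0] else 0.0
            if best is None or ident > best[0]:
                best = (ident, start, len(aln[0]))
        assert best is not None
        ident, start, aligned_len = best
        hits.append(
            AlignmentHit(
                query_id=query.id,
                subject_id=subject.id,
                mode=SearchMode.WINDOW80,
                identity_pct=ident,
                aligned_length=aligned_len,
                query_window=(start + 1, start + eff_window),
            )
        )
    hits.sort(key=lambda h: (-h.identity_pct, h.subject_id))
    return hits


def hits_to_frame(hits: Sequence[AlignmentHit]) -> pd.DataFrame:
    """Tabulate hits with columns query_id, subject_id, mode, identity_pct,
    window_start, window_end, aligned_length."""
    rows = [
        {
            "query_id": h.query_id,
            "subject_id": h.subject_id,
            "mode": h.mode.value,
            "identity_pct": h.identity_pct,
            "window_start": h.query_window[0] if h.query_window else pd.NA,
            "window_end": h.query_window[1] if h.query_window else pd.NA,
            "aligned_length": h.aligned_length,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "query_id",
            "subject_id",
            "mode",
            "identity_pct",
            "window_start",
            "window_end",
            "aligned_length",
        ],
    )


def write_hits(hits: Sequence[AlignmentHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)
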