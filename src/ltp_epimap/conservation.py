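"""MSA conservation annotation.

Two complementary per-column annotations are produced from a multiple
alignment:

* Clustal-style symbols — ``*`` for an identical, gap-free column, ``:``
  when all residues fall inside one Gonnet-PAM250 "strong" group, ``.`` for
  a "weak" group, blank otherwise.  Any gap in a column disqualifies all
  three symbols (Clustal convention).
* A per-residue percent conservation score for a chosen reference row:
  score(X) = (number of aligned sequences carrying residue X in that
  column) x 100 / N.  Only exact residue identity counts — gaps and
  similar residues do not — and N is the total number of sequences
  (N = 15 in the allergenic-LTP panel this score was designed around).
  Scores are stored at full precision and floored to whole percent for
  display, so 14/15 prints as 93 and 2/15 as 13.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .msa import MultipleAlignment
from .residues import GAP, in_one_strong_group, in_one_weak_group


@dataclass(frozen=True)
class ResidueConservation:
    """Conservation of one reference residue mapped back to its own numbering."""

    position: int  # 1-based position in the ungapped reference sequence
    residue: str
    column: int  # 0-based MSA column
    symbol: str
    score: float  # exact percent, e.g. 93.333...

    @property
    def score_floor(self) -> int:
        """Display form: percent floored to an integer (93.33 -> 93)."""
        return math.floor(self.score)


@dataclass(frozen=True)
class ConservationProfile:
    reference_id: str
    n_sequences: int
    column_symbols: tuple[str, ...]
    residues: tuple[ResidueConservation, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "position": r.position,
                    "residue": r.residue,
                    "column": r.column,
                    "symbol": r.symbol,
                    "eq1_score": round(r.score, 4),
                    "eq1_score_floor": r.score_floor,
                }
                for r in self.residues
            ]
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def conservation_symbols(msa: MultipleAlignment) -> tuple[str, ...]:
    """Per-column Clustal symbol ('*', ':', '.', ' ')."""
    symbols = []
    for j in range(msa.n_cols):
        column = msa.column(j)
        if GAP in column:
            symbols.append(" ")
            continue
        residues = set(column)
        if len(residues) == 1:
            symbols.append("*")
        elif in_one_strong_group(residues):
            symbols.append(":")
        elif in_one_weak_group(residues):
            symbols.append(".")
        else:
            symbols.append(" ")
    return tuple(symbols)


def eq1_scores(
    msa: MultipleAlignment, reference_id: str, n_total: int | None = None
) -> tuple[ResidueConservation, ...]:
    """Percent conservation of every reference residue across the alignment.

    ``n_total`` defaults to the number of rows; it is exposed because the
    score is conventionally quoted against a fixed panel size (15).
    """
    reference = msa.row(reference_id)  # KeyError if absent
    n = n_total if n_total is not None else msa.n_rows
    if n < 1:
        raise ValueError("n_total must be >= 1")
    symbols = conservation_symbols(msa)
    out = []
    position = 0
    for j, ref_char in enumerate(reference):
        if ref_char == GAP:
            continue
        position += 1
        column = msa.column(j)
        count = sum(1 for ch in column if ch == ref_char)  # gaps never match
        out.append(
            ResidueConservation(
                position=position,
                residue=ref_char,
                column=j,
                symbol=symbols[j],
                score=count * 100.0 / n,
            )
        )
    return tuple(out)


def conservation_profile(
    msa: MultipleAlignment, reference_id: str, n_total: int | None = None
) -> ConservationProfile:
    return ConservationProfile(
        reference_id=reference_id,
        n_sequences=n_total if n_total is not None else msa.n_rows,
        column_symbols=conservation_symbols(msa),
        residues=eq1_scores(msa, reference_id, n_total),
    )


def fully_conserved_count(msa: MultipleAlignment, reference_id: str) -> int:
    """Number of reference residues sitting in '*' (fully conserved) columns."""
    return sum(1 for r in eq1_scores(msa, reference_id) if r.symbol == "*")


def partially_conserved_count(msa: MultipleAlignment, reference_id: str) -> int:
    """Reference residues in ':' columns (one Gonnet strong group, score > 0.5)."""
    return sum(1 for r in eq1_scores(msa, reference_id) if r.symbol == ":")


def distance_matrix(msa: MultipleAlignment) -> np.ndarray:
    """Uncorrected pairwise distances: 1 - fractional identity over columns
    where neither row is gapped.  Raises if a pair shares no comparable column."""
    n = msa.n_rows
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = 0
            same = 0
            for x, y in zip(msa.rows[i], msa.rows[j]):
                if x != GAP and y != GAP:
                    comparable += 1
                    if x == y:
                        same += 1
            if comparable == 0:
                raise ValueError(
                    f"rows {msa.ids[i]!r} and {msa.ids[j]!r} share no gap-free columns"
                )
            dist[i, j] = dist[j, i] = 1.0 - same / comparable
    return dist
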