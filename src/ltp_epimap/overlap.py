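"""Shared-epitope motif analysis: common substrings, triads, validation.

Cross-reactivity between homologous allergens is argued from exact residue
stretches shared between predicted epitope sets — e.g. the TTPDRQ / IPYK
motifs that predicted legume-LTP epitopes share with the experimentally
validated peach (Pru p 3) epitopes.  Matching here is exact identity only;
a motif is reported when it occurs verbatim in an epitope of each member
set, is at least ``min_len`` residues long (default 4, the shortest motif
of interest), and is maximal (not a substring of a longer reported motif of
the same cell/result).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .epitopes import EpitopeRegion


@dataclass(frozen=True)
class Occurrence:
    """One verbatim occurrence of a motif inside an epitope."""

    parent_id: str
    epitope_index: int | None
    offset: int  # 0-based offset within the epitope string


@dataclass(frozen=True)
class SharedRegion:
    motif: str
    members: tuple[Occurrence, ...]

    def __len__(self) -> int:
        return len(self.motif)


def normalize_motif(text: str) -> str:
    """Normalize hyphenated residue notation ('I-P-Y-K') to a plain string."""
    return text.replace("-", "").replace(" ", "").upper()


def _substrings(text: str, min_len: int) -> set[str]:
    return {
        text[i:j]
        for i in range(len(text))
        for j in range(i + min_len, len(text) + 1)
    }


def _maximal(motifs: Iterable[str]) -> list[str]:
    """Drop motifs contained in a longer motif of the same set; sort by
    length descending then lexicographically."""
    pool = set(motifs)
    kept = [m for m in pool if not any(m != other and m in other for other in pool)]
    return sorted(kept, key=lambda m: (-len(m), m))


def _occurrences(motif: str, epitopes: Sequence[EpitopeRegion]) -> tuple[Occurrence, ...]:
    found = []
    for ep in epitopes:
        offset = ep.sequence.find(motif)
        while offset != -1:
            found.append(Occurrence(ep.parent_id, ep.epitope_index, offset))
            offset = ep.sequence.find(motif, offset + 1)
    return tuple(found)


def _common_motifs(
    set_a: Sequence[EpitopeRegion], set_b: Sequence[EpitopeRegion], min_len: int
) -> set[str]:
    subs_a: set[str] = set()
    for ep in set_a:
        subs_a |= _substrings(ep.sequence, min_len)
    return {m for m in subs_a if any(m in ep.sequence for ep in set_b)}


def shared_substrings(
    set_a: Sequence[EpitopeRegion],
    set_b: Sequence[EpitopeRegion],
    min_len: int = 4,
) -> list[SharedRegion]:
    """Maximal common substrings (>= min_len) between two epitope sets.

    Deduplicated by motif, sorted by length descending then lexicographic;
    every returned motif is verifiable by direct substring search in each
    listed member occurrence.  Empty output is a valid result (the "0"
    cells of a triad diagram).
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    motifs = _maximal(_common_motifs(set_a, set_b, min_len))
    return [
        SharedRegion(motif=m, members=_occurrences(m, list(set_a) + list(set_b)))
        for m in motifs
    ]


def longest_shared_motif(
    set_a: Sequence[EpitopeRegion], set_b: Sequence[EpitopeRegion], min_len: int = 1
) -> str | None:
    regions = shared_substrings(set_a, set_b, min_len)
    return regions[0].motif if regions else None


def triad_partition(
    sets: Mapping[str, Sequence[EpitopeRegion]], min_len: int = 4
) -> dict[frozenset[str], list[str]]:
    """Venn partition of shared motifs among exactly three epitope sets.

    Each motif is assigned to its most specific cell: the three-way cell
    holds motifs occurring in all three sets; a two-way cell holds motifs
    common to exactly those two.  Cells are independently
    maximal-deduplicated, so a pairwise motif may properly contain a
    shorter three-way motif.
    """
    if len(sets) != 3:
        raise ValueError(f"triad_partition needs exactly 3 sets, got {len(sets)}")
    labels = list(sets)
    present: dict[str, set[str]] = {}
    for label in labels:
        for ep in sets[label]:
            for motif in _substrings(ep.sequence, min_len):
                present.setdefault(motif, set()).add(label)

    cells: dict[frozenset[str], list[str]] = {}
    triple = frozenset(labels)
    for pair_or_triple in [triple] + [triple - {x} for x in labels]:
        members = [
            m for m, owners in present.items() if owners >= pair_or_triple
        ]
        if pair_or_triple != triple:
            # exactly these two: exclude motifs also present in the third set
            members = [m for m in members if present[m] != set(triple)]
        cells[frozenset(pair_or_triple)] = _maximal(members)
    return cells


def render_triad(cells: Mapping[frozenset[str], list[str]]) -> dict[str, str | list[str]]:
    """Text rendering of a triad partition; empty cells become '0'."""
    out: dict[str, str | list[str]] = {}
    for cell, motifs in cells.items():
        key = " & ".join(sorted(cell))
        out[key] = motifs if motifs else "0"
    return out


@dataclass(frozen=True)
class ValidatedOverlap:
    """Shared-motif report of a predicted set against one validated epitope."""

    validated: EpitopeRegion
    motifs: tuple[SharedRegion, ...]

    @property
    def overlaps(self) -> bool:
        return bool(self.motifs)


def validated_epitope_check(
    predicted: Sequence[EpitopeRegion],
    validated: Sequence[EpitopeRegion],
    min_len: int = 4,
) -> list[ValidatedOverlap]:
    """Check predicted regions against each validated epitope separately."""
    if not validated:
        raise ValueError("validated epitope set must be non-empty")
    reports = []
    for v in validated:
        motifs = shared_substrings(list(predicted), [v], min_len) if predicted else []
        reports.append(ValidatedOverlap(validated=v, motifs=tuple(motifs)))
    return reports


def write_partition(
    cells: Mapping[frozenset[str], list[str]], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(render_triad(cells), handle, indent=2, sort_keys=True)
        handle.write("\n")
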