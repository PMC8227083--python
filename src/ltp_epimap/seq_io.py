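"""Protein FASTA input/output and description-line filtering.

Ingest is strict: records must use the 20-letter amino-acid alphabet
(upper-cased on read); ``X``, ``B``, ``Z`` and gap characters are rejected
with the offending line number, because every downstream statistic (identity
percentages, propensity profiles, PD index) is defined only on standard
residues.  Gaps exist only inside alignments, never in input records.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .residues import AMINO_ACIDS

_VALID = set(AMINO_ACIDS)


class FastaParseError(ValueError):
    """Malformed FASTA input; message names the offending line."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence: accession-or-label id, free-text description, residues."""

    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"{self.id}: residues must be non-empty")
        bad = set(self.residues) - _VALID
        if bad:
            raise ValueError(
                f"{self.id}: illegal residue(s) {sorted(bad)}; "
                f"allowed alphabet is {AMINO_ACIDS}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a protein FASTA file into records, preserving file order.

    Residues are upper-cased and whitespace-stripped.  Raises
    :class:`FastaParseError` naming the line number for headerless leading
    sequence data, empty headers, duplicate ids, empty records, or residues
    outside the 20-letter alphabet.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush(end_line: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        residues = "".join(chunks)
        if not residues:
            raise FastaParseError(f"{path}:{header_line}: record '{header}' has no residues")
        parts = header.split(None, 1)
        rec_id = parts[0]
        description = parts[1] if len(parts) == 2 else ""
        if rec_id in seen:
            raise FastaParseError(f"{path}:{header_line}: duplicate id '{rec_id}'")
        seen.add(rec_id)
        try:
            records.append(SequenceRecord(rec_id, description, residues))
        except ValueError as exc:
            raise FastaParseError(f"{path}: record ending at line {end_line}: {exc}") from exc
        header, chunks = None, []

    with open(path, encoding="utf-8") as handle:
        lineno = 0
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno - 1)
                header = line[1:].strip()
                header_line = lineno
                if not header:
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
            else:
                if header is None:
                    raise FastaParseError(f"{path}:{lineno}: sequence data before any '>' header")
                seq = "".join(line.split()).upper()
                bad = set(seq) - _VALID
                if bad:
                    raise FastaParseError(
                        f"{path}:{lineno}: illegal residue(s) {sorted(bad)} "
                        f"(alphabet {AMINO_ACIDS})"
                    )
                chunks.append(seq)
        flush(lineno)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping residue lines at *width* columns."""
    if width < 1:
        raise ValueError("wrap width must be >= 1")
    with open(path, "w", encoding="utf-8") as handle:
        for rec in records:
            head = f">{rec.id} {rec.description}".rstrip()
            handle.write(head + "\n")
            for start in range(0, len(rec.residues), width):
                handle.write(rec.residues[start : start + width] + "\n")


def filter_by_description(
    records: Sequence[SequenceRecord], keywords: Sequence[str]
) -> list[SequenceRecord]:
    """Keep records whose description contains >=1 keyword (case-insensitive substring).

    This is the description-line selection rule used to pick nsLTP entries out
    of a mixed retrieval set: phrases such as "lipid transfer protein",
    "nonspecific lipid transfer protein" or "lipid transfer like protein" are
    matched as plain substrings, never as regular expressions.  An empty
    keyword list keeps nothing.
    """
    lowered = [k.lower() for k in keywords]
    return [rec for rec in records if any(k in rec.description.lower() for k in lowered)]


#: Description-line phrases used to select nsLTP candidates from NCBI retrievals.
LTP_DESCRIPTION_KEYWORDS: tuple[str, ...] = (
    "lipid transfer protein",
    "nonspecific lipid transfer protein",
    "lipid transfer like protein",
)
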