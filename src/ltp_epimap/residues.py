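"""Amino-acid alphabet and Clustal-style residue similarity groups.

The strong/weak groups are the classic Clustal conservation classes derived
from the Gonnet PAM250 matrix: a "strong" group collects residues whose
mutual Gonnet score exceeds 0.5, a "weak" group those scoring > 0 but below
the strong cutoff.  They drive both the ':' / '.' conservation symbols and
the conservative-substitution model of the synthetic family generator.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"

#: Clustal "strong" groups (Gonnet PAM250 score > 0.5).
STRONG_GROUPS: tuple[frozenset[str], ...] = tuple(
    frozenset(g) for g in ("STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW")
)

#: Clustal "weak" groups (Gonnet PAM250 score > 0).
WEAK_GROUPS: tuple[frozenset[str], ...] = tuple(
    frozenset(g)
    for g in (
        "CSA",
        "ATV",
        "SAG",
        "STNK",
        "STPA",
        "SGND",
        "SNDEQK",
        "NDEQHK",
        "NEQHRK",
        "FVLIM",
        "HFY",
    )
)


def strong_partners(residue: str) -> frozenset[str]:
    """Residues sharing at least one strong group with *residue* (itself excluded)."""
    partners: set[str] = set()
    for group in STRONG_GROUPS:
        if residue in group:
            partners |= group
    partners.discard(residue)
    return frozenset(partners)


def in_one_strong_group(residues: set[str]) -> bool:
    return any(residues <= group for group in STRONG_GROUPS)


def in_one_weak_group(residues: set[str]) -> bool:
    return any(residues <= group for group in WEAK_GROUPS)
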