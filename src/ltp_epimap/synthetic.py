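"""Synthetic nsLTP-like protein families with known ground truth.

Plant type-1 nsLTPs are ~9 kDa (~90-95 residue mature chains) with eight
invariant cysteines forming four disulfides.  The generator emulates
exactly those features — a fixed-length ancestor with an immutable
eight-cysteine scaffold, descendants mutated site-wise with a bias toward
conservative (Clustal strong-group) substitutions, and optional planted
motifs standing in for shared epitopes.  Indels are omitted by default so
plain Hamming identity is exact ground truth for the alignment and
conservation stages.

The per-descendant mutation rate is derived from the requested *pairwise*
descendant-descendant identity: two descendants differ at a site when
either lineage mutated, so for a target identity t over a length-L scaffold
with k invariant cysteines the per-site rate r solves
``(k + (L-k) * (1-r)^2) / L = t`` (chance convergence of two mutations to
the same residue adds a small positive margin).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .phylo import PhyloTree, TreeNode
from .residues import AMINO_ACIDS, strong_partners
from .seq_io import SequenceRecord

#: Cysteine scaffold of the mature type-1 LTP fold (1-based positions).
DEFAULT_CYSTEINES: tuple[int, ...] = (3, 13, 27, 28, 48, 50, 73, 87)


@dataclass(frozen=True)
class PlantedMotif:
    motif: str
    descendants: tuple[int, ...]  # 0-based indices of carriers
    position: int  # 1-based start within the sequence
    overwrite_cysteines: bool = False


@dataclass(frozen=True)
class FamilySpec:
    length: int = 93
    cysteine_positions: tuple[int, ...] = DEFAULT_CYSTEINES
    n_descendants: int = 6
    target_identity: float = 0.7
    motifs: tuple[PlantedMotif, ...] = field(default_factory=tuple)
    p_strong: float = 0.5  # probability a substitution stays in a strong group
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_identity <= 1.0:
            raise ValueError("target identity must be in (0, 1]")
        if not 0.0 <= self.p_strong <= 1.0:
            raise ValueError("p_strong must be in [0, 1]")
        positions = self.cysteine_positions
        if list(positions) != sorted(set(positions)):
            raise ValueError("cysteine positions must be strictly increasing")
        if positions and (positions[0] < 1 or positions[-1] > self.length):
            raise ValueError("cysteine positions out of sequence bounds")
        for m in self.motifs:
            if m.position < 1 or m.position + len(m.motif) - 1 > self.length:
                raise ValueError(f"motif {m.motif!r} does not fit within length {self.length}")
            span = range(m.position, m.position + len(m.motif))
            if not m.overwrite_cysteines and any(p in span for p in positions):
                raise ValueError(
                    f"motif {m.motif!r} at {m.position} collides with the cysteine "
                    "scaffold; set overwrite_cysteines=True to allow"
                )


def descendant_mutation_rate(spec: FamilySpec) -> float:
    """Per-site, per-descendant rate giving ~target pairwise identity."""
    length = spec.length
    k = len(spec.cysteine_positions)
    mutable = length - k
    if mutable <= 0:
        return 0.0
    q = (spec.target_identity * length - k) / mutable
    if q >= 1.0:
        return 0.0
    if q <= 0.0:
        return 1.0
    return 1.0 - float(np.sqrt(q))


def _substitute(residue: str, rng: np.random.Generator, p_strong: float) -> str:
    partners = sorted(strong_partners(residue))
    if partners and rng.random() < p_strong:
        return partners[rng.integers(len(partners))]
    others = [aa for aa in AMINO_ACIDS if aa != residue]
    return others[rng.integers(len(others))]


def generate_family(
    spec: FamilySpec, mutation_rate: float | None = None
) -> tuple[list[SequenceRecord], dict]:
    """Ancestor + mutated descendants, with a full per-site mutation log.

    Returns ``(records, truth)`` where records[0] is the ancestor and truth
    holds the seed, the realized mutation rate and the per-descendant
    mutation log (position, from, to).  Fully reproducible from the spec
    seed.
    """
    rng = np.random.default_rng(spec.seed)
    rate = descendant_mutation_rate(spec) if mutation_rate is None else mutation_rate
    cys = set(spec.cysteine_positions)
    alphabet = list(AMINO_ACIDS)

    ancestor = [alphabet[rng.integers(20)] for _ in range(spec.length)]
    for pos in spec.cysteine_positions:
        ancestor[pos - 1] = "C"
    records = [SequenceRecord("ancestor", "synthetic LTP-like ancestor", "".join(ancestor))]

    log: dict[str, list[tuple[int, str, str]]] = {}
    for d in range(spec.n_descendants):
        residues = list(ancestor)
        events: list[tuple[int, str, str]] = []
        for pos in range(1, spec.length + 1):
            if pos in cys:
                continue
            if rng.random() < rate:
                new = _substitute(residues[pos - 1], rng, spec.p_strong)
                events.append((pos, residues[pos - 1], new))
                residues[pos - 1] = new
        name = f"desc{d}"
        for motif in spec.motifs:
            if d in motif.descendants:
                for k, ch in enumerate(motif.motif):
                    residues[motif.position - 1 + k] = ch
        records.append(
            SequenceRecord(name, "synthetic LTP-like descendant", "".join(residues))
        )
        log[name] = events

    truth = {
        "seed": spec.seed,
        "mutation_rate": rate,
        "target_identity": spec.target_identity,
        "cysteine_positions": list(spec.cysteine_positions),
        "motifs": [
            {"motif": m.motif, "descendants": list(m.descendants), "position": m.position}
            for m in spec.motifs
        ],
        "mutations": {name: [list(e) for e in events] for name, events in log.items()},
    }
    return records, truth


def hamming_identity(a: str, b: str) -> float:
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(1 for x, y in zip(a, b) if x == y) / len(a)


def mean_pairwise_identity(records: Sequence[SequenceRecord]) -> float:
    """Mean Hamming identity over all pairs (equal-length, indel-free sets)."""
    n = len(records)
    if n < 2:
        raise ValueError("need >= 2 records")
    total = 0.0
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += hamming_identity(records[i].residues, records[j].residues)
            count += 1
    return total / count


def generate_tree_family(
    tree: PhyloTree,
    rate: float,
    seed: int,
    length: int = 93,
    cysteine_positions: Sequence[int] = DEFAULT_CYSTEINES,
    p_strong: float = 0.5,
) -> list[SequenceRecord]:
    """Evolve sequences down a phylogeny (oracle for tree reconstruction).

    Each branch mutates every non-cysteine site independently with
    probability ``1 - exp(-rate * branch_length)``, so expected leaf-leaf
    divergence grows with path length.  Leaves of the tree become the
    output records.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    cys = set(cysteine_positions)
    alphabet = list(AMINO_ACIDS)
    ancestor = [alphabet[rng.integers(20)] for _ in range(length)]
    for pos in cysteine_positions:
        ancestor[pos - 1] = "C"

    records: list[SequenceRecord] = []

    def evolve(node: TreeNode, residues: list[str]) -> None:
        if node.is_leaf:
            records.append(
                SequenceRecord(node.name, "synthetic tree-evolved LTP-like", "".join(residues))
            )
            return
        for child, branch in node.children:
            child_res = list(residues)
            p_mut = 1.0 - float(np.exp(-rate * branch))
            for pos in range(1, length + 1):
                if pos in cys:
                    continue
                if rng.random() < p_mut:
                    child_res[pos - 1] = _substitute(child_res[pos - 1], rng, p_strong)
            evolve(child, child_res)

    evolve(tree.root, ancestor)
    return records


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(truth, handle, indent=2, sort_keys=True)
        handle.write("\n")
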