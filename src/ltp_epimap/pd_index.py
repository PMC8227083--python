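"""Property-distance (PD) peptide similarity.

Each residue is mapped into a published five-dimensional physicochemical
descriptor space (a factor-analytic summary of ~500 amino-acid property
scales: polarity, secondary-structure propensity, size, composition,
charge).  The PD index between two equal-length peptides is the
length-averaged per-position Euclidean distance in that space, multiplied
by one global calibration constant:

    pd(a, b) = c * (1/n) * sum_i ||d(a_i) - d(b_i)||

The constant pins the scale to its conventional behavioral anchors:
identical peptides score 0, a single conservative substitution in a 10-mer
stays below 4, and random unrelated peptide pairs score above 10 (the
shipped calibration sets the random-pair median to 13).  ``c`` is computed
once by :func:`calibrate`, persisted in the packaged configuration, and
never recomputed silently.

PD is a metric on equal-length peptides and is insensitive to peptide
length by construction (averaging over positions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .residues import AMINO_ACIDS
from .seq_io import SequenceRecord

DEFAULT_THRESHOLD: float = 4.0
DEFAULT_ANCHOR: float = 13.0


def load_descriptor_table(path: str | Path | None = None) -> dict[str, np.ndarray]:
    """Residue -> 5-vector descriptor table (packaged table by default)."""
    if path is None:
        handle = resources.files("ltp_epimap.data").joinpath("atchley_factors.tsv")
        lines = handle.read_text().splitlines()
    else:
        lines = Path(path).read_text().splitlines()
    table: dict[str, np.ndarray] = {}
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("residue"):
            continue
        parts = line.split("\t")
        table[parts[0]] = np.array([float(x) for x in parts[1:]])
    missing = set(AMINO_ACIDS) - set(table)
    if missing:
        raise ValueError(f"descriptor table missing residues {sorted(missing)}")
    if not all(np.isfinite(v).all() for v in table.values()):
        raise ValueError("descriptor table contains non-finite values")
    return table


def load_calibration() -> dict:
    """The persisted calibration record (constant + the procedure that set it)."""
    with resources.files("ltp_epimap.data").joinpath("pd_calibration.json").open() as fh:
        return json.load(fh)


_TABLE: dict[str, np.ndarray] | None = None
_C: float | None = None


def _defaults() -> tuple[dict[str, np.ndarray], float]:
    global _TABLE, _C
    if _TABLE is None:
        _TABLE = load_descriptor_table()
    if _C is None:
        _C = float(load_calibration()["c"])
    return _TABLE, _C


@dataclass(frozen=True)
class PDMatch:
    query: str
    subject_id: str
    offset: int  # 1-based offset of the window in the subject
    subject_peptide: str
    pd: float


def pd_distance(
    pep_a: str,
    pep_b: str,
    table: Mapping[str, np.ndarray] | None = None,
    c: float | None = None,
) -> float:
    """PD index between two equal-length peptides (0 iff identical)."""
    if len(pep_a) != len(pep_b):
        raise ValueError(f"peptide lengths differ: {len(pep_a)} vs {len(pep_b)}")
    if not pep_a:
        raise ValueError("peptides must be non-empty")
    default_table, default_c = _defaults()
    table = table if table is not None else default_table
    c = c if c is not None else default_c
    try:
        va = np.array([table[ch] for ch in pep_a])
        vb = np.array([table[ch] for ch in pep_b])
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None
    return float(c * np.linalg.norm(va - vb, axis=1).mean())


def db_scan(
    query: str,
    db: Sequence[SequenceRecord],
    threshold: float = DEFAULT_THRESHOLD,
    table: Mapping[str, np.ndarray] | None = None,
    c: float | None = None,
) -> list[PDMatch]:
    """Scan every query-length window of every database sequence.

    Returns matches with pd < ``threshold`` sorted by pd ascending, ties by
    subject id then offset.  Pass ``threshold=float('inf')`` to keep every
    window.
    """
    if not query:
        raise ValueError("empty query peptide")
    default_table, default_c = _defaults()
    table = table if table is not None else default_table
    c = c if c is not None else default_c
    n = len(query)
    q = np.array([table[ch] for ch in query])
    matches: list[PDMatch] = []
    for subject in db:
        seq = subject.residues
        if len(seq) < n:
            continue
        s = np.array([table[ch] for ch in seq])
        # dist[i, p] = descriptor distance between query residue i and subject position p
        dist = np.linalg.norm(q[:, None, :] - s[None, :, :], axis=2)
        for offset in range(len(seq) - n + 1):
            pd_val = float(c * dist[np.arange(n), offset + np.arange(n)].mean())
            if pd_val < threshold:
                matches.append(
                    PDMatch(
                        query=query,
                        subject_id=subject.id,
                        offset=offset + 1,
                        subject_peptide=seq[offset : offset + n],
                        pd=pd_val,
                    )
                )
    matches.sort(key=lambda m: (m.pd, m.subject_id, m.offset))
    return matches


def random_pair_distances(
    table: Mapping[str, np.ndarray],
    seed: int,
    n_pairs: int,
    length: int = 10,
) -> np.ndarray:
    """Uncalibrated mean per-position distances of random unrelated peptide pairs."""
    rng = np.random.default_rng(seed)
    residues = np.array(list(AMINO_ACIDS))
    vectors = np.array([table[ch] for ch in residues])
    idx_a = rng.integers(0, 20, size=(n_pairs, length))
    idx_b = rng.integers(0, 20, size=(n_pairs, length))
    return np.linalg.norm(vectors[idx_a] - vectors[idx_b], axis=2).mean(axis=1)


def calibrate(
    table: Mapping[str, np.ndarray] | None = None,
    seed: int = 42,
    n_pairs: int = 10_000,
    anchor: float = DEFAULT_ANCHOR,
    length: int = 10,
) -> float:
    """Choose the global constant c so the median PD of random unrelated
    peptide pairs equals ``anchor``.

    With the anchor at its default (13) this realizes the conventional PD
    scale: identity at 0, conservative single substitutions < 4, random
    pairs > 10.  The result is persisted in the packaged configuration; it
    is an input to the method, not something recomputed per run.
    """
    if n_pairs < 1000:
        raise ValueError("n_pairs must be >= 1000 for a stable median")
    if table is None:
        table = load_descriptor_table()
    vectors = np.array([table[ch] for ch in AMINO_ACIDS])
    if np.allclose(vectors, vectors[0]):
        raise ValueError("degenerate descriptor table: all residue vectors equal")
    median = float(np.median(random_pair_distances(table, seed, n_pairs, length)))
    return anchor / median
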